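"""Stimulus configuration and harmonic sine-cosine reference signals.

For a stimulus flickering at f_k the SSVEP carries power at f_k and its
harmonics, so the canonical reference is a matrix whose rows are
sin(2*pi*h*f_k*n) and cos(2*pi*h*f_k*n) for harmonics h = 1..N_h sampled at
n = 1/Fs, 2/Fs, ..., Np/Fs. The time index starts at 1/Fs (a fixed phase
convention; correlation-based recognition is insensitive to it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusConfig", "ReferenceSet", "build_reference", "build_reference_set"]


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus frequencies f_k (Hz), harmonic count N_h, sampling rate Fs."""

    frequencies: tuple[float, ...]
    n_harmonics: int = 5
    fs: float = 256.0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        if len(freqs) == 0:
            raise ValueError("need at least one stimulus frequency")
        if any(f <= 0 for f in freqs):
            raise ValueError(f"frequencies must be positive, got {freqs}")
        if len(set(freqs)) != len(freqs):
            raise ValueError(f"frequencies must be distinct, got {freqs}")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_harmonics * max(freqs) >= self.fs / 2:
            raise ValueError(
                f"harmonic {self.n_harmonics} of {max(freqs)} Hz reaches the "
                f"Nyquist frequency {self.fs / 2} Hz"
            )
        object.__setattr__(self, "frequencies", freqs)

    @property
    def n_targets(self) -> int:
        return len(self.frequencies)


def build_reference(f: float, n_harmonics: int, fs: float, n_samples: int) -> np.ndarray:
    """Reference matrix (2*N_h, Np): rows alternate sin/cos of harmonics 1..N_h."""
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if n_harmonics * f >= fs / 2:
        raise ValueError(
            f"harmonic {n_harmonics} of {f} Hz reaches Nyquist ({fs / 2} Hz)"
        )
    n = np.arange(1, n_samples + 1) / fs
    out = np.empty((2 * n_harmonics, n_samples))
    for h in range(1, n_harmonics + 1):
        phase = 2 * np.pi * h * f * n
        out[2 * (h - 1)] = np.sin(phase)
        out[2 * (h - 1) + 1] = np.cos(phase)
    return out


@dataclass(frozen=True)
class ReferenceSet:
    """One reference matrix Y_k per stimulus frequency, ordered as the config."""

    matrices: tuple[np.ndarray, ...]
    config: StimulusConfig

    def __getitem__(self, k: int) -> np.ndarray:
        return self.matrices[k]

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_samples(self) -> int:
        return self.matrices[0].shape[1]


def build_reference_set(config: StimulusConfig, n_samples: int) -> ReferenceSet:
    """Pre-construct Y_k for every configured frequency at ``n_samples`` points."""
    matrices = tuple(
        build_reference(f, config.n_harmonics, config.fs, n_samples)
        for f in config.frequencies
    )
    return ReferenceSet(matrices=matrices, config=config)
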