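"""Synthetic multi-subject SSVEP datasets with controllable narrowband SNR.

The generator emulates a six-target, six-channel occipital SSVEP recording:
for each (subject, block, target) trial the epoch is

    X = g * A_n @ S_k + E,

where S_k stacks the harmonic sources sin(2*pi*h*f_k*t + phi) with
amplitudes h**(-gamma), A_n is a subject-specific channel-mixing matrix that
is fixed across blocks (the structure the optimized common template
exploits: a shared stimulus-locked waveform observed through per-subject
spatial projections), and E is the background: per-channel pink (1/f) noise
plus subject-specific narrowband rhythms — alpha (8-13 Hz) and weaker beta
(13-25 Hz) oscillators with fixed individual frequencies and topographies,
random phase and Rayleigh-modulated amplitude per trial. The rhythms matter:
occipital alpha overlaps the 9-14 Hz stimulus range and, being nearly
sinusoidal, matches sine-cosine references perfectly while averaging out of
stimulus-locked templates — the background structure that separates
template-based recognition from the ideal-reference baseline in real EEG.

The gain g is chosen so that the fundamental's power relative to the total
background power (pink floor + rhythms of that trial) inside a 1 Hz band
around f_k hits the requested SNR in dB.

Phases are stimulus-locked: each (frequency, harmonic) has one population
phase, each subject a fixed offset around it (``subject_phase_sd``), and
each trial adds small phase and amplitude jitter. Everything is driven by a
single seed, so identical configs generate bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .references import StimulusConfig
from .signal_model import Dataset, EEGEpoch

__all__ = [
    "SimConfig",
    "generate_dataset",
    "pink_noise",
    "ssvep_source",
    "measure_narrowband_snr",
    "DEFAULT_CHANNELS",
]

#: occipital/parietal montage of the six-target recording this emulates
DEFAULT_CHANNELS = ("Oz", "O1", "O2", "P3", "P4", "Pz")


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: 5 subjects, 6 blocks, 9-14 Hz targets, 256 Hz."""

    n_subjects: int = 5
    n_blocks: int = 6
    frequencies: tuple[float, ...] = (9.0, 10.0, 11.0, 12.0, 13.0, 14.0)
    n_channels: int = 6
    fs: float = 256.0
    duration: float = 5.0
    snr_db: float = 0.0
    n_harmonics_src: int = 3
    harmonic_decay: float = 1.0
    phase_jitter_sd: float = 0.1
    amplitude_jitter_sd: float = 0.1
    subject_phase_sd: float = 0.3
    n_alpha_osc: int = 2
    n_beta_osc: int = 3
    rhythm_amp: float = 1.0
    onset_tau: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_blocks", "n_channels", "n_harmonics_src"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        freqs = tuple(float(f) for f in self.frequencies)
        if len(freqs) == 0 or any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be positive")
        if self.n_harmonics_src * max(freqs) >= self.fs / 2:
            raise ValueError(
                f"harmonic {self.n_harmonics_src} of {max(freqs)} Hz reaches "
                f"Nyquist ({self.fs / 2} Hz)"
            )
        if self.harmonic_decay < 0:
            raise ValueError("harmonic_decay must be >= 0")
        if self.n_alpha_osc < 0 or self.n_beta_osc < 0 or self.rhythm_amp < 0:
            raise ValueError("rhythm parameters must be >= 0")
        if self.onset_tau < 0:
            raise ValueError("onset_tau must be >= 0 (0 disables the buildup)")
        object.__setattr__(self, "frequencies", freqs)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == len(DEFAULT_CHANNELS):
            return DEFAULT_CHANNELS
        return tuple(f"CH{i + 1}" for i in range(self.n_channels))

    def stimulus_config(self, n_harmonics: int = 5) -> StimulusConfig:
        """Matching analysis-side stimulus description."""
        return StimulusConfig(
            frequencies=self.frequencies, n_harmonics=n_harmonics, fs=self.fs
        )


def pink_noise(
    n_channels: int, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-variance noise with ~1/f power spectral density.

    Shaped in the frequency domain: white Gaussian spectra scaled by
    f**(-1/2) in amplitude (DC removed), then normalized per channel.
    """
    if n_channels < 1 or n_samples < 2:
        raise ValueError("need n_channels >= 1 and n_samples >= 2")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * scale
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    noise -= noise.mean(axis=1, keepdims=True)
    std = noise.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std


def _harmonic_rows(
    f: float,
    n_samples: int,
    fs: float,
    harmonics: int,
    decay: float,
    phases: np.ndarray,
) -> np.ndarray:
    """(harmonics, n_samples) rows h**(-decay) * sin(2 pi h f t + phi_h)."""
    t = np.arange(1, n_samples + 1) / fs
    h = np.arange(1, harmonics + 1)
    amps = h.astype(float) ** -decay
    return amps[:, None] * np.sin(
        2 * np.pi * h[:, None] * f * t[None, :] + np.asarray(phases)[:, None]
    )


def ssvep_source(
    f: float,
    n_samples: int,
    fs: float,
    harmonics: int,
    decay: float,
    phases,
) -> np.ndarray:
    """Single-channel evoked source: sum over harmonics of damped sinusoids.

    The fundamental has unit amplitude before any SNR scaling.
    """
    if harmonics * f >= fs / 2:
        raise ValueError(
            f"harmonic {harmonics} of {f} Hz reaches Nyquist ({fs / 2} Hz)"
        )
    phases = np.broadcast_to(np.asarray(phases, dtype=float), (harmonics,))
    return _harmonic_rows(f, n_samples, fs, harmonics, decay, phases).sum(axis=0)


def _narrowband_process(
    f_center: float,
    bandwidth: float,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance narrowband noise: Gaussian spectral peak at ``f_center``.

    Models a cortical rhythm (alpha/beta): nearly sinusoidal over ~1 s but
    with drifting amplitude and phase, so its correlation with a pure sine
    decays as windows grow.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.exp(-0.5 * ((freqs - f_center) / bandwidth) ** 2)
    shape[0] = 0.0
    spec = (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    ) * shape
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    std = x.std()
    return x / std if std > 0 else x


def _band_power(
    x: np.ndarray, fs: float, f_lo: float, f_hi: float, return_bins: bool = False
):
    """Per-channel signal power contributed by frequencies in [f_lo, f_hi]."""
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    # Parseval with one-sided doubling (DC/Nyquist excluded by the band)
    power = 2.0 * np.sum(np.abs(spec[..., band]) ** 2, axis=-1) / n**2
    if return_bins:
        return power, int(band.sum())
    return power


def measure_narrowband_snr(
    data: np.ndarray, f: float, fs: float, half_bw: float = 0.5
) -> float:
    """Estimate SNR (dB) at ``f``: band power minus a flank-estimated noise floor.

    The noise floor inside the signal band is interpolated from flanking
    bands 1-3 Hz away on each side (which contain no stimulus harmonics for
    the 9-14 Hz designs this emulates). Power is counted per FFT bin so the
    flank estimate scales exactly to the signal band's bin count. ``data``
    may be one epoch (channels x samples) or a stack of epochs; all leading
    axes are pooled.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    p_band, n_band = _band_power(data, fs, f - half_bw, f + half_bw, True)
    p_lo, n_lo = _band_power(data, fs, f - 3.0, f - 1.0, True)
    p_hi, n_hi = _band_power(data, fs, f + 1.0, f + 3.0, True)
    per_bin = (p_lo.mean() + p_hi.mean()) / (n_lo + n_hi)
    noise_in_band = per_bin * n_band
    signal = max(p_band.mean() - noise_in_band, 1e-300)
    return float(10.0 * np.log10(signal / max(noise_in_band, 1e-300)))


def generate_dataset(config: SimConfig) -> Dataset:
    """Simulate every (subject, block, target) epoch of the configured study."""
    rng = np.random.default_rng(config.seed)
    n_p = config.n_samples
    n_c = config.n_channels
    H = config.n_harmonics_src
    K = len(config.frequencies)
    t = np.arange(1, n_p + 1) / config.fs
    # stimulus-locked onset buildup of the evoked oscillation; reproducible
    # across trials, so templates capture it while sine references cannot
    if config.onset_tau > 0:
        envelope = 1.0 - np.exp(-t / config.onset_tau)
    else:
        envelope = np.ones(n_p)
    env_ms = float(np.mean(envelope**2))

    # population phases per (frequency, harmonic); stimulus-locked
    base_phases = rng.uniform(0, 2 * np.pi, size=(K, H))
    # subject-specific fixed structure: mixing, phase offsets, background rhythms
    mixings, subject_phases, rhythms = [], [], []
    for _ in range(config.n_subjects):
        A = rng.normal(1.0, 0.5, size=(n_c, H)) * np.sign(
            rng.uniform(-0.2, 1.0, size=(n_c, H))
        )
        mixings.append(A)
        subject_phases.append(
            base_phases + rng.normal(0, config.subject_phase_sd, size=(K, H))
        )
        oscs = []
        for _ in range(config.n_alpha_osc):
            oscs.append(
                (
                    rng.uniform(8.0, 13.0),  # individual alpha frequency
                    rng.normal(0, 1.0, size=n_c),  # fixed topography
                    config.rhythm_amp * rng.rayleigh(1.0),
                )
            )
        for _ in range(config.n_beta_osc):
            oscs.append(
                (
                    rng.uniform(13.0, 25.0),
                    rng.normal(0, 1.0, size=n_c),
                    0.5 * config.rhythm_amp * rng.rayleigh(1.0),
                )
            )
        rhythms.append(oscs)

    dataset = Dataset(stimulus_config=config.stimulus_config())
    snr_lin = 10.0 ** (config.snr_db / 10.0)
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        A = mixings[s]
        for block in range(config.n_blocks):
            for k, f_k in enumerate(config.frequencies):
                jitter = rng.normal(0, config.phase_jitter_sd, size=H)
                amp = max(1.0 + rng.normal(0, config.amplitude_jitter_sd), 0.05)
                rows = _harmonic_rows(
                    f_k, n_p, config.fs, H, config.harmonic_decay,
                    subject_phases[s][k] + jitter,
                )
                signal = amp * (A @ (envelope * rows))
                noise = pink_noise(n_c, n_p, config.fs, rng)
                for f_osc, topo, osc_amp in rhythms[s]:
                    trial_amp = osc_amp * rng.rayleigh(1.0)
                    source = _narrowband_process(
                        f_osc, 0.6, n_p, config.fs, rng
                    )
                    noise = noise + trial_amp * topo[:, None] * source[None, :]
                # fundamental power per channel: env_ms * (amp * A[:, 0])**2 / 2;
                # background power taken from the realized noise in f_k +/- 0.5 Hz
                p_sig = float(env_ms * np.mean((amp * A[:, 0]) ** 2) / 2.0)
                p_noise = float(
                    _band_power(noise, config.fs, f_k - 0.5, f_k + 0.5).mean()
                )
                g = np.sqrt(snr_lin * p_noise / max(p_sig, 1e-300))
                data = 10.0 * (g * signal + noise)  # ~10 µV background scale
                dataset.add(
                    EEGEpoch(
                        data=data,
                        fs=config.fs,
                        channel_labels=config.channel_labels,
                        subject_id=subject_id,
                        block_id=block,
                        target_index=k,
                    )
                )
    return dataset
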