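"""EEG epoch container and the preprocessing chain.

An :class:`EEGEpoch` is one multichannel window of EEG (channels x samples,
microvolts) together with its sampling rate, electrode labels and the
(subject, block, target) labels that identify it inside a recording session.
The preprocessing operations mirror standard SSVEP practice: per-channel mean
removal, a zero-phase band-pass (7-80 Hz by default), a powerline notch
(50 Hz), anti-aliased integer-factor down-sampling, window extraction and
channel (montage) selection.

All filters run forward-backward (``filtfilt``), so the chain introduces no
group delay and window onsets stay aligned with the stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGEpoch",
    "Dataset",
    "PreprocessSpec",
    "center",
    "bandpass",
    "notch",
    "downsample",
    "extract_window",
    "select_channels",
    "preprocess",
]


@dataclass(frozen=True)
class EEGEpoch:
    """One multichannel EEG window: ``data`` is (n_channels, n_samples) in µV."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = "unknown"
    block_id: int = 0
    target_index: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={data.ndim}")
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError(f"need >=1 channel and >=2 samples, got shape {data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        labels = tuple(self.channel_labels)
        if len(labels) != data.shape[0]:
            raise ValueError(
                f"{len(labels)} channel labels for {data.shape[0]} data rows"
            )
        if len(set(labels)) != len(labels):
            raise ValueError(f"channel labels must be distinct, got {labels}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Window length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGEpoch":
        """Copy of this epoch with new samples (labels and ids preserved)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing parameters: band edges, notch frequency, target rate.

    ``notch_freq=None`` disables the notch. ``onset_offset`` is the delay (s)
    from epoch start to the analysis window used downstream.
    """

    band_low: float = 7.0
    band_high: float = 80.0
    notch_freq: float | None = 50.0
    target_fs: float = 256.0
    onset_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError(
                f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})"
            )
        if self.band_high >= self.target_fs / 2:
            raise ValueError(
                f"band_high={self.band_high} must lie below target Nyquist "
                f"{self.target_fs / 2}"
            )
        if self.notch_freq is not None and not (
            self.band_low < self.notch_freq < self.band_high
        ):
            raise ValueError(
                f"notch_freq={self.notch_freq} outside the passband "
                f"({self.band_low}, {self.band_high}); use None to disable"
            )
        if self.onset_offset < 0:
            raise ValueError("onset_offset must be >= 0")


def center(epoch: EEGEpoch) -> EEGEpoch:
    """Remove each channel's mean (idempotent)."""
    data = epoch.data - epoch.data.mean(axis=1, keepdims=True)
    return epoch.with_data(data)


def bandpass(epoch: EEGEpoch, low: float, high: float) -> EEGEpoch:
    """Zero-phase 4th-order Butterworth band-pass between ``low`` and ``high`` Hz."""
    nyq = epoch.fs / 2
    if low <= 0:
        raise ValueError(f"band_low must be > 0, got {low}")
    if high <= low:
        raise ValueError(f"band_high={high} must exceed band_low={low}")
    if high >= nyq:
        raise ValueError(f"band_high={high} must lie below Nyquist {nyq}")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=epoch.fs, output="sos")
    return epoch.with_data(sps.sosfiltfilt(sos, epoch.data, axis=1))


def notch(epoch: EEGEpoch, f0: float, quality: float = 35.0) -> EEGEpoch:
    """Zero-phase IIR notch at ``f0`` Hz (quality factor 35 by default)."""
    nyq = epoch.fs / 2
    if not (0 < f0 < nyq):
        raise ValueError(f"notch frequency {f0} must lie in (0, {nyq})")
    b, a = sps.iirnotch(f0, quality, fs=epoch.fs)
    return epoch.with_data(sps.filtfilt(b, a, epoch.data, axis=1))


def downsample(epoch: EEGEpoch, target_fs: float) -> EEGEpoch:
    """Anti-aliased decimation to ``target_fs`` (must divide fs exactly).

    A zero-phase low-pass at 0.8x the target Nyquist precedes taking every
    k-th sample, so stimulus harmonics below the new Nyquist are preserved.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    ratio = epoch.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"fs={epoch.fs} is not an integer multiple of target_fs={target_fs}"
        )
    if factor == 1:
        return epoch
    cutoff = 0.8 * (target_fs / 2)
    sos = sps.butter(8, cutoff, btype="lowpass", fs=epoch.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, epoch.data, axis=1)
    return epoch.with_data(filtered[:, ::factor], fs=target_fs)


def extract_window(epoch: EEGEpoch, onset: float, tw: float) -> EEGEpoch:
    """Samples in the half-open window [onset, onset + tw) seconds, 0-based."""
    if onset < 0:
        raise ValueError(f"onset must be >= 0, got {onset}")
    start = int(round(onset * epoch.fs))
    length = int(round(tw * epoch.fs))
    if start + length > epoch.n_samples:
        raise ValueError(
            f"window onset={onset}s tw={tw}s needs {start + length} samples but the "
            f"epoch has {epoch.n_samples} ({epoch.duration:.3f}s)"
        )
    return epoch.with_data(epoch.data[:, start : start + length])


def select_channels(epoch: EEGEpoch, labels: Sequence[str]) -> EEGEpoch:
    """Subset/reorder channels to ``labels`` (each must be present)."""
    index = {lab: i for i, lab in enumerate(epoch.channel_labels)}
    missing = [lab for lab in labels if lab not in index]
    if missing:
        raise KeyError(
            f"channel(s) {missing} not in epoch montage {list(epoch.channel_labels)}"
        )
    rows = [index[lab] for lab in labels]
    return replace(epoch, data=epoch.data[rows, :], channel_labels=tuple(labels))


def preprocess(epoch: EEGEpoch, spec: PreprocessSpec) -> EEGEpoch:
    """Full chain: center -> band-pass -> notch -> down-sample.

    Window extraction is left to the evaluation stage, which sweeps window
    lengths on the already-filtered signal.
    """
    out = center(epoch)
    out = bandpass(out, spec.band_low, spec.band_high)
    if spec.notch_freq is not None:
        out = notch(out, spec.notch_freq)
    if abs(out.fs - spec.target_fs) > 1e-9:
        out = downsample(out, spec.target_fs)
    return out


class Dataset:
    """Epochs indexed by (subject_id, block_id, target_index).

    All epochs must share the sampling rate and montage; duplicate keys are
    rejected. ``stimulus_config`` (see :mod:`octcca.references`) travels with
    the data so that downstream stages know the stimulus frequencies.
    """

    def __init__(self, stimulus_config=None):
        self.stimulus_config = stimulus_config
        self._epochs: dict[tuple, EEGEpoch] = {}

    def add(self, epoch: EEGEpoch) -> None:
        key = (epoch.subject_id, epoch.block_id, epoch.target_index)
        if key in self._epochs:
            raise ValueError(f"duplicate epoch for (subject, block, target)={key}")
        if self._epochs:
            ref = next(iter(self._epochs.values()))
            if abs(epoch.fs - ref.fs) > 1e-9:
                raise ValueError(f"mixed sampling rates: {epoch.fs} vs {ref.fs}")
            if epoch.channel_labels != ref.channel_labels:
                raise ValueError(
                    f"mixed montages: {epoch.channel_labels} vs {ref.channel_labels}"
                )
        self._epochs[key] = epoch

    def get(self, subject_id, block_id: int, target_index: int) -> EEGEpoch:
        key = (subject_id, block_id, target_index)
        try:
            return self._epochs[key]
        except KeyError:
            raise KeyError(
                f"no epoch for subject={subject_id!r} block={block_id} "
                f"target={target_index}"
            ) from None

    def __len__(self) -> int:
        return len(self._epochs)

    def __iter__(self) -> Iterator[EEGEpoch]:
        return iter(self._epochs.values())

    def __contains__(self, key: tuple) -> bool:
        return key in self._epochs

    @property
    def subjects(self) -> list:
        return sorted({k[0] for k in self._epochs})

    @property
    def blocks(self) -> list[int]:
        return sorted({k[1] for k in self._epochs})

    @property
    def targets(self) -> list[int]:
        return sorted({k[2] for k in self._epochs})

    @property
    def fs(self) -> float:
        ref = next(iter(self._epochs.values()))
        return ref.fs

    @property
    def channel_labels(self) -> tuple[str, ...]:
        ref = next(iter(self._epochs.values()))
        return ref.channel_labels

    def map(self, fn) -> "Dataset":
        """New dataset with ``fn`` applied to every epoch."""
        out = Dataset(stimulus_config=self.stimulus_config)
        for epoch in self._epochs.values():
            out.add(fn(epoch))
        return out
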