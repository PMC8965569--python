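"""Disk formats: HDF5 dataset/model containers, benchmark MAT reader, CSV results.

Datasets are stored one HDF5 group per epoch (``s<subject>/b<block>/t<target>``)
with a ``data`` array and fs/label attributes. The benchmark reader opens the
public 40-target SSVEP benchmark's per-subject MAT container, a 4-D array
ordered (channel, sample, target, block); the container carries no channel
names, so a label list is supplied by the caller (default CH1..CH64).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat

from .references import StimulusConfig
from .signal_model import Dataset, EEGEpoch, extract_window, select_channels
from .templates import OCTModel

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_oct_model",
    "load_oct_model",
    "read_benchmark_subject",
    "ResultsTable",
    "write_results",
    "read_results",
    "load_config",
]

RESULTS_COLUMNS = ["method", "subject", "window_s", "accuracy_pct", "itr_bits_min"]


def save_dataset(dataset: Dataset, path) -> None:
    """Write every epoch plus the stimulus config to an HDF5 container."""
    with h5py.File(path, "w") as h5:
        if dataset.stimulus_config is not None:
            cfg = dataset.stimulus_config
            h5.attrs["frequencies"] = list(cfg.frequencies)
            h5.attrs["n_harmonics"] = cfg.n_harmonics
            h5.attrs["stim_fs"] = cfg.fs
        for epoch in dataset:
            grp = h5.create_group(
                f"s{epoch.subject_id}/b{epoch.block_id}/t{epoch.target_index}"
            )
            grp.create_dataset("data", data=epoch.data)
            grp.attrs["fs"] = epoch.fs
            grp.attrs["channel_labels"] = list(epoch.channel_labels)
            grp.attrs["subject_id"] = str(epoch.subject_id)
            grp.attrs["block_id"] = int(epoch.block_id)
            grp.attrs["target_index"] = int(epoch.target_index)


def load_dataset(path) -> Dataset:
    """Inverse of :func:`save_dataset`."""
    with h5py.File(path, "r") as h5:
        stim = None
        if "frequencies" in h5.attrs:
            stim = StimulusConfig(
                frequencies=tuple(h5.attrs["frequencies"]),
                n_harmonics=int(h5.attrs["n_harmonics"]),
                fs=float(h5.attrs["stim_fs"]),
            )
        dataset = Dataset(stimulus_config=stim)
        for sname in h5:
            for bname in h5[sname]:
                for tname in h5[sname][bname]:
                    grp = h5[sname][bname][tname]
                    dataset.add(
                        EEGEpoch(
                            data=grp["data"][()],
                            fs=float(grp.attrs["fs"]),
                            channel_labels=tuple(
                                lab if isinstance(lab, str) else lab.decode()
                                for lab in grp.attrs["channel_labels"]
                            ),
                            subject_id=str(grp.attrs["subject_id"]),
                            block_id=int(grp.attrs["block_id"]),
                            target_index=int(grp.attrs["target_index"]),
                        )
                    )
    return dataset


def save_oct_model(model: OCTModel, path) -> None:
    """Store /omega (K, N, N_c), /xhat (K, N, N_p) and /lambda (K,)."""
    omega = np.stack([np.stack(block) for block in model.omegas])
    xhat = np.stack(model.xhat)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("omega", data=omega)
        h5.create_dataset("xhat", data=xhat)
        h5.create_dataset("lambda", data=np.asarray(model.lambdas))


def load_oct_model(path) -> OCTModel:
    with h5py.File(path, "r") as h5:
        omega = h5["omega"][()]
        xhat = h5["xhat"][()]
        lams = h5["lambda"][()]
    return OCTModel(
        omegas=tuple(tuple(row for row in block) for block in omega),
        xhat=tuple(xhat),
        lambdas=tuple(float(v) for v in lams),
    )


def read_benchmark_subject(
    path,
    montage: list[str] | None = None,
    channel_labels: list[str] | None = None,
    onset_offset: float = 0.5,
    fs: float = 250.0,
    subject_id: str | None = None,
    stimulus_config: StimulusConfig | None = None,
) -> Dataset:
    """Read one subject of the public 40-target benchmark MAT container.

    Expects a 4-D array (channel, sample, target, block). ``onset_offset``
    seconds (the visual cue period) are dropped from the start of every
    epoch; ``montage`` optionally subsets channels by label.
    """
    mat = loadmat(path)
    arrays = [v for k, v in mat.items() if not k.startswith("__")]
    candidates = [a for a in arrays if isinstance(a, np.ndarray) and a.ndim == 4]
    if not candidates:
        shapes = [getattr(a, "shape", None) for a in arrays]
        raise ValueError(
            f"no 4-D (channel, sample, target, block) array in {path}; "
            f"found shapes {shapes}"
        )
    data = candidates[0].astype(float)
    n_ch, n_samp, n_targets, n_blocks = data.shape
    if channel_labels is None:
        channel_labels = [f"CH{i + 1}" for i in range(n_ch)]
    if len(channel_labels) != n_ch:
        raise ValueError(
            f"{len(channel_labels)} channel labels for {n_ch} data channels"
        )
    if subject_id is None:
        subject_id = str(path)
    dataset = Dataset(stimulus_config=stimulus_config)
    for block in range(n_blocks):
        for target in range(n_targets):
            epoch = EEGEpoch(
                data=data[:, :, target, block],
                fs=fs,
                channel_labels=tuple(channel_labels),
                subject_id=subject_id,
                block_id=block,
                target_index=target,
            )
            if onset_offset > 0:
                epoch = extract_window(
                    epoch, onset_offset, epoch.duration - onset_offset
                )
            if montage is not None:
                epoch = select_channels(epoch, montage)
            dataset.add(epoch)
    return dataset


@dataclass
class ResultsTable:
    """Rows of (method, subject, window_s, accuracy_pct, itr_bits_min)."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULTS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"results table missing columns {missing}")
        acc = self.frame["accuracy_pct"]
        if len(acc) and (acc.min() < 0 or acc.max() > 100):
            raise ValueError("accuracy_pct outside [0, 100]")
        if len(self.frame) and self.frame["itr_bits_min"].min() < 0:
            raise ValueError("itr_bits_min must be >= 0")


def write_results(table: ResultsTable, path) -> None:
    table.frame.to_csv(path, index=False, columns=RESULTS_COLUMNS)


def read_results(path) -> ResultsTable:
    frame = pd.read_csv(path)
    missing = [c for c in RESULTS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("window_s", "accuracy_pct", "itr_bits_min"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        frame[col] = coerced
    return ResultsTable(frame=frame)


def load_config(path) -> dict:
    """JSON run configuration (frequencies, harmonics, fs, windows, ...)."""
    with open(path) as fh:
        return json.load(fh)
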