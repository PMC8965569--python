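"""Evaluation harness: leave-one-block-out CV, accuracy, ITR, t-tests.

Cross-validation holds out one recording block at a time: templates (and the
optimized common templates) are rebuilt from the remaining blocks, every
held-out trial is cut to the requested time window and classified, and
per-subject accuracies are aggregated over all folds. The Wolpaw information
transfer rate converts accuracy P over N classes at selection time T into

    ITR = (60 / T) * [log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1))]

bits per minute, with the P -> 1 limit handled exactly and accuracies at or
below chance clamped to zero (the raw formula rebounds below chance, which
is not meaningful throughput). T is the gaze window alone; gaze-shift time
is reported separately by users who need wall-clock command rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .recognition import METHODS, classify, fit
from .references import build_reference_set
from .signal_model import Dataset, extract_window
from .templates import build_bank

__all__ = [
    "EvalConfig",
    "EvalReport",
    "leave_one_block_out",
    "itr",
    "summarize",
    "confusion",
    "paired_ttest",
    "star_code",
]


@dataclass(frozen=True)
class EvalConfig:
    """Window sweep and cross-validation options."""

    window_lengths: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    methods: tuple[str, ...] = ("CCA", "ITCCA", "OCTCCA")
    onset_offset: float = 0.0
    include_target_subject: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        tws = tuple(float(t) for t in self.window_lengths)
        if len(tws) == 0 or any(t <= 0 for t in tws):
            raise ValueError("window_lengths must be positive")
        if list(tws) != sorted(tws):
            raise ValueError("window_lengths must be ascending")
        methods = tuple(m.upper() for m in self.methods)
        for m in methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        object.__setattr__(self, "window_lengths", tws)
        object.__setattr__(self, "methods", methods)


@dataclass
class EvalReport:
    """Tidy per-(method, subject, window) results plus confusions and t-tests.

    ``results`` columns: method, subject, window_s, n_trials, accuracy_pct,
    itr_bits_min. ``confusions`` maps (method, subject, window_s) to a K x K
    count matrix (rows = true class).
    """

    results: pd.DataFrame
    confusions: dict
    n_folds: int
    n_classes: int

    def summary(self) -> pd.DataFrame:
        """Mean and sample std of accuracy/ITR over subjects, per method+window."""
        rows = []
        for (method, tw), grp in self.results.groupby(["method", "window_s"]):
            acc_m, acc_s = summarize(grp["accuracy_pct"].tolist())
            itr_m, itr_s = summarize(grp["itr_bits_min"].tolist())
            rows.append(
                dict(
                    method=method,
                    window_s=tw,
                    accuracy_mean=acc_m,
                    accuracy_std=acc_s,
                    itr_mean=itr_m,
                    itr_std=itr_s,
                )
            )
        return pd.DataFrame(rows)

    def ttests(self) -> pd.DataFrame:
        """Paired t-tests over subjects for each method pair at each window."""
        rows = []
        methods = sorted(self.results["method"].unique())
        for tw in sorted(self.results["window_s"].unique()):
            sub = self.results[self.results["window_s"] == tw]
            pivot = sub.pivot(index="subject", columns="method", values="accuracy_pct")
            for i, ma in enumerate(methods):
                for mb in methods[i + 1 :]:
                    if len(pivot) < 2:
                        continue
                    t, p, stars = paired_ttest(pivot[ma].values, pivot[mb].values)
                    rows.append(
                        dict(method_a=ma, method_b=mb, window_s=tw, t=t, p=p, stars=stars)
                    )
        return pd.DataFrame(rows)


def itr(p: float, n_classes: int, t_select: float) -> float:
    """Wolpaw information transfer rate in bits/min (see module docstring)."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"accuracy fraction must be in [0, 1], got {p}")
    if t_select <= 0:
        raise ValueError(f"selection time must be positive, got {t_select}")
    if p <= 1.0 / n_classes:
        return 0.0
    if p >= 1.0:
        bits = np.log2(n_classes)
    else:
        bits = (
            np.log2(n_classes)
            + p * np.log2(p)
            + (1.0 - p) * np.log2((1.0 - p) / (n_classes - 1))
        )
    return float(60.0 / t_select * bits)


def summarize(values) -> tuple[float, float]:
    """(mean, sample std with n-1 denominator); a single value has std 0."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty list")
    if vals.size == 1:
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1))


def confusion(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size != p.size:
        raise ValueError(f"label lengths differ: {t.size} vs {p.size}")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (t, p), 1)
    return mat


def star_code(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def paired_ttest(a, b) -> tuple[float, float, str]:
    """Two-tailed paired t-test on the element-wise differences.

    Degenerate zero-variance differences: identical vectors give (0, 1, ns);
    a constant nonzero shift gives t = +/-inf, p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diffs = a - b
    if np.ptp(diffs) == 0:
        if diffs[0] == 0:
            return 0.0, 1.0, "ns"
        t = np.inf if diffs[0] > 0 else -np.inf
        return float(t), 0.0, "***"
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), star_code(float(p))


def _window_trial(epoch, onset: float, tw: float):
    return extract_window(epoch, onset, tw)


def leave_one_block_out(
    dataset: Dataset, config: EvalConfig, method: str | None = None
) -> EvalReport:
    """Leave-one-block-out accuracy/ITR sweep over window lengths.

    ``method`` restricts the run to one classifier; by default all of
    ``config.methods`` are evaluated (needed for the paired t-tests).
    """
    blocks = dataset.blocks
    if len(blocks) < 2:
        raise ValueError(f"leave-one-block-out needs >= 2 blocks, got {len(blocks)}")
    methods = (method.upper(),) if method is not None else config.methods
    stim = dataset.stimulus_config
    if stim is None:
        raise ValueError("dataset has no stimulus_config; cannot build references")
    targets = dataset.targets
    n_classes = len(targets)
    subjects = dataset.subjects
    if "OCTCCA" in methods and len(subjects) < 2:
        raise ValueError("OCT-CCA needs >= 2 subjects")

    # tallies[(method, subject, tw)] = (true list, predicted list)
    tallies: dict = {
        (m, s, tw): ([], [])
        for m in methods
        for s in subjects
        for tw in config.window_lengths
    }

    for held_out in blocks:
        training = [b for b in blocks if b != held_out]
        for tw in config.window_lengths:
            n_samples = int(round(tw * dataset.fs))
            refs = build_reference_set(stim, n_samples)
            windowed = dataset.map(
                lambda e: _window_trial(e, config.onset_offset, tw)
            )
            bank = build_bank(windowed, training)
            models = {}
            for m in methods:
                if m == "OCTCCA" and not config.include_target_subject:
                    models[m] = {
                        s: fit(m, bank.without_subject(s), refs) for s in subjects
                    }
                else:
                    models[m] = fit(m, bank if m != "CCA" else None, refs)
            for subject in subjects:
                for k_pos, target in enumerate(targets):
                    trial = _window_trial(
                        dataset.get(subject, held_out, target),
                        config.onset_offset,
                        tw,
                    )
                    for m in methods:
                        model = models[m]
                        if isinstance(model, dict):
                            model = model[subject]
                        sv = classify(model, trial, subject_id=subject)
                        true_list, pred_list = tallies[(m, subject, tw)]
                        true_list.append(k_pos)
                        pred_list.append(sv.predicted_index)

    rows, confusions = [], {}
    for (m, subject, tw), (true_list, pred_list) in tallies.items():
        mat = confusion(true_list, pred_list, n_classes)
        acc = float(np.trace(mat)) / mat.sum() * 100.0
        rows.append(
            dict(
                method=m,
                subject=subject,
                window_s=tw,
                n_trials=int(mat.sum()),
                accuracy_pct=acc,
                itr_bits_min=itr(acc / 100.0, n_classes, tw),
            )
        )
        confusions[(m, subject, tw)] = mat
    results = pd.DataFrame(rows).sort_values(
        ["method", "window_s", "subject"], ignore_index=True
    )
    return EvalReport(
        results=results,
        confusions=confusions,
        n_folds=len(blocks),
        n_classes=n_classes,
    )
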