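"""Individual templates and optimized common templates (OCT).

An individual template is a subject's trial-averaged SSVEP response for one
stimulus frequency — the data-driven reference used by IT-CCA. The optimized
common template pools N subjects: for each frequency it finds one channel-
weight vector omega_n per subject such that the projected single-channel
time courses omega_n' Xbar_n are maximally correlated across subjects. The
weights solve the joint symmetric generalized eigensystem

    sum_{n2} Sigma_{n1 n2} omega_{n2} = lambda Sigma_{n1 n1} omega_{n1},

assembled as B w = lambda D w on the stacked vector w = [omega_1; ...;
omega_N], where Sigma_{n1 n2} = Xbar_{n1} Xbar_{n2}' are cross-covariance
blocks of the centered templates, B contains all blocks (diagonal included)
and D is block-diagonal. The leading eigenvalue is bounded by N and attains
it exactly when the subjects' templates are linearly dependent. Only the
leading eigenvector is used by default, giving an optimized template with
one projected row per subject.

A single multiplier cannot satisfy all N unit-self-correlation constraints
at once (the classic MAXVAR relaxation), so each block omega_n is rescaled
after the solve to omega_n' Sigma_nn omega_n = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .cca import RIDGE_EPS, _fix_sign, _SINGULAR_RTOL
from .signal_model import Dataset, EEGEpoch

__all__ = [
    "SubjectTemplate",
    "TemplateBank",
    "OCTModel",
    "individual_template",
    "build_bank",
    "optimize_common_template",
    "build_oct_model",
]


@dataclass(frozen=True)
class SubjectTemplate:
    """Per-frequency trial-averaged templates (each N_c x N_p) for one subject."""

    subject_id: object
    templates: tuple[np.ndarray, ...]  # length K, each (N_c, N_p)
    n_trials_averaged: int

    def __post_init__(self) -> None:
        if len(self.templates) == 0:
            raise ValueError("need at least one per-frequency template")
        shape = self.templates[0].shape
        if any(t.shape != shape for t in self.templates):
            raise ValueError("all per-frequency templates must share one shape")
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")


@dataclass(frozen=True)
class TemplateBank:
    """Ordered subject templates sharing montage, length and frequency list."""

    subjects: tuple[SubjectTemplate, ...]
    stimulus_config: object = None

    def __post_init__(self) -> None:
        if len(self.subjects) == 0:
            raise ValueError("template bank needs at least one subject")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if len(s.templates) != len(ref.templates):
                raise ValueError("subjects disagree on the number of frequencies")
            if s.templates[0].shape != ref.templates[0].shape:
                raise ValueError("subjects disagree on template shape")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_frequencies(self) -> int:
        return len(self.subjects[0].templates)

    @property
    def template_shape(self) -> tuple[int, int]:
        return self.subjects[0].templates[0].shape

    def without_subject(self, subject_id) -> "TemplateBank":
        kept = tuple(s for s in self.subjects if s.subject_id != subject_id)
        if len(kept) == len(self.subjects):
            raise KeyError(f"subject {subject_id!r} not in bank")
        return TemplateBank(subjects=kept, stimulus_config=self.stimulus_config)


def individual_template(trials: list) -> np.ndarray:
    """Element-wise mean over same-shape trials (EEGEpoch or arrays)."""
    if len(trials) == 0:
        raise ValueError("cannot average an empty trial list")
    arrays = [np.asarray(getattr(t, "data", t), dtype=float) for t in trials]
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(f"trial {i} has shape {a.shape}, expected {shape}")
    return np.mean(arrays, axis=0)


def build_bank(dataset: Dataset, training_blocks: list[int]) -> TemplateBank:
    """Average the listed blocks' trials into per-subject, per-frequency templates.

    Templates are centered per channel, as the joint eigensystem assumes
    zero-mean signals.
    """
    training_blocks = list(training_blocks)
    if len(training_blocks) == 0:
        raise ValueError("need at least one training block")
    targets = dataset.targets
    subjects = []
    for subject in dataset.subjects:
        per_freq = []
        for k in targets:
            trials = []
            for b in training_blocks:
                trials.append(dataset.get(subject, b, k))  # raises naming the key
            avg = individual_template(trials)
            avg = avg - avg.mean(axis=1, keepdims=True)
            per_freq.append(avg)
        subjects.append(
            SubjectTemplate(
                subject_id=subject,
                templates=tuple(per_freq),
                n_trials_averaged=len(training_blocks),
            )
        )
    return TemplateBank(
        subjects=tuple(subjects), stimulus_config=dataset.stimulus_config
    )


def _solve_joint_gev(
    tmpls: list[np.ndarray], n_components: int = 1
) -> tuple[list[list[np.ndarray]], float]:
    """Top eigenvectors of B w = lambda D w, split and rescaled per block.

    Returns one list of per-subject blocks per retained component plus the
    leading eigenvalue.
    """
    N = len(tmpls)
    n_c = tmpls[0].shape[0]
    dim = N * n_c
    B = np.empty((dim, dim))
    D = np.zeros((dim, dim))
    diag_blocks = []
    for i in range(N):
        for j in range(N):
            B[i * n_c : (i + 1) * n_c, j * n_c : (j + 1) * n_c] = tmpls[i] @ tmpls[j].T
    for i in range(N):
        blk = B[i * n_c : (i + 1) * n_c, i * n_c : (i + 1) * n_c].copy()
        mean_eig = np.trace(blk) / n_c
        if mean_eig <= 0 or linalg.eigvalsh(blk)[0] <= _SINGULAR_RTOL * max(mean_eig, 1):
            warnings.warn(
                f"self-covariance of subject block {i} is near-singular; ridging"
            )
            blk = blk + RIDGE_EPS * max(mean_eig, 1.0) * np.eye(n_c)
        diag_blocks.append(blk)
        D[i * n_c : (i + 1) * n_c, i * n_c : (i + 1) * n_c] = blk
    B = (B + B.T) / 2

    eigvals, eigvecs = linalg.eigh(B, D)
    lam1 = float(eigvals[-1])

    per_component = []
    for c in range(n_components):
        w = eigvecs[:, -1 - c]
        omegas = []
        for i in range(N):
            wi = w[i * n_c : (i + 1) * n_c].copy()
            norm = wi @ diag_blocks[i] @ wi
            if norm <= 0:
                warnings.warn(f"degenerate projection for subject block {i}")
                wi = np.ones(n_c) / np.sqrt(n_c)
                norm = wi @ diag_blocks[i] @ wi
            wi = wi / np.sqrt(norm)
            omegas.append(_fix_sign(wi))
        per_component.append(omegas)
    return per_component, lam1


def optimize_common_template(
    bank: TemplateBank, freq_index: int, n_components: int = 1
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Projection vectors omega_n, optimized template X_hat, lambda_1.

    Each omega_n satisfies the unit self-correlation constraint
    omega_n' Sigma_nn omega_n = 1, and row n of the returned template is
    omega_n' Xbar_n. By default only the leading eigenvector is retained,
    giving an N x N_p template; ``n_components > 1`` stacks further
    eigenvectors' projections below it (component-major, N rows each).
    """
    if bank.n_subjects < 2:
        raise ValueError("OCT undefined for a single subject (need N >= 2)")
    if not (1 <= n_components <= bank.n_subjects * bank.template_shape[0]):
        raise ValueError(f"n_components={n_components} out of range")
    tmpls = []
    for s in bank.subjects:
        t = np.asarray(s.templates[freq_index], dtype=float)
        tmpls.append(t - t.mean(axis=1, keepdims=True))
    per_component, lam1 = _solve_joint_gev(tmpls, n_components)
    xhat = np.vstack(
        [w @ t for omegas in per_component for w, t in zip(omegas, tmpls)]
    )
    return per_component[0], xhat, lam1


@dataclass(frozen=True)
class OCTModel:
    """Per-frequency OCT solution: omegas (K x N x N_c), templates, eigenvalues."""

    omegas: tuple[tuple[np.ndarray, ...], ...]  # [k][n] -> (N_c,)
    xhat: tuple[np.ndarray, ...]  # [k] -> (N, N_p)
    lambdas: tuple[float, ...]  # leading eigenvalue per frequency
    bank: TemplateBank = None

    @property
    def n_frequencies(self) -> int:
        return len(self.xhat)

    @property
    def n_subjects(self) -> int:
        return self.xhat[0].shape[0]


def build_oct_model(bank: TemplateBank, n_components: int = 1) -> OCTModel:
    """Solve the joint eigensystem at every stimulus frequency."""
    omegas, xhats, lams = [], [], []
    for k in range(bank.n_frequencies):
        w, xh, lam = optimize_common_template(bank, k, n_components)
        omegas.append(tuple(w))
        xhats.append(xh)
        lams.append(lam)
    return OCTModel(
        omegas=tuple(omegas), xhat=tuple(xhats), lambdas=tuple(lams), bank=bank
    )
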