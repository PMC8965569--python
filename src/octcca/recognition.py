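"""SSVEP classifiers: standard CCA, IT-CCA and OCT-CCA.

All three score a test window X against each candidate stimulus frequency
and pick the argmax:

* CCA      — largest canonical correlation between X and the sine-cosine
             reference Y_k.
* IT-CCA   — largest canonical correlation between X and the test subject's
             own trial-averaged template M_k.
* OCT-CCA  — an ensemble of three correlations per frequency, combined with
             the signed-square rule rho_k = sum_i sign(rho_i) * rho_i**2:
               rho_1: Pearson correlation between the test signal projected
                      by its online spatial filter v_k (from CCA(X, X_hat_k))
                      and the optimized template projected by the precomputed
                      filter u_k (from CCA(X_hat_k, Y_k));
               rho_2: max canonical correlation CCA(X, X_hat_k);
               rho_3: max canonical correlation CCA(X, Y_k).

sign(r)*r**2 is strictly increasing on [-1, 1], so the combination preserves
each component's ordering while weighting confident correlations more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cca import cca, max_canonical_corr, pearson
from .references import ReferenceSet
from .templates import OCTModel, TemplateBank, build_oct_model

__all__ = [
    "RecognitionModel",
    "ScoreVector",
    "fit",
    "score",
    "classify_cca",
    "classify_itcca",
    "signed_square_combine",
]

METHODS = ("CCA", "ITCCA", "OCTCCA")


@dataclass(frozen=True)
class ScoreVector:
    """Per-frequency scores, optional (rho1, rho2, rho3) components, argmax."""

    scores: np.ndarray  # (K,)
    predicted_index: int
    components: np.ndarray | None = None  # (K, 3) for OCT-CCA


@dataclass(frozen=True)
class RecognitionModel:
    """Fitted state for one method (references, templates, spatial filters)."""

    method: str
    reference_set: ReferenceSet
    oct_model: OCTModel | None = None
    subject_templates: dict | None = None  # subject_id -> tuple of M_k
    filters_u: tuple[np.ndarray, ...] | None = None  # [k] -> (N, n_comp)
    template_proj: tuple[np.ndarray, ...] | None = None  # [k] -> (n_comp, N_p) U_k' X_hat_k


def signed_square_combine(components) -> float:
    """rho = sum_i sign(rho_i) * rho_i**2 over the component correlations."""
    comps = np.asarray(components, dtype=float)
    return float(np.sum(np.sign(comps) * comps**2))


def fit(
    method: str,
    bank: TemplateBank | None,
    refs: ReferenceSet,
    oct_components: int = 1,
) -> RecognitionModel:
    """Build a recognition model; ``bank`` may be None for plain CCA.

    ``oct_components`` optionally retains further joint eigenvectors in the
    optimized templates (off by default).
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    if method == "CCA":
        return RecognitionModel(method=method, reference_set=refs)

    if bank is None:
        raise ValueError(f"{method} requires a template bank")
    n_p = bank.template_shape[1]
    if refs.n_samples != n_p:
        raise ValueError(
            f"reference length {refs.n_samples} != template length {n_p}"
        )

    if method == "ITCCA":
        per_subject = {
            s.subject_id: tuple(s.templates) for s in bank.subjects
        }
        return RecognitionModel(
            method=method, reference_set=refs, subject_templates=per_subject
        )

    # OCT-CCA: joint eigensystem, then per-frequency spatial filter U_k from
    # CCA between the optimized template and the harmonic reference.
    oct_model = build_oct_model(bank, oct_components)
    filters, projections = [], []
    for k in range(oct_model.n_frequencies):
        res = cca(oct_model.xhat[k], refs[k])
        filters.append(res.weights_a)
        projections.append(res.weights_a.T @ oct_model.xhat[k])
    return RecognitionModel(
        method=method,
        reference_set=refs,
        oct_model=oct_model,
        filters_u=tuple(filters),
        template_proj=tuple(projections),
    )


def _signal_matrix(X) -> np.ndarray:
    arr = np.asarray(getattr(X, "data", X), dtype=float)
    return arr - arr.mean(axis=1, keepdims=True)


def score(model: RecognitionModel, X, n_pairs: int = 1) -> ScoreVector:
    """Score a test window with an OCT-CCA model (ensemble feature + argmax).

    ``n_pairs`` optionally pools the template-projection correlation over
    that many canonical pairs (sum of signed-squared PCCs); the default
    single leading pair is the validated form.
    """
    if model.method != "OCTCCA":
        raise ValueError(f"score() expects an OCT-CCA model, got {model.method}")
    sig = _signal_matrix(X)
    refs = model.reference_set
    if sig.shape[1] != refs.n_samples:
        raise ValueError(
            f"test window has {sig.shape[1]} samples but the model was fitted "
            f"for {refs.n_samples}"
        )
    K = len(refs)
    comps = np.empty((K, 3))
    scores = np.empty(K)
    for k in range(K):
        xhat_k = model.oct_model.xhat[k]
        n_avail = min(n_pairs, model.template_proj[k].shape[0], sig.shape[0])
        res = cca(sig, xhat_k, n_comp=n_avail)
        rho2 = float(res.correlations[0])
        # u_k and v_k come from two independent eigensolves, so their signs
        # are mutually arbitrary; anchor each precomputed template projection
        # u_k' X_hat to the matching online canonical direction of X_hat
        # (weights_b), which pairs positively with v_k' X by construction.
        # Genuine anti-correlation at wrong frequencies survives.
        pcc_term = 0.0
        rho1 = 0.0
        for j in range(n_avail):
            proj = model.template_proj[k][j]
            anchor = res.weights_b[:, j] @ xhat_k
            if np.dot(proj - proj.mean(), anchor - anchor.mean()) < 0:
                proj = -proj
            p_j = pearson(res.weights_a[:, j] @ sig, proj)
            if j == 0:
                rho1 = p_j
            pcc_term += np.sign(p_j) * p_j**2
        rho3 = max_canonical_corr(sig, refs[k])
        comps[k] = (rho1, rho2, rho3)
        scores[k] = pcc_term + np.sign(rho2) * rho2**2 + np.sign(rho3) * rho3**2
    return ScoreVector(
        scores=scores, predicted_index=int(np.argmax(scores)), components=comps
    )


def classify_cca(X, refs: ReferenceSet) -> ScoreVector:
    """Training-free baseline: max canonical correlation against each Y_k."""
    sig = _signal_matrix(X)
    if sig.shape[1] != refs.n_samples:
        raise ValueError(
            f"test window has {sig.shape[1]} samples, references have "
            f"{refs.n_samples}"
        )
    scores = np.array([max_canonical_corr(sig, refs[k]) for k in range(len(refs))])
    return ScoreVector(scores=scores, predicted_index=int(np.argmax(scores)))


def classify_itcca(X, model: RecognitionModel, subject_id=None) -> ScoreVector:
    """Individual-template baseline: CCA against the subject's own M_k."""
    if model.method != "ITCCA":
        raise ValueError(f"classify_itcca() expects an IT-CCA model, got {model.method}")
    if subject_id is None:
        subject_id = getattr(X, "subject_id", None)
    if subject_id not in model.subject_templates:
        raise KeyError(
            f"subject {subject_id!r} has no templates in this model "
            f"(have {sorted(model.subject_templates)})"
        )
    sig = _signal_matrix(X)
    templates = model.subject_templates[subject_id]
    if sig.shape[1] != templates[0].shape[1]:
        raise ValueError(
            f"test window has {sig.shape[1]} samples, templates have "
            f"{templates[0].shape[1]}"
        )
    scores = np.array([max_canonical_corr(sig, m) for m in templates])
    return ScoreVector(scores=scores, predicted_index=int(np.argmax(scores)))


def classify(model: RecognitionModel, X, subject_id=None) -> ScoreVector:
    """Dispatch to the model's method."""
    if model.method == "CCA":
        return classify_cca(X, model.reference_set)
    if model.method == "ITCCA":
        return classify_itcca(X, model, subject_id=subject_id)
    return score(model, X)
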