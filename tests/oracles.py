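"""Independent reference computations used to validate the implementation."""

import numpy as np


def cca_whitening_svd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Canonical correlations by whitening both sets and taking singular values.

    Independent of the generalized-eigenvalue route: center, whiten each set
    with the inverse square root of its covariance, then the singular values
    of the whitened cross-covariance are the canonical correlations.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)

    def inv_sqrt(c):
        vals, vecs = np.linalg.eigh(c)
        return vecs @ np.diag(vals**-0.5) @ vecs.T

    wa = inv_sqrt(a @ a.T)
    wb = inv_sqrt(b @ b.T)
    k = wa @ (a @ b.T) @ wb
    s = np.linalg.svd(k, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def confusion_tally(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Brute-force confusion count by explicit iteration."""
    mat = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        mat[int(t), int(p)] += 1
    return mat


def paired_t_closed_form(a, b):
    """Paired t statistic and two-tailed p from the t CDF, written directly."""
    from scipy.special import betainc

    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    df = n - 1
    # two-tailed p via the regularized incomplete beta function
    x = df / (df + t**2)
    p = betainc(df / 2.0, 0.5, x)
    return t, p
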