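"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def standardize_columns(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Return a column-wise z-scored copy of ``X``.

    Columns with zero variance are centered but left unscaled so downstream
    products stay finite.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd


def column_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between paired columns of two n x d arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    num = (az * bz).sum(axis=0)
    den = np.sqrt((az ** 2).sum(axis=0) * (bz ** 2).sum(axis=0))
    out = np.zeros(a.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def abs_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Sign-invariant cosine similarity of two vectors (0 if either is null)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(abs(a @ b) / (na * nb))


def fix_sign(w: np.ndarray) -> np.ndarray:
    """Flip a vector so its largest-magnitude entry is positive (idempotent)."""
    w = np.asarray(w, dtype=float)
    i = int(np.argmax(np.abs(w)))
    if w[i] < 0:
        return -w
    return w
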