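"""Sparse canonical correlation analysis via penalized matrix decomposition.

Given two column-standardized blocks ``X`` (n x k) and ``Y`` (n x q), each
component seeks unit-l2 loading vectors ``u`` and ``v`` maximizing the
cross-block covariance ``u' X'Y v`` subject to l1 bounds on both vectors.
The l1/l2 combination acts as an elastic net on the loadings and yields
sparse, interpretable canonical variates.  The solver is the classic
alternating soft-thresholded power iteration on the cross-covariance
matrix, with rank-one deflation of the cross-covariance between components.

A penalty value ``c`` on the [0, 1] grid maps to the l1 bound
``max(1, c * sqrt(dim))``; at ``c = 1`` the bound is inactive (the solution
is dense), at the low end the loading collapses to a single coordinate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import column_pearson, fix_sign, standardize_columns

GRID = np.round(np.arange(0.0, 1.01, 0.1), 10)

__all__ = [
    "PenaltyPair",
    "SCCAModel",
    "VariateScores",
    "scca_fit",
    "scca_project",
    "covariance_explained",
    "classical_cca",
    "l1_bound",
]


@dataclass(frozen=True)
class PenaltyPair:
    """A point on the sparsity grid: brain-side and behavior-side penalties.

    ``c_behavior`` is constrained to exceed 0.5 so the behavioral loadings
    keep enough support to be interpretable across the eight syndrome scales.
    """

    c_brain: float
    c_behavior: float

    def __post_init__(self) -> None:
        for name, val in (("c_brain", self.c_brain), ("c_behavior", self.c_behavior)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
            if not np.any(np.isclose(val, GRID, atol=1e-9)):
                raise ValueError(f"{name}={val} is not on the 0.1-step grid")
        if self.c_behavior <= 0.5:
            raise ValueError(
                f"c_behavior={self.c_behavior} must be larger than 0.5"
            )


def l1_bound(c: float, dim: int) -> float:
    """Map a grid penalty to the l1 bound on a unit-l2 loading of length ``dim``.

    Bounds below 1 are infeasible for a unit vector, so they are clamped to 1
    (maximal sparsity) to keep the whole printed grid usable.
    """
    return max(1.0, float(c) * np.sqrt(dim))


def _soft(a: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _unit_l1_project(a: np.ndarray, s: float, tol: float = 1e-10) -> np.ndarray:
    """Soft-threshold ``a`` and l2-normalize so the l1 norm is at most ``s``.

    The threshold delta solving ``||S(a, delta)||_1 / ||S(a, delta)||_2 = s``
    is found exactly: on each interval between consecutive sorted magnitudes
    the ratio is a smooth function of delta and the equation reduces to a
    quadratic.  Returns the zero vector if ``a`` is zero.
    """
    a = np.asarray(a, dtype=float)
    nrm = math.sqrt(a @ a)
    if nrm == 0:
        return np.zeros_like(a)
    u = a / nrm
    if np.abs(u).sum() <= s + tol:
        return u
    absa = np.sort(np.abs(a))[::-1]
    m = absa.size
    csum = np.cumsum(absa)  # csum[k-1]: sum of the top k magnitudes
    qsum = np.cumsum(absa * absa)
    s2 = s * s
    delta = None
    for k in range(m, 0, -1):
        i = k - 1
        lo = absa[k] if k < m else 0.0
        hi = absa[i]
        if hi - lo <= 0:
            continue  # tied magnitudes: empty segment
        c, q = csum[i], qsum[i]
        alpha = k * (k - s2)
        beta = 2.0 * c * (s2 - k)
        gamma = c * c - s2 * q
        if abs(alpha) < 1e-14:
            cands = [lo] if abs(beta) < 1e-14 else [-gamma / beta]
        else:
            disc = beta * beta - 4.0 * alpha * gamma
            if disc < 0:
                continue
            r = math.sqrt(disc)
            cands = [(-beta - r) / (2.0 * alpha), (-beta + r) / (2.0 * alpha)]
        eps = 1e-12 * max(1.0, hi)
        for cand in cands:
            if lo - eps <= cand < hi:
                delta = min(max(cand, lo), hi)
                break
        if delta is not None:
            break
    if delta is None:
        # s is below the attainable ratio (ties at the maximum); keep the tied top
        k_min = int(np.sum(absa >= absa[0] - 1e-12))
        delta = absa[k_min] if k_min < m else 0.0
    su = _soft(a, delta)
    su[np.abs(su) < 1e-12 * absa[0]] = 0.0  # snap fp residue at the threshold
    n = math.sqrt(su @ su)
    if n == 0:
        return np.zeros_like(a)
    return su / n


@dataclass
class SCCAModel:
    """Fitted sparse CCA loadings and training canonical correlations."""

    u: np.ndarray  # (k_pc, d) brain-side loadings, unit l2 columns
    v: np.ndarray  # (q, d) behavior-side loadings, unit l2 columns
    penalties: PenaltyPair
    train_correlations: np.ndarray  # (d,)
    n_components: int
    converged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def to_dict(self) -> dict:
        return {
            "format": "holdoutcca-scca-model",
            "version": 1,
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "penalties": [self.penalties.c_brain, self.penalties.c_behavior],
            "train_correlations": self.train_correlations.tolist(),
            "n_components": int(self.n_components),
            "converged": self.converged.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SCCAModel":
        if d.get("format") != "holdoutcca-scca-model":
            raise ValueError("not a serialized SCCA model")
        return cls(
            u=np.asarray(d["u"], dtype=float),
            v=np.asarray(d["v"], dtype=float),
            penalties=PenaltyPair(*d["penalties"]),
            train_correlations=np.asarray(d["train_correlations"], dtype=float),
            n_components=int(d["n_components"]),
            converged=np.asarray(d["converged"], dtype=bool),
        )


@dataclass
class VariateScores:
    """Canonical variate scores (Xu, Yv) and their per-component correlations."""

    brain_scores: np.ndarray  # (n, d)
    behavior_scores: np.ndarray  # (n, d)
    correlations: np.ndarray  # (d,)


def scca_fit(
    X: np.ndarray,
    Y: np.ndarray,
    penalties: PenaltyPair,
    d: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    standardize: bool = True,
) -> SCCAModel:
    """Fit ``d`` sparse canonical components to blocks ``X`` (n x k) and ``Y`` (n x q).

    Both blocks are column-standardized internally (covariance maximization is
    scale-sensitive and the two views live in different units).  Components are
    extracted sequentially with rank-one deflation of the cross-covariance, and
    each returned loading column is sign-fixed so its largest-magnitude entry
    is positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    n, k = X.shape
    q = Y.shape[1]
    if d is None:
        d = min(k, q)
    if d > min(k, q):
        raise ValueError(f"d={d} exceeds min(k, q)={min(k, q)}")
    if standardize:
        X = standardize_columns(X)
        Y = standardize_columns(Y)

    s_u = l1_bound(penalties.c_brain, k)
    s_v = l1_bound(penalties.c_behavior, q)

    C = X.T @ Y
    U = np.zeros((k, d))
    V = np.zeros((q, d))
    converged = np.zeros(d, dtype=bool)
    for comp in range(d):
        # warm start from the leading singular pair of the deflated cross-covariance
        left, _, right = np.linalg.svd(C, full_matrices=False)
        u, v = left[:, 0], right[0, :]
        for _ in range(max_iter):
            u_new = _unit_l1_project(C @ v, s_u)
            v_new = _unit_l1_project(C.T @ u_new, s_v)
            delta = max(
                np.abs(u_new - u).max(initial=0.0),
                np.abs(v_new - v).max(initial=0.0),
            )
            u, v = u_new, v_new
            if delta < tol:
                converged[comp] = True
                break
        if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
            raise ValueError(
                f"component {comp + 1}: loading fully thresholded to zero; "
                "increase the penalty value (less sparsity)"
            )
        if not converged[comp]:
            warnings.warn(
                f"SCCA component {comp + 1} did not converge in {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        C = C - (u @ C @ v) * np.outer(u, v)
        U[:, comp] = fix_sign(u)
        V[:, comp] = fix_sign(v)

    corr = column_pearson(X @ U, Y @ V)
    return SCCAModel(
        u=U,
        v=V,
        penalties=penalties,
        train_correlations=corr,
        n_components=d,
        converged=converged,
    )


def scca_project(model: SCCAModel, X_new: np.ndarray, Y_new: np.ndarray) -> VariateScores:
    """Project new blocks onto fitted loadings; no re-fitting.

    The new blocks are standardized with their own internal statistics,
    mirroring the per-set residualization stance of the hold-out framework.
    """
    X_new = np.asarray(X_new, dtype=float)
    Y_new = np.asarray(Y_new, dtype=float)
    if X_new.shape[1] != model.u.shape[0]:
        raise ValueError(
            f"X has {X_new.shape[1]} columns but model expects {model.u.shape[0]}"
        )
    if Y_new.shape[1] != model.v.shape[0]:
        raise ValueError(
            f"Y has {Y_new.shape[1]} columns but model expects {model.v.shape[0]}"
        )
    Xs = standardize_columns(X_new)
    Ys = standardize_columns(Y_new)
    bs = Xs @ model.u
    ys = Ys @ model.v
    return VariateScores(
        brain_scores=bs,
        behavior_scores=ys,
        correlations=column_pearson(bs, ys),
    )


def covariance_explained(scores: VariateScores) -> tuple[np.ndarray, np.ndarray]:
    """Share of total absolute cross-block covariance carried by each component.

    Returns ``(shares, gate)`` where ``gate[j]`` marks components whose share
    strictly exceeds the mean share — the rule used to pick which canonical
    variates enter permutation testing.
    """
    d = scores.brain_scores.shape[1]
    covs = np.array(
        [
            abs(np.cov(scores.brain_scores[:, j], scores.behavior_scores[:, j])[0, 1])
            for j in range(d)
        ]
    )
    total = covs.sum()
    if total == 0:
        warnings.warn("all cross-block covariances are zero; uniform shares", RuntimeWarning)
        shares = np.full(d, 1.0 / d)
    else:
        shares = covs / total
    gate = shares > shares.mean()
    return shares, gate


def classical_cca(
    X: np.ndarray, Y: np.ndarray, d: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpenalized canonical correlation analysis (generalized eigenproblem).

    Solves ``Sxy Syy^-1 Syx a = rho^2 Sxx a`` for the brain-side loadings and
    recovers the behavior side by regression.  Used for the no-sparsity
    sensitivity arm; requires full-rank within-view covariances.
    """
    X = standardize_columns(np.asarray(X, dtype=float))
    Y = standardize_columns(np.asarray(Y, dtype=float))
    n, k = X.shape
    q = Y.shape[1]
    if d is None:
        d = min(k, q)
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    from scipy import linalg

    for name, S in (("X", Sxx), ("Y", Syy)):
        if np.linalg.cond(S) > 1e10:
            raise ValueError(
                f"within-view covariance of {name} is singular or near-singular; "
                "reduce dimensionality (e.g. with PCA) first"
            )
    M = Sxy @ linalg.solve(Syy, Sxy.T, assume_a="pos")
    evals, evecs = linalg.eigh(M, Sxx)
    order = np.argsort(evals)[::-1][:d]
    rho = np.sqrt(np.clip(evals[order], 0.0, 1.0))
    A = evecs[:, order]
    B = linalg.solve(Syy, Sxy.T @ A, assume_a="pos")
    # normalize so variate scores have unit variance; sign-fix per column
    for j in range(d):
        sa = np.sqrt(A[:, j] @ Sxx @ A[:, j])
        sb = np.sqrt(B[:, j] @ Syy @ B[:, j])
        if sa > 0:
            A[:, j] /= sa
        if sb > 0:
            B[:, j] /= sb
        A[:, j] = fix_sign(A[:, j])
        B[:, j] = fix_sign(B[:, j])
    return A, B, rho
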