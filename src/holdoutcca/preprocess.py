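"""Covariate residualization, rank-based weighting, and weighted PCA.

All estimators here follow a strict fit/transform separation: parameters are
estimated on a training set only and applied unchanged to held-out data, so
no information can leak from test sites into the fitted model.

The weighting scheme up-weights subjects with more psychiatric symptoms when
building the principal-component basis, so that the retained components carry
variance relevant to the behavioral phenotype rather than only the dominant
(largely motion- and site-driven) connectivity variance.  With subjects ranked
by total symptom score (rank 1 = most symptoms), the pre-weight of subject i is

    w~_i = ln n - ln r_i

which is 0 for the lowest-ranked subject and ln n for the top; pre-weights are
normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankWeights",
    "rank_weights",
    "Residualizer",
    "residualize_fit_transform",
    "WeightedPCAModel",
    "weighted_pca_fit",
    "weighted_pca_transform",
]


@dataclass
class RankWeights:
    ranks: np.ndarray  # fractional ranks, 1 = highest total score
    preweights: np.ndarray  # ln n - ln r_i
    weights: np.ndarray  # normalized, sum 1

    def to_dict(self) -> dict:
        return {
            "format": "holdoutcca-rank-weights",
            "version": 1,
            "ranks": self.ranks.tolist(),
            "preweights": self.preweights.tolist(),
            "weights": self.weights.tolist(),
        }


def rank_weights(total_scores: np.ndarray, highest_first: bool = True) -> RankWeights:
    """Log-rank weights from total symptom scores.

    Ties receive average fractional ranks (deterministic and invariant to the
    input order).  ``highest_first=True`` gives rank 1 to the largest score,
    emphasizing high-symptom subjects; the flag flips the direction.
    """
    scores = np.asarray(total_scores, dtype=float).ravel()
    n = scores.size
    if n < 2:
        raise ValueError("at least 2 subjects are required for rank weighting")
    if np.any(scores < 0):
        raise ValueError("total scores must be non-negative")
    ranks = stats.rankdata(-scores if highest_first else scores, method="average")
    preweights = np.log(n) - np.log(ranks)
    total = preweights.sum()
    if total <= 0:  # only possible when all ranks equal n, i.e. n == 1
        raise ValueError("degenerate pre-weights; need n >= 2")
    return RankWeights(ranks=ranks, preweights=preweights, weights=preweights / total)


class Residualizer:
    """Per-feature OLS removal of covariate effects (intercept + dummy coding).

    Fit on exactly one dataset; ``transform`` refuses covariate category
    levels unseen at fit time, since the dummy design would silently
    misalign otherwise.
    """

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None
        self.design_columns_: list[str] | None = None
        self.categories_: dict[str, list] | None = None

    def _design(self, covariates: pd.DataFrame) -> pd.DataFrame:
        cov = covariates.copy()
        if self.categories_ is not None:
            for col, levels in self.categories_.items():
                unseen = set(cov[col].dropna().unique()) - set(levels)
                if unseen:
                    raise ValueError(
                        f"covariate '{col}' has levels unseen at fit: {sorted(map(str, unseen))}"
                    )
                cov[col] = pd.Categorical(cov[col], categories=levels)
        else:
            self.categories_ = {
                col: sorted(cov[col].dropna().unique().tolist())
                for col in cov.columns
                if not pd.api.types.is_numeric_dtype(cov[col])
            }
            for col, levels in self.categories_.items():
                cov[col] = pd.Categorical(cov[col], categories=levels)
        D = pd.get_dummies(cov, drop_first=True, dtype=float)
        D.insert(0, "_intercept", 1.0)
        return D

    def fit(self, covariates: pd.DataFrame, features: np.ndarray) -> "Residualizer":
        D = self._design(covariates)
        X = D.to_numpy(dtype=float)
        n, c = X.shape
        if features.shape[0] != n:
            raise ValueError("features and covariates must have matching rows")
        if n <= c:
            raise ValueError(f"n={n} must exceed the {c} encoded design columns")
        rank = np.linalg.matrix_rank(X)
        if rank < c:
            # locate aliased columns by greedy QR-style elimination
            aliased = []
            kept: list[int] = []
            for j in range(c):
                trial = X[:, kept + [j]]
                if np.linalg.matrix_rank(trial) > len(kept):
                    kept.append(j)
                else:
                    aliased.append(D.columns[j])
            raise ValueError(f"rank-deficient covariate design; aliased columns: {aliased}")
        self.design_columns_ = D.columns.tolist()
        coef, *_ = np.linalg.lstsq(X, np.asarray(features, dtype=float), rcond=None)
        self.coef_ = coef
        self._fit_design = X
        return self

    def fit_transform(self, covariates: pd.DataFrame, features: np.ndarray) -> np.ndarray:
        self.fit(covariates, features)
        return np.asarray(features, dtype=float) - self._fit_design @ self.coef_

    def transform(self, covariates: pd.DataFrame, features: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise ValueError("Residualizer is not fitted")
        D = self._design(covariates)
        if D.columns.tolist() != self.design_columns_:
            raise ValueError("covariate design columns differ from fit")
        return np.asarray(features, dtype=float) - D.to_numpy(dtype=float) @ self.coef_

    def to_dict(self) -> dict:
        return {
            "format": "holdoutcca-residualizer",
            "version": 1,
            "design_columns": self.design_columns_,
            "coef": None if self.coef_ is None else self.coef_.tolist(),
        }


def residualize_fit_transform(
    features: np.ndarray, covariates: pd.DataFrame
) -> tuple[Residualizer, np.ndarray]:
    """Fit a residualizer on one set and return (model, residual matrix)."""
    model = Residualizer()
    residuals = model.fit_transform(covariates, features)
    return model, residuals


@dataclass
class WeightedPCAModel:
    """Eigenvectors of the weight-adjusted connectivity matrix.

    ``components`` columns are unit-norm variable loadings; held-out data are
    projected by plain matrix multiplication without re-centering (residuals
    are near-zero-mean by construction).
    """

    feature_means: np.ndarray  # (p,)
    components: np.ndarray  # (p, k), orthonormal columns
    explained_share: np.ndarray  # (k,), non-increasing
    k: int

    def transform(self, residuals_new: np.ndarray) -> np.ndarray:
        return weighted_pca_transform(self, residuals_new)

    def to_dict(self) -> dict:
        return {
            "format": "holdoutcca-weighted-pca",
            "version": 1,
            "feature_means": self.feature_means.tolist(),
            "components": self.components.tolist(),
            "explained_share": self.explained_share.tolist(),
            "k": int(self.k),
        }


def weighted_pca_fit(
    residuals: np.ndarray,
    weights: RankWeights | np.ndarray,
    k: int,
    demean: str = "unweighted",
    row_scale: str = "w",
) -> WeightedPCAModel:
    """PCA of the demeaned, row-weighted residual matrix.

    Each subject's row is multiplied by its normalized weight (``row_scale="w"``,
    the literal reading of the weighting scheme; ``"sqrt_w"`` gives the
    weighted-covariance variant) before extracting eigenvectors.  Uniform
    weights reduce to standard PCA up to an overall scale.
    """
    X = np.asarray(residuals, dtype=float)
    w = weights.weights if isinstance(weights, RankWeights) else np.asarray(weights, float)
    n, p = X.shape
    if w.shape != (n,):
        raise ValueError("weights length must match number of rows")
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n, p)={min(n, p)}")
    if demean == "unweighted":
        means = X.mean(axis=0)
    elif demean == "weighted":
        means = (w / w.sum()) @ X
    else:
        raise ValueError("demean must be 'unweighted' or 'weighted'")
    M = X - means
    if row_scale == "w":
        M = M * w[:, None]
    elif row_scale == "sqrt_w":
        M = M * np.sqrt(w)[:, None]
    else:
        raise ValueError("row_scale must be 'w' or 'sqrt_w'")
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    var = s ** 2
    rank = int((s > s[0] * max(n, p) * np.finfo(float).eps).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the weighted matrix")
    total = var.sum()
    share = var[:k] / total if total > 0 else np.zeros(k)
    return WeightedPCAModel(
        feature_means=means,
        components=Vt[:k].T,
        explained_share=share,
        k=k,
    )


def weighted_pca_transform(model: WeightedPCAModel, residuals_new: np.ndarray) -> np.ndarray:
    """Project per-set residualized data onto training eigenvectors (no re-fit)."""
    X = np.asarray(residuals_new, dtype=float)
    if X.shape[1] != model.components.shape[0]:
        raise ValueError(
            f"expected {model.components.shape[0]} features, got {X.shape[1]}"
        )
    return X @ model.components
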