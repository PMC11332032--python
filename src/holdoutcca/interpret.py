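"""Post-hoc characterization of fitted brain-behavior dimensions.

Edge-level contributions are the Pearson correlations between raw
connectivity features and a brain canonical variate score; contributions are
aggregated into within/between network-module cells, z-scored, and the top
20% of edges by absolute contribution are flagged.  A covariate-adjusted
regression relates brain variate scores to external outcomes such as
cognitive ability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


__all__ = [
    "NetworkContributionTable",
    "OutcomeAssociation",
    "edge_contributions",
    "aggregate_modules",
    "outcome_regression",
]


@dataclass
class NetworkContributionTable:
    """Edge contributions and their network-module aggregation."""

    edge_contribution: np.ndarray  # (p,) correlation of each edge with the variate
    networks: list[str]  # module names, sorted
    module_matrix: np.ndarray  # (M, M) aggregated |contribution| (within on diagonal)
    module_z: np.ndarray  # (M, M) z-scored over the unique (upper-tri) cells
    top_mask: np.ndarray  # (p,) bool, top 20% of edges by |contribution|

    def module_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.module_matrix, index=self.networks, columns=self.networks)


@dataclass
class OutcomeAssociation:
    """Standardized regression coefficient of an outcome on a variate score."""

    standardized_beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def edge_contributions(raw_features: np.ndarray, brain_scores: np.ndarray) -> np.ndarray:
    """Correlation of each raw connectivity feature with the brain variate score.

    The score is typically the raw brain PCs multiplied by canonical loadings
    averaged over the hold-out repetitions.  Zero-variance features get a
    contribution of 0 with a warning.
    """
    X = np.asarray(raw_features, dtype=float)
    s = np.asarray(brain_scores, dtype=float).ravel()
    if X.shape[0] != s.shape[0]:
        raise ValueError("feature matrix and score vector row counts differ")
    Xc = X - X.mean(axis=0)
    sc = s - s.mean()
    den = np.sqrt((Xc ** 2).sum(axis=0) * (sc ** 2).sum())
    bad = den == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance feature(s); contribution set to 0",
            RuntimeWarning,
        )
    out = np.zeros(X.shape[1])
    np.divide(Xc.T @ sc, den, out=out, where=~bad)
    return out


def aggregate_modules(
    contributions: np.ndarray,
    edge_index: list[tuple[int, int]],
    parcel_to_network: dict[int, str] | pd.Series,
    top_fraction: float = 0.2,
    signed: bool = False,
) -> NetworkContributionTable:
    """Sum edge contributions into within/between network-module cells.

    Each edge (i, j) lands in exactly one cell of the M x M module matrix
    (within-network on the diagonal).  Absolute contributions are summed by
    default so opposing-sign edges do not cancel (``signed=True`` for raw
    sums).  z-scores are computed over the unique cells — the upper triangle
    including the diagonal — and ``top_mask`` marks the global top
    ``top_fraction`` of edges by absolute contribution (ceil(0.2 p) edges).
    """
    contributions = np.asarray(contributions, dtype=float)
    if isinstance(parcel_to_network, pd.Series):
        parcel_to_network = parcel_to_network.to_dict()
    if len(contributions) != len(edge_index):
        raise ValueError("contributions and edge_index lengths differ")
    parcels = {i for ij in edge_index for i in ij}
    unmapped = sorted(p for p in parcels if p not in parcel_to_network)
    if unmapped:
        raise ValueError(f"parcel(s) not assigned to any network: {unmapped}")
    networks = sorted(set(parcel_to_network[p] for p in parcels))
    pos = {name: m for m, name in enumerate(networks)}
    M = len(networks)
    module = np.zeros((M, M))
    vals = contributions if signed else np.abs(contributions)
    for val, (i, j) in zip(vals, edge_index):
        a, b = pos[parcel_to_network[i]], pos[parcel_to_network[j]]
        a, b = min(a, b), max(a, b)
        module[a, b] += val
    module = module + np.triu(module, k=1).T  # mirror for a symmetric table
    iu, ju = np.triu_indices(M)
    cells = module[iu, ju]
    mu, sd = cells.mean(), cells.std(ddof=0)
    z_cells = (cells - mu) / sd if sd > 0 else np.zeros_like(cells)
    module_z = np.zeros((M, M))
    module_z[iu, ju] = z_cells
    module_z[ju, iu] = z_cells
    p = len(contributions)
    n_top = int(np.ceil(top_fraction * p))
    order = np.argsort(-np.abs(contributions), kind="stable")
    top_mask = np.zeros(p, dtype=bool)
    top_mask[order[:n_top]] = True
    return NetworkContributionTable(
        edge_contribution=contributions,
        networks=networks,
        module_matrix=module,
        module_z=module_z,
        top_mask=top_mask,
    )


def outcome_regression(
    brain_scores: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> OutcomeAssociation:
    """OLS of a standardized outcome on the standardized brain variate score.

    Complete cases only (listwise deletion over score, outcome, and
    covariates).  Categorical covariates are dummy-encoded; the reported beta
    is the coefficient of the score with its 95% confidence interval.
    """
    import statsmodels.api as sm

    s = np.asarray(brain_scores, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    if s.shape != y.shape:
        raise ValueError("score and outcome lengths differ")
    keep = np.isfinite(s) & np.isfinite(y)
    if covariates is not None:
        D = pd.get_dummies(covariates.reset_index(drop=True), drop_first=True, dtype=float)
        keep &= D.notna().all(axis=1).to_numpy()
        D = D.loc[keep]
        D_arr = D.to_numpy(dtype=float)
    else:
        D_arr = np.empty((int(keep.sum()), 0))
    s, y = s[keep], y[keep]
    n = s.size
    if n <= D_arr.shape[1] + 2:
        raise ValueError("too few complete cases for the covariate design")
    s_std = (s - s.mean()) / s.std(ddof=1)
    y_std = (y - y.mean()) / y.std(ddof=1)
    X = sm.add_constant(np.column_stack([s_std, D_arr]))
    fit = sm.OLS(y_std, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return OutcomeAssociation(
        standardized_beta=float(fit.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        n=int(n),
    )
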