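"""From regional BOLD time series and phenotype tables to analysis-ready views.

Covers connectivity estimation (confound regression, pairwise Pearson
correlation, Fisher z), motion-based scan QC, and syndrome-scale scoring of a
113-item caregiver checklist with the standard proration rule for missing
items.  Voxel-level preprocessing is out of scope: the contract starts at a
regions x time matrix plus a confound matrix (which may include filtering
regressors and motion expansions supplied upstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalTimeSeries",
    "ConnectivityVector",
    "upper_triangle_index",
    "flatten_upper",
    "unflatten_upper",
    "connectivity_from_timeseries",
    "qc_filter",
    "syndrome_scores",
]

_R_CLIP = 1.0 - 1e-7  # keep atanh finite for numerically perfect correlations


@dataclass
class RegionalTimeSeries:
    """Averaged BOLD series per region plus nuisance regressors."""

    values: np.ndarray  # (T, R)
    confounds: np.ndarray  # (T, m)
    region_labels: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.confounds = np.asarray(self.confounds, dtype=float)
        T, R = self.values.shape
        if R < 2:
            raise ValueError("need at least 2 regions")
        if len(self.region_labels) != R:
            raise ValueError("region_labels length must match region count")
        if self.confounds.shape[0] != T:
            raise ValueError("confounds must align with time points")
        if T <= self.confounds.shape[1] + 2:
            raise ValueError("too few time points for confound regression")
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.confounds)):
            raise ValueError("non-finite values in time series or confounds")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class ConnectivityVector:
    """Strict-upper-triangle Fisher-z connectivity edges, row-major order."""

    values: np.ndarray  # (R*(R-1)/2,)
    edge_index: list[tuple[int, int]]


def upper_triangle_index(n_regions: int) -> list[tuple[int, int]]:
    """Row-major (i, j) pairs of the strict upper triangle, i < j."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def flatten_upper(matrix: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle of a square matrix, row-major."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju]


def unflatten_upper(values: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from flattened edges."""
    values = np.asarray(values, dtype=float)
    if n_regions is None:
        n_regions = int(round((1 + np.sqrt(1 + 8 * values.size)) / 2))
    if n_regions * (n_regions - 1) // 2 != values.size:
        raise ValueError("edge vector length is not a triangular number for n_regions")
    mat = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    mat[iu, ju] = values
    mat[ju, iu] = values
    return mat


def connectivity_from_timeseries(ts: RegionalTimeSeries) -> ConnectivityVector:
    """Confound-regress each regional series, correlate pairwise, Fisher-z.

    Each region is residualized on the confound matrix (plus intercept) by
    ordinary least squares; Pearson correlations of the residual series are
    z-transformed with ``atanh`` after clipping |r| at 1 - 1e-7, and the
    strict upper triangle is flattened row-major.
    """
    T, R = ts.values.shape
    D = np.column_stack([np.ones(T), ts.confounds])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("confound matrix is rank-deficient")
    coef, *_ = np.linalg.lstsq(D, ts.values, rcond=None)
    resid = ts.values - D @ coef
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant residual series for region(s): {bad}")
    r = np.corrcoef(resid, rowvar=False)
    flat = flatten_upper(r)
    flat = np.clip(flat, -_R_CLIP, _R_CLIP)
    return ConnectivityVector(
        values=np.arctanh(flat), edge_index=upper_triangle_index(R)
    )


def qc_filter(
    motion: pd.DataFrame,
    mean_fd_thresh: float = 0.25,
    frac_thresh: float = 0.20,
    min_frames: int | None = None,
    frames_col: str = "n_frames",
) -> pd.Series:
    """Boolean inclusion mask from per-subject motion summaries.

    A subject is excluded iff mean FD exceeds ``mean_fd_thresh`` (mm) or the
    fraction of volumes with FD above 0.2 mm exceeds ``frac_thresh`` — both
    strict inequalities, so subjects sitting exactly on a threshold are kept.
    Missing summaries exclude the subject with a logged warning.  The optional
    ``min_frames`` rule (frames remaining after censoring) is off by default.
    """
    if mean_fd_thresh <= 0 or frac_thresh <= 0:
        raise ValueError("thresholds must be positive")
    mean_fd = motion["mean_fd_mm"]
    frac = motion["frac_fd_above_02"]
    missing = mean_fd.isna() | frac.isna()
    if missing.any():
        logger.warning(
            "excluding %d subject(s) with missing motion summaries", int(missing.sum())
        )
    include = ~missing & ~(mean_fd > mean_fd_thresh) & ~(frac > frac_thresh)
    if min_frames is not None:
        include &= motion[frames_col].fillna(0) > min_frames
    return include.astype(bool)


def syndrome_scores(
    items: pd.DataFrame,
    scale_map: dict[str, str] | pd.Series,
    item_missing_thresh: float = 0.25,
    subject_missing_thresh: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Prorated syndrome sum scores from 3-point item responses.

    For each scale, if the fraction of missing items is below
    ``item_missing_thresh`` the score is the mean of answered items times the
    scale length (the prorated sum); otherwise the scale is flagged
    unavailable (NaN).  Returns ``(scores, available, exclude)`` where
    ``exclude`` flags subjects whose overall item missingness exceeds
    ``subject_missing_thresh``.
    """
    if isinstance(scale_map, pd.Series):
        scale_map = scale_map.to_dict()
    unknown = [c for c in scale_map if c not in items.columns]
    if unknown:
        raise ValueError(f"scale_map references unknown items: {unknown}")
    vals = items[list(scale_map)].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bad = ~np.isnan(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"item value {vals[i, j]} outside {{0, 1, 2}} "
            f"(subject row {i}, item {list(scale_map)[j]})"
        )
    scales = sorted(set(scale_map.values()))
    scores = pd.DataFrame(index=items.index, columns=scales, dtype=float)
    available = pd.DataFrame(True, index=items.index, columns=scales)
    for scale in scales:
        cols = [c for c, s in scale_map.items() if s == scale]
        block = items[cols].to_numpy(dtype=float)
        n_items = len(cols)
        n_missing = np.isnan(block).sum(axis=1)
        frac_missing = n_missing / n_items
        ok = frac_missing < item_missing_thresh
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prorated = np.nanmean(block, axis=1) * n_items
        scores[scale] = np.where(ok, prorated, np.nan)
        available[scale] = ok
    overall_missing = items[list(scale_map)].isna().to_numpy().mean(axis=1)
    exclude = pd.Series(overall_missing > subject_missing_thresh, index=items.index)
    return scores, available, exclude
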