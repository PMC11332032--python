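"""Cross-study external validity of sparse CCA models.

Two notions of external validity are implemented, and they can disagree:

* **Gold-standard generalizability** — the model fitted in the source cohort
  (PCA eigenvectors and canonical loadings) is projected, unchanged, onto the
  target cohort, and the resulting external canonical correlations are tested
  by permutation.  This is the transportable-biomarker criterion.

* **Qualitative replication** — the model is refitted independently in each
  cohort (own residualization, own weighted PCA) with shared penalties, and
  each cohort's data are scored both with its own loadings and with the other
  cohort's; a component is deemed generalizable only if the cross-projected
  and natively trained variate scores correlate significantly in *both*
  directions.  Because the behavior view is low-dimensional and its loading
  structure tends to be stable across cohorts, replication can succeed even
  when the brain-side loadings — and hence the gold-standard projection —
  do not transfer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import column_pearson, standardize_columns
from .preprocess import (
    rank_weights,
    residualize_fit_transform,
    weighted_pca_fit,
)
from .scca import PenaltyPair, scca_fit
from .synthdata import TwoViewCohort
from .validate import (
    HoldoutResult,
    PermutationResult,
    match_components,
    permutation_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneralizabilityResult",
    "ReplicationResult",
    "gold_standard_test",
    "qualitative_replication",
]


@dataclass
class GeneralizabilityResult:
    """External canonical correlations per source repetition, plus summary."""

    per_repetition: list[PermutationResult]
    mean_correlations: np.ndarray  # (d,)
    n_significant: np.ndarray  # (d,) count of repetitions with q < alpha
    alpha: float


def gold_standard_test(
    source: HoldoutResult,
    target: TwoViewCohort,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> GeneralizabilityResult:
    """Project every source-repetition model onto the target cohort.

    The target is residualized with its own covariates (the per-set
    residualization contract), pushed through each repetition's training
    eigenvectors to obtain target PCs, and scored with the training canonical
    loadings.  Significance per component uses project-mode permutations with
    the source repetition's covariance-explained gate.
    """
    if not source.repetitions:
        raise ValueError("source hold-out result contains no repetitions")
    target.validate()
    p_expected = source.repetitions[0].pca.components.shape[0]
    if target.brain.shape[1] != p_expected:
        raise ValueError(
            f"target has {target.brain.shape[1]} brain features, source models "
            f"expect {p_expected}"
        )
    _, R_target = residualize_fit_transform(target.brain, target.covariates)
    Y_target = target.symptoms
    root = np.random.SeedSequence(seed)
    results = []
    for rep, rep_ss in zip(source.repetitions, root.spawn(len(source.repetitions))):
        X_target = rep.pca.transform(R_target)
        results.append(
            permutation_test(
                X_target,
                Y_target,
                rep.model,
                mode="project",
                B=B,
                seed=np.random.default_rng(rep_ss),
                components=rep.gate,
            )
        )
    obs = np.array([r.observed for r in results])
    q = np.array([r.q_values for r in results])
    with np.errstate(invalid="ignore"):
        n_sig = np.nansum(q < alpha, axis=0).astype(int)
    return GeneralizabilityResult(
        per_repetition=results,
        mean_correlations=obs.mean(axis=0),
        n_significant=n_sig,
        alpha=alpha,
    )


@dataclass
class ReplicationResult:
    """Bidirectional cross-projection correlations and the replication flag.

    ``correlations_ab[j]`` is the Pearson correlation, over cohort B's
    subjects, between B's behavior block scored with A's loadings and with
    B's own (matched, sign-aligned) loadings; ``_ba`` is the mirror image.
    Brain-side analogues are carried alongside.  A component is flagged
    generalizable only when both directions reach significance.
    """

    correlations_ab: np.ndarray  # (d,) behavior-side, direction A -> B
    correlations_ba: np.ndarray
    brain_correlations_ab: np.ndarray
    brain_correlations_ba: np.ndarray
    p_ab: np.ndarray
    p_ba: np.ndarray
    generalizable: np.ndarray  # (d,) bool
    B: int


def _preprocess_for_fit(cohort: TwoViewCohort, k_pc: int, highest_first: bool = True):
    _, residuals = residualize_fit_transform(cohort.brain, cohort.covariates)
    weights = rank_weights(cohort.total_scores(), highest_first=highest_first)
    pca = weighted_pca_fit(residuals, weights, k=k_pc)
    return pca.transform(residuals), cohort.symptoms


def _perm_p_for_correlation(
    a: np.ndarray, b: np.ndarray, B: int, rng: np.random.Generator
) -> float:
    """Add-one permutation p for |corr(a, b)| by shuffling rows of one vector."""
    obs = abs(column_pearson(a, b)[0])
    n = a.shape[0]
    count = 0
    for _ in range(B):
        if abs(column_pearson(a[rng.permutation(n)], b)[0]) >= obs:
            count += 1
    return (1.0 + count) / (B + 1.0)


def qualitative_replication(
    cohort_a: TwoViewCohort,
    cohort_b: TwoViewCohort,
    penalties: PenaltyPair,
    d: int,
    k_pc: int,
    B: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ReplicationResult:
    """Fit independently in each cohort and correlate cross-projected scores.

    Both cohorts get their own residualization and weighted PCA; the SCCA is
    fitted in each with the shared penalty pair (in practice, the pair most
    selected in the discovery cohort).  Cohort B's components are matched to
    cohort A's through the behavior-side loadings before comparison.
    """
    X_a, Y_a = _preprocess_for_fit(cohort_a, k_pc)
    X_b, Y_b = _preprocess_for_fit(cohort_b, k_pc)
    model_a = scca_fit(X_a, Y_a, penalties, d=d)
    model_b = scca_fit(X_b, Y_b, penalties, d=d)
    d_a, d_b = model_a.n_components, model_b.n_components
    if d_a != d_b:
        d = min(d_a, d_b)
        warnings.warn(f"component count mismatch; truncating to {d}", RuntimeWarning)

    perm, signs = match_components(model_a.v, model_b.v)
    u_b = model_b.u[:, perm] * signs
    v_b = model_b.v[:, perm] * signs

    Ya_s, Yb_s = standardize_columns(Y_a), standardize_columns(Y_b)
    Xa_s, Xb_s = standardize_columns(X_a), standardize_columns(X_b)

    # direction A -> B: cohort B's blocks scored with A's loadings vs B's own
    cross_beh_ab = Yb_s @ model_a.v[:, :d]
    native_beh_b = Yb_s @ v_b[:, :d]
    cross_brain_ab = Xb_s @ model_a.u[:, :d]
    native_brain_b = Xb_s @ u_b[:, :d]
    # direction B -> A: cohort A's blocks scored with B's matched loadings
    cross_beh_ba = Ya_s @ v_b[:, :d]
    native_beh_a = Ya_s @ model_a.v[:, :d]
    cross_brain_ba = Xa_s @ u_b[:, :d]
    native_brain_a = Xa_s @ model_a.u[:, :d]

    corr_ab = column_pearson(cross_beh_ab, native_beh_b)
    corr_ba = column_pearson(cross_beh_ba, native_beh_a)
    brain_ab = column_pearson(cross_brain_ab, native_brain_b)
    brain_ba = column_pearson(cross_brain_ba, native_brain_a)

    # one seed sequence shared by both directions keeps the procedure symmetric
    perm_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    p_ab = np.array(
        [
            _perm_p_for_correlation(
                cross_beh_ab[:, j], native_beh_b[:, j], B, np.random.default_rng(perm_seed + j)
            )
            for j in range(d)
        ]
    )
    p_ba = np.array(
        [
            _perm_p_for_correlation(
                cross_beh_ba[:, j], native_beh_a[:, j], B, np.random.default_rng(perm_seed + j)
            )
            for j in range(d)
        ]
    )
    flag = (p_ab < alpha) & (p_ba < alpha)
    return ReplicationResult(
        correlations_ab=corr_ab,
        correlations_ba=corr_ba,
        brain_correlations_ab=brain_ab,
        brain_correlations_ba=brain_ba,
        p_ab=p_ab,
        p_ba=p_ba,
        generalizable=flag,
        B=B,
    )
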