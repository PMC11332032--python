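"""Site-stratified multiple hold-out validation of sparse CCA models.

The engine repeatedly splits a multi-site cohort into disjoint train/test
site sets, confines every fitted quantity (residualization, rank weights,
weighted PCA, penalty selection, SCCA loadings) to the training sites, and
evaluates the fitted model on the held-out sites by pure projection.
Inference is by permutation: behavioral rows are shuffled to break the
brain-behavior pairing while the connectivity block is held fixed, with
refitting on training data and fixed-loading projection on test data.
Multiple testing across components is handled with Benjamini-Hochberg FDR.
Bootstrap resampling of the training subjects quantifies loading stability,
with canonical variates re-matched to the reference model through an
assignment on the behavior-side loadings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from ._utils import column_pearson
from .preprocess import (
    RankWeights,
    Residualizer,
    WeightedPCAModel,
    rank_weights,
    residualize_fit_transform,
    weighted_pca_fit,
)
from .scca import (
    PenaltyPair,
    SCCAModel,
    VariateScores,
    covariance_explained,
    scca_fit,
    scca_project,
)
from .synthdata import TwoViewCohort

logger = logging.getLogger(__name__)

__all__ = [
    "SplitScheme",
    "HoldoutConfig",
    "make_site_splits",
    "make_disjoint_folds",
    "grid_search_penalties",
    "PermutationResult",
    "permutation_test",
    "BootstrapResult",
    "bootstrap_stability",
    "match_components",
    "bh_qvalues",
    "RepetitionResult",
    "HoldoutResult",
    "run_multiple_holdout",
]

DEFAULT_GRID_BRAIN = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
DEFAULT_GRID_BEHAVIOR = tuple(np.round(np.arange(0.6, 1.01, 0.1), 10))


@dataclass(frozen=True)
class SplitScheme:
    """One train/test partition of the site labels."""

    repetition: int
    train_sites: tuple[str, ...]
    test_sites: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_sites) & set(self.test_sites):
            raise ValueError("train and test sites overlap")


def _site_labels(cohort) -> np.ndarray:
    if isinstance(cohort, TwoViewCohort):
        return np.unique(cohort.site)
    return np.unique(np.asarray(cohort))


def make_site_splits(
    cohort, n_test_sites: int = 3, n_reps: int = 30, seed: int = 0
) -> list[SplitScheme]:
    """Sample ``n_reps`` train/test site partitions, independently per repetition.

    Test sites are drawn uniformly without replacement within a repetition;
    the same site may serve as a test site in several repetitions (the
    multiple hold-out scheme; see :func:`make_disjoint_folds` for the
    no-repeats variant).
    """
    sites = _site_labels(cohort)
    if len(sites) <= n_test_sites:
        raise ValueError(
            f"{len(sites)} sites cannot supply {n_test_sites} test sites"
        )
    rng = np.random.default_rng(seed)
    schemes = []
    for rep in range(1, n_reps + 1):
        test = tuple(sorted(rng.choice(sites, size=n_test_sites, replace=False)))
        train = tuple(sorted(s for s in sites if s not in test))
        schemes.append(
            SplitScheme(repetition=rep, train_sites=train, test_sites=test, seed=seed)
        )
    return schemes


def make_disjoint_folds(cohort, n_folds: int = 5, seed: int = 0) -> list[SplitScheme]:
    """Site-level cross-validation folds with no site repeated across test sets.

    Sites are shuffled once and chopped into ``n_folds`` contiguous chunks as
    evenly as possible (earlier folds take the remainder, so 21 sites over 5
    folds gives test sizes 5, 4, 4, 4, 4).
    """
    sites = _site_labels(cohort)
    if len(sites) < n_folds:
        raise ValueError(f"cannot partition {len(sites)} sites into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sites)
    base, rem = divmod(len(sites), n_folds)
    folds = []
    start = 0
    for f in range(n_folds):
        size = base + (1 if f < rem else 0)
        test = tuple(sorted(order[start : start + size]))
        start += size
        train = tuple(sorted(s for s in sites if s not in test))
        folds.append(SplitScheme(repetition=f + 1, train_sites=train, test_sites=test, seed=seed))
    return folds


def grid_search_penalties(
    X: np.ndarray,
    Y: np.ndarray,
    grid_brain=DEFAULT_GRID_BRAIN,
    grid_behavior=DEFAULT_GRID_BEHAVIOR,
    n_inner: int = 100,
    train_frac: float = 0.8,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> PenaltyPair:
    """Select the penalty pair by repeated inner resampling of the training set.

    The training block is split into inner-training (80%) and validation (20%)
    subsets ``n_inner`` times; for every candidate pair, a one-component model
    fitted on each inner-training subset is projected onto its validation
    subset, and the first canonical correlation (sign-aligned with the
    inner-training correlation) is averaged over the splits.  The argmax pair
    wins; exact ties go to the sparser pair, brain penalty first.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    behavior = [c for c in grid_behavior if c > 0.5]
    if not behavior:
        raise ValueError("no behavior penalty above the 0.5 constraint")
    pairs = [PenaltyPair(cb, ch) for cb in sorted(grid_brain) for ch in sorted(behavior)]
    n = X.shape[0]
    cut = int(round(train_frac * n))
    if cut < 3 or n - cut < 3:
        raise ValueError("inner split leaves too few subjects")
    perms = [rng.permutation(n) for _ in range(n_inner)]
    best_pair, best_score = None, -np.inf
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for pair in pairs:
            vals = np.empty(n_inner)
            try:
                for i, perm in enumerate(perms):
                    tr, va = perm[:cut], perm[cut:]
                    model = scca_fit(X[tr], Y[tr], pair, d=1, max_iter=max_iter)
                    r_val = scca_project(model, X[va], Y[va]).correlations[0]
                    sign = np.sign(model.train_correlations[0]) or 1.0
                    vals[i] = sign * r_val
            except ValueError:
                n_failed += 1
                continue
            score = vals.mean()
            if score > best_score:
                best_pair, best_score = pair, score
    if best_pair is None:
        raise ValueError("every candidate penalty pair failed to fit")
    if n_failed:
        logger.info("grid search: %d candidate pair(s) failed to fit", n_failed)
    return best_pair


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries passed through)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class PermutationResult:
    """Null distribution, add-one p-values, and FDR q-values per component."""

    observed: np.ndarray  # (d,)
    null_draws: np.ndarray  # (B, d)
    p_values: np.ndarray  # (d,), NaN for components outside the tested set
    q_values: np.ndarray  # (d,)
    B: int
    tested: np.ndarray  # (d,) bool

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.tolist(),
            "p_values": self.p_values.tolist(),
            "q_values": self.q_values.tolist(),
            "B": int(self.B),
            "tested": self.tested.astype(bool).tolist(),
        }


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    model: SCCAModel,
    mode: str = "project",
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    components: np.ndarray | None = None,
    use_abs: bool = True,
) -> PermutationResult:
    """Permutation significance of canonical correlations.

    Rows of the behavioral block are shuffled to destroy the brain-behavior
    pairing while the connectivity block is held fixed.  ``mode="refit"``
    (training sets) refits the model with the same penalties on each shuffled
    dataset; ``mode="project"`` (test and external sets) re-projects the fixed
    loadings.  p-values use the add-one estimator ``(1 + b) / (B + 1)`` on
    exceedances of |null| over |observed| (``use_abs=False`` for raw signed
    exceedance), and q-values apply Benjamini-Hochberg over the tested
    components.
    """
    if mode not in ("refit", "project"):
        raise ValueError("mode must be 'refit' or 'project'")
    if B < 100:
        warnings.warn(f"B={B} permutations is small; p-values will be coarse", RuntimeWarning)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    d = model.n_components
    tested = np.ones(d, dtype=bool) if components is None else np.asarray(components, bool)

    scores = scca_project(model, X, Y)
    observed = scores.correlations

    null = np.empty((B, d))
    if mode == "project":
        # permuting Y's rows permutes the behavior variate scores identically,
        # so the null can be drawn directly on the score columns
        bs, ys = scores.brain_scores, scores.behavior_scores
        for b in range(B):
            null[b] = column_pearson(bs, ys[rng.permutation(n)])
    else:
        # column standardization commutes with row permutation, so the blocks
        # can be standardized once outside the refit loop
        from ._utils import standardize_columns

        Xs = standardize_columns(X)
        Ys = standardize_columns(Y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for b in range(B):
                refit = scca_fit(
                    Xs,
                    Ys[rng.permutation(n)],
                    model.penalties,
                    d=d,
                    max_iter=100,
                    standardize=False,
                )
                null[b] = refit.train_correlations

    p = np.full(d, np.nan)
    if tested.any():
        if use_abs:
            exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
        else:
            exceed = (null >= observed[None, :]).sum(axis=0)
        p[tested] = (1.0 + exceed[tested]) / (B + 1.0)
    else:
        logger.info("covariance-explained gate selected no components; empty test")
    return PermutationResult(
        observed=observed,
        null_draws=null,
        p_values=p,
        q_values=bh_qvalues(p),
        B=B,
        tested=tested,
    )


def match_components(
    v_reference: np.ndarray, v_other: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bijectively match components by |cosine| of behavior-side loadings.

    Returns ``(perm, signs)`` such that ``v_other[:, perm[j]] * signs[j]``
    aligns with reference component ``j`` (cosine >= 0 after flipping).
    """
    v_reference = np.asarray(v_reference, dtype=float)
    v_other = np.asarray(v_other, dtype=float)
    if v_reference.shape != v_other.shape:
        raise ValueError("loading matrices must share shape for matching")
    ref = v_reference / np.maximum(np.linalg.norm(v_reference, axis=0), 1e-12)
    oth = v_other / np.maximum(np.linalg.norm(v_other, axis=0), 1e-12)
    cos = ref.T @ oth
    rows, cols = linear_sum_assignment(-np.abs(cos))
    perm = np.empty_like(cols)
    perm[rows] = cols
    signs = np.array([1.0 if cos[j, perm[j]] >= 0 else -1.0 for j in range(len(perm))])
    return perm, signs


@dataclass
class BootstrapResult:
    """Aligned loadings and correlations over bootstrap resamples."""

    matched_u: np.ndarray  # (B_kept, k_pc, d)
    matched_v: np.ndarray  # (B_kept, q, d)
    correlations: np.ndarray  # (B_kept, d)
    match_permutations: np.ndarray  # (B_kept, d)
    B: int
    n_failed: int = 0


def bootstrap_stability(
    X: np.ndarray,
    Y: np.ndarray,
    reference: SCCAModel,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> BootstrapResult:
    """Refit on subject resamples (with replacement) and align to the reference.

    Bootstrapping can permute component order and flip loading signs, so each
    resample's components are bijectively matched to the reference through the
    behavior-side loadings and sign-aligned (both ``u`` and ``v`` flipped
    together, which leaves the canonical correlation unchanged).  Resamples on
    which the refit fails are dropped and counted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = X.shape[0]
    d = reference.n_components
    out_u, out_v, out_r, out_perm = [], [], [], []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(B):
            idx = rng.integers(n, size=n)
            try:
                boot = scca_fit(X[idx], Y[idx], reference.penalties, d=d, max_iter=100)
            except ValueError:
                n_failed += 1
                continue
            perm, signs = match_components(reference.v, boot.v)
            out_u.append(boot.u[:, perm] * signs)
            out_v.append(boot.v[:, perm] * signs)
            out_r.append(boot.train_correlations[perm])
            out_perm.append(perm)
    if n_failed:
        logger.warning("bootstrap: %d of %d resamples failed to refit", n_failed, B)
    return BootstrapResult(
        matched_u=np.array(out_u),
        matched_v=np.array(out_v),
        correlations=np.array(out_r),
        match_permutations=np.array(out_perm),
        B=B,
        n_failed=n_failed,
    )


@dataclass(frozen=True)
class HoldoutConfig:
    """Knobs of the multiple hold-out run."""

    n_reps: int = 30
    n_test_sites: int = 3
    k_pc: int = 100
    d: int = 8
    grid_brain: tuple = DEFAULT_GRID_BRAIN
    grid_behavior: tuple = DEFAULT_GRID_BEHAVIOR
    n_inner: int = 100
    inner_train_frac: float = 0.8
    B_train: int = 2000
    B_test: int = 2000
    alpha: float = 0.05
    highest_first: bool = True
    seed: int = 0


@dataclass
class RepetitionResult:
    """Everything fitted and measured in one train/test repetition."""

    scheme: SplitScheme
    residualizer: Residualizer
    weights: RankWeights
    pca: WeightedPCAModel
    penalties: PenaltyPair
    model: SCCAModel
    train_scores: VariateScores
    test_scores: VariateScores
    covariance_shares: np.ndarray
    gate: np.ndarray
    train_perm: PermutationResult
    test_perm: PermutationResult

    def training_state(self) -> dict:
        """Serializable snapshot of every training-fit parameter."""
        return {
            "train_sites": list(self.scheme.train_sites),
            "residualizer": self.residualizer.to_dict(),
            "weights": self.weights.to_dict(),
            "pca": self.pca.to_dict(),
            "penalties": [self.penalties.c_brain, self.penalties.c_behavior],
            "model": self.model.to_dict(),
        }

    def to_dict(self) -> dict:
        return {
            "training_state": self.training_state(),
            "test_sites": list(self.scheme.test_sites),
            "train_correlations": self.train_scores.correlations.tolist(),
            "test_correlations": self.test_scores.correlations.tolist(),
            "covariance_shares": self.covariance_shares.tolist(),
            "gate": self.gate.astype(bool).tolist(),
            "train_perm": self.train_perm.to_dict(),
            "test_perm": self.test_perm.to_dict(),
        }


@dataclass
class HoldoutResult:
    repetitions: list[RepetitionResult]
    config: HoldoutConfig
    n_failed: int = 0

    def summary_table(self):
        import pandas as pd

        rows = []
        for rep in self.repetitions:
            for j in range(self.config.d):
                rows.append(
                    {
                        "repetition": rep.scheme.repetition,
                        "component": j + 1,
                        "train_r": rep.train_scores.correlations[j],
                        "test_r": rep.test_scores.correlations[j],
                        "covariance_share": rep.covariance_shares[j],
                        "gated": bool(rep.gate[j]),
                        "train_p": rep.train_perm.p_values[j],
                        "train_q": rep.train_perm.q_values[j],
                        "test_p": rep.test_perm.p_values[j],
                        "test_q": rep.test_perm.q_values[j],
                        "c_brain": rep.penalties.c_brain,
                        "c_behavior": rep.penalties.c_behavior,
                    }
                )
        return pd.DataFrame(rows)

    def mean_train_correlations(self) -> np.ndarray:
        return np.mean([r.train_scores.correlations for r in self.repetitions], axis=0)

    def mean_test_correlations(self) -> np.ndarray:
        return np.mean([r.test_scores.correlations for r in self.repetitions], axis=0)

    def n_validated(self, alpha: float | None = None) -> np.ndarray:
        """Per component, the number of repetitions with test q below alpha."""
        alpha = self.config.alpha if alpha is None else alpha
        q = np.array([r.test_perm.q_values for r in self.repetitions])
        with np.errstate(invalid="ignore"):
            return np.nansum(q < alpha, axis=0).astype(int)

    def most_selected_penalties(self) -> PenaltyPair:
        """Mode of the selected penalty pairs; ties go to the sparser pair."""
        from collections import Counter

        counts = Counter(
            (r.penalties.c_brain, r.penalties.c_behavior) for r in self.repetitions
        )
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return PenaltyPair(*best[0])

    def to_json(self) -> str:
        payload = {
            "format": "holdoutcca-holdout-result",
            "version": 1,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.__dict__.items()
            },
            "n_failed": self.n_failed,
            "repetitions": [r.to_dict() for r in self.repetitions],
        }
        return json.dumps(payload, sort_keys=True)


def run_multiple_holdout(cohort: TwoViewCohort, config: HoldoutConfig) -> HoldoutResult:
    """The full leakage-safe pipeline over all train/test repetitions.

    Per repetition: residualize each set with its own covariates, compute rank
    weights and the weighted PCA on training data only, transfer eigenvectors
    to the test set, select penalties by inner resampling of the training set,
    fit the SCCA model, project it onto the test set, and run permutation
    tests (refit-mode on training, project-mode on test) for the components
    passing the covariance-explained gate.  A repetition that errors at any
    stage is dropped with a logged diagnosis; at least one must survive.
    """
    cohort.validate()
    root = np.random.SeedSequence(config.seed)
    split_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
    schemes = make_site_splits(
        cohort, n_test_sites=config.n_test_sites, n_reps=config.n_reps, seed=split_seed
    )
    rep_seeds = root.spawn(config.n_reps)

    reps: list[RepetitionResult] = []
    n_failed = 0
    for scheme, rep_ss in zip(schemes, rep_seeds):
        try:
            reps.append(_run_repetition(cohort, scheme, config, rep_ss))
        except Exception as exc:  # noqa: BLE001 — any stage failure aborts the repetition
            n_failed += 1
            logger.warning("repetition %d failed: %s", scheme.repetition, exc)
    if not reps:
        raise RuntimeError("all hold-out repetitions failed")
    return HoldoutResult(repetitions=reps, config=config, n_failed=n_failed)


def _run_repetition(
    cohort: TwoViewCohort,
    scheme: SplitScheme,
    config: HoldoutConfig,
    rep_ss: np.random.SeedSequence,
) -> RepetitionResult:
    grid_ss, perm_train_ss, perm_test_ss = rep_ss.spawn(3)
    train_mask = np.isin(cohort.site, scheme.train_sites)
    test_mask = np.isin(cohort.site, scheme.test_sites)

    res_train, R_train = residualize_fit_transform(
        cohort.brain[train_mask], cohort.covariates.loc[train_mask].reset_index(drop=True)
    )
    _, R_test = residualize_fit_transform(
        cohort.brain[test_mask], cohort.covariates.loc[test_mask].reset_index(drop=True)
    )

    weights = rank_weights(
        cohort.total_scores()[train_mask], highest_first=config.highest_first
    )
    pca = weighted_pca_fit(R_train, weights, k=config.k_pc)
    X_train = pca.transform(R_train)
    X_test = pca.transform(R_test)
    Y_train = cohort.symptoms[train_mask]
    Y_test = cohort.symptoms[test_mask]

    penalties = grid_search_penalties(
        X_train,
        Y_train,
        grid_brain=config.grid_brain,
        grid_behavior=config.grid_behavior,
        n_inner=config.n_inner,
        train_frac=config.inner_train_frac,
        seed=np.random.default_rng(grid_ss),
    )
    model = scca_fit(X_train, Y_train, penalties, d=config.d)
    train_scores = scca_project(model, X_train, Y_train)
    test_scores = scca_project(model, X_test, Y_test)
    shares, gate = covariance_explained(train_scores)

    train_perm = permutation_test(
        X_train,
        Y_train,
        model,
        mode="refit",
        B=config.B_train,
        seed=np.random.default_rng(perm_train_ss),
        components=gate,
    )
    test_perm = permutation_test(
        X_test,
        Y_test,
        model,
        mode="project",
        B=config.B_test,
        seed=np.random.default_rng(perm_test_ss),
        components=gate,
    )
    return RepetitionResult(
        scheme=scheme,
        residualizer=res_train,
        weights=weights,
        pca=pca,
        penalties=penalties,
        model=model,
        train_scores=train_scores,
        test_scores=test_scores,
        covariance_shares=shares,
        gate=gate,
        train_perm=train_perm,
        test_perm=test_perm,
    )
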