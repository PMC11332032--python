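# Methods

This note documents the models and procedures implemented in `holdoutcca`,
the parameter choices that matter, and what the synthetic-data experiments do
and do not demonstrate.

## The sparse CCA model

Both blocks are column-standardized internally before fitting (covariance
maximization is scale-sensitive, and brain principal components and symptom
sum scores live in different units). For each component the solver maximizes
`u' X'Y v` subject to unit l2 norms and l1 bounds on `u` and `v`, by
alternating updates

    u <- S(X'Y v, delta_u) / ||.||_2 ,   v <- S(Y'X u, delta_v) / ||.||_2

where `S` is soft thresholding and each `delta` is chosen so the l1 bound
holds — the penalized-matrix-decomposition realization of sparse CCA with an
elastic-net-style (l1 + l2) constraint on the loadings. The threshold is
computed in closed form: the l1/l2 ratio of the thresholded vector is smooth
between consecutive sorted magnitudes, so the bound equation reduces to a
per-segment quadratic. Iterations start from the leading singular pair of the
(deflated) cross-covariance and stop when the largest loading change falls
below 1e-6 (200 iterations maximum; non-convergence is a warning and a flag,
not an error). Components are extracted sequentially with rank-one deflation
of the cross-covariance `C <- C - (u'Cv) uv'` — deflating the cross-product
rather than the data keeps components comparable across penalty settings.

A grid value `c` in [0, 1] maps to the l1 bound `max(1, c * sqrt(dim))`.
Bounds below 1 are infeasible for a unit-l2 vector and are clamped to 1
(maximal sparsity: a coordinate vector) so the whole printed grid is usable.
The behavior-side penalty is constrained to exceed 0.5 to keep the
syndrome-scale loadings interpretable. The default number of components is
`q` (8, the number of syndrome scales); analyses typically examine the first
three.

**Sign conventions.** Each returned loading column is flipped so its
largest-magnitude entry is positive. This makes loadings reproducible, but it
means the *sign* of a canonical correlation is arbitrary (flipping `u` alone
negates `corr(Xu, Yv)`). Wherever training and held-out correlations are
compared — the inner penalty search, the shrinkage check, summary reporting —
the held-out value is aligned with the sign of the corresponding training
correlation, and cross-repetition summaries are taken on magnitudes.
Permutation tests are two-sided (`|null| >= |observed|`) for the same reason,
with a flag for raw one-sided exceedance.

## Weighted PCA and the rank-weighting scheme

Subjects are ranked by total symptom score (rank 1 = most symptoms, average
fractional ranks for ties); pre-weights are `ln n - ln r_i`, normalized to
sum to one. The feature matrix is demeaned with unweighted column means and
each row multiplied by its normalized weight before the eigendecomposition;
with uniform weights this reduces exactly to standard PCA. Two points were
genuinely open and are settable by flag:

- *rank direction*: descending was chosen because the scheme's purpose is to
  emphasize high-symptom subjects in the component basis;
- *row scaling*: rows are multiplied by `w_i` (the literal reading of
  "adjusted with the normalized weights"); `sqrt(w_i)` — the
  weighted-covariance variant — is available as `row_scale="sqrt_w"`;
- *demeaning*: unweighted column means (weighted means available).

Held-out data are projected onto the training eigenvectors by plain matrix
multiplication without re-centering: residualized features are near-zero-mean
by construction, and re-centering with training means would mix a training
statistic into the test transform for no benefit.

## The hold-out engine and inference

Each repetition draws test sites uniformly without replacement (sites may
recur across repetitions; a disjoint-fold variant exists for the no-repeat
sensitivity analysis). Residualization of the brain features on
age/sex/education/origin covariates is done *separately* per set; rank
weights, PCA, penalty selection, and SCCA fitting see training rows only.
The inner penalty search splits the training set 80/20 at the subject level
(unstratified — the literal reading of a further random split), fits one
component per candidate pair, and averages the sign-aligned validation
correlation over the inner splits; exact ties go to the sparser pair, brain
penalty first.

Permutation p-values use the add-one estimator `(1 + b) / (B + 1)` rather
than a raw exceedance count divided by B, so p = 0 is impossible and the null
distribution of p is uniform on its attainable grid. Training sets use
refit-mode permutations (same penalties, full refit per shuffle); test and
external sets use project-mode (loadings fixed) — refitting on test data
would leak. Only components whose share of total absolute cross-block
covariance strictly exceeds the mean share are tested; q-values are
Benjamini-Hochberg across the tested components, and a component counts as
validated in a repetition when its test-set q < 0.05.

Bootstrap stability resamples training subjects with replacement, refits with
the reference penalties, and re-matches components to the reference model by
maximizing total |cosine| between behavior-side loading columns under a
one-to-one assignment (Hungarian algorithm), flipping matched pairs so the
behavior-side cosine is non-negative; `u` and `v` flip together, leaving the
canonical correlation unchanged. The same matcher aligns components across
cohorts in the replication procedure.

## Cross-study generalizability

The gold-standard test residualizes the target cohort with its own
covariates, pushes the residuals through each source repetition's training
eigenvectors, scores with the training loadings, and permutation-tests the
external correlations (project mode, source gate). Qualitative replication
fits the model independently in each cohort — own residualization, own
weighted PCA — with a shared penalty pair (the pair most selected across the
source repetitions; ties to the sparser pair), then correlates each cohort's
cross-projected behavior variate scores with its natively trained ones, in
both directions, each with its own permutation test; a component is flagged
generalizable only when both directions are significant. The replication
correlations are computed on the behavior-side scores: the behavior view is
low-dimensional and its loading structure is the stable part across cohorts,
which is exactly why replication can succeed while the gold-standard
projection — which additionally requires the brain-side loadings to
transfer — fails. The regression test for this divergence constructs two
cohorts sharing behavior-side structure but with disjoint brain-loading
supports.

## The synthetic cohort generator

For each planted component a latent pair is drawn with exact correlation
`rho`; the brain view is `Z A' + covariates + site shifts + noise` with `A`
sparse (supports drawn disjointly across components when there is room,
Gram-Schmidt orthogonalized otherwise) and unit-norm columns. Symptoms are
built from `Z B' + covariates + noise`, column-standardized, and passed
through the monotone map `round(exp(0.5 + 0.9 g) - 1)` floored at zero, which
produces non-negative integer scores with means near 2, standard deviations
exceeding the means, positive skew, and a substantial spike at zero — the
signature shape of caregiver-reported syndrome scales in population samples.
Site shifts (per-site Gaussian offsets) act on the brain view only, mirroring
scanner-driven variability; covariates act linearly on both views so that
residualization is non-trivial to test.

Defaults: q = 8 symptom scales, 21 sites, 10% loading sparsity, site and
covariate effect scales 0.1, unit noise. Sample size, feature count, and the
planted correlations are required arguments. The planted-recovery experiments
use one component with latent correlation 0.6, 10% sparsity, n = 1500,
p = 150 features, 6 sites, noise scale 0.5, 25 retained PCs — sizes at which
a desk-scale machine resolves the signal clearly while the grid search,
permutations (B = 200), and five hold-out repetitions still run in seconds.
The null-calibration experiment uses independent 300 x 20 and 300 x 8 blocks.
The generator does **not** emulate hemodynamics, scanner-specific artifact
structure, heavy-tailed motion contamination, or longitudinal dependence;
passing tests demonstrate the statistical machinery is correct and calibrated
under the stated generative model, not that real connectivity data meet its
assumptions.

## Numerical choices and degenerate inputs

- Correlations are clipped at |r| = 1 - 1e-7 before the Fisher z-transform so
  numerically perfect edges stay finite; constant residual series raise an
  error naming the offending region.
- Zero-variance columns are centered but not scaled during standardization;
  zero-variance features get an edge contribution of 0 with a warning.
- A loading fully removed by thresholding raises an error suggesting a larger
  penalty value; a refit failure inside the bootstrap drops that resample
  with a logged count.
- Ranks use average ties, making the weights deterministic and invariant to
  input order; the lowest-ranked subject's pre-weight is exactly zero.
- The covariance-explained gate is strict (`share > mean`), so a single
  fitted component is never gated in; permutation tests then return an empty
  (all-NaN) result with a log note.
- All randomness flows from integer seeds through `numpy` seed sequences;
  identical seed and configuration reproduce hold-out results byte-for-byte.

## Known limitations

- The solver is the standard alternating scheme for penalized matrix
  decomposition; like all such schemes it converges to a stationary point,
  and global optimality is only verified against exhaustive search on small
  problems.
- Module aggregation sums absolute contributions by default (signed sums
  available), and z-scores are computed over the unique module cells within
  one dimension; other normalization populations are defensible.
- The qualitative-replication procedure projects loadings across cohorts in
  each cohort's own PC basis, as the procedure is usually practiced; the
  bases are not rotated into alignment first.
- Voxel-level preprocessing, scanner harmonization, covariate imputation, and
  clustering of variate scores are out of scope.
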