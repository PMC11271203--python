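# Methods

## Model and procedure

The pipeline treats each subject's K component time courses as one draw of
a linear dynamical system and asks which components' past values help
predict the others' futures. The operational definition of "component *i*
causes component *j*" is the signed coefficient `A[i,j]` of the jointly
fitted first-order vector autoregression

    x_j(t) = Σ_i A[i,j] · x_i(t−1) + e_j(t),   t = 2…T,

estimated per subject by least squares on the demeaned time courses, with
all K lagged predictors entering every target equation simultaneously
(multivariate, not pairwise, Granger causality). Matrices are stored and
written source-major — row = source, column = target — and every matrix
file carries a convention header so a transposed file cannot be consumed
silently.

Group-level influence is the entrywise sum of |A| across subjects (the
`absolute` approach). Two alternatives are implemented: `signed` (raw sums;
excitatory and inhibitory influences cancel) and `split` (positive and
negative parts summed separately, for users who care about the direction of
the effect and not only its size). Absolute aggregation is the default
because a component that strongly inhibits another is no less causal than
one that excites it.

A component's **score** is its aggregated row sum over targets with the
diagonal excluded: self-coupling says nothing about influence on *other*
networks. An `include_diagonal` flag exists for sensitivity analysis.

### Selection rule

"Top 20%" is implemented as a value threshold: components with score
strictly above `0.8 · max(score)`. The alternative reading — the top
⌈0.2·K⌉ components by rank — is available as `rule="rank_count"`, but the
value threshold is the default because the worked example's arithmetic
(maximum 4413.19, cutoff 3530.55, 12 of 114 components selected rather than
~23) identifies it uniquely. The cutoff is displayed at 2 decimals; full
precision is kept in machine output. Boundary-equal scores are excluded
(strictly "above" the cutoff). The same rule is applied per source row when
selecting each causal component's targets, for internal consistency; both
stages record which rule produced the output.

On null data (no true influence) the value-threshold selection size is a
calibration artifact of the rule — scores are then all estimation noise of
similar size and the threshold may admit many components. The rule is
designed for data with genuine spread; the test suite reports recovery
under a dominant source, not selection size under the null.

### Global signal regression

The global signal G is regressed out of each component signal Y by
standardizing both, fitting the no-intercept slope of z(Y) on z(G) (equal
to the Pearson r), and denormalizing the residual back to Y's mean and
standard deviation. Consequences asserted by tests: the corrected signal's
mean equals μ_Y to floating precision, its standard deviation equals
σ_Y·√(1−r²), it is exactly uncorrelated with G, and the operation is
idempotent. Whether z-scoring uses the population (T) or sample (T−1)
denominator is configurable (`ddof`, default 1); the choice rescales only
the intermediate standardized residual and cancels exactly in the corrected
signal, which is also asserted. When only component time series are
available the global signal must be supplied as a file: component signals
cannot reconstruct a gray-matter average.

### Dual regression

Stage 1 solves, for each time point, the least-squares regression of the
voxel vector on the K group-map columns within the mask; map columns are
demeaned over mask voxels first (absorbing an intercept), matching the
common default of the standard implementation. Stage 2 regresses each
voxel's time series on the stage-1 time courses after demeaning and
variance-normalizing them (switchable), so map units are comparable across
components. Rank-deficient map matrices are rejected with the collinear
columns named. Voxel ordering is the flattened native array order; shape
checks, not resampling, enforce agreement.

## Conditioning of the VAR fit

With 144 volumes and 114 components the lagged design has 143 rows and 114
columns — barely overdetermined — and the coefficient estimates are
dominated by noise. The default fit is deliberately unregularized for
fidelity to the coefficient-mode procedure it reproduces, but it logs a
loud warning with the design's condition number whenever there are fewer
than two samples per predictor or the condition number exceeds 1e8, and it
returns the minimum-norm (pseudoinverse) solution when the design is
genuinely rank-deficient. A generalized-cross-validation ridge heuristic
(`suggest_ridge`) is provided for users who prefer a regularized estimate;
it is advisory and off by default.

## Synthetic data generator

The generator emulates the study conditions: S subjects × T volumes × K
components (defaults 63 × 144 × K at a TR of 2.5 s) from a stationary
VAR(1) with known source-major coefficient matrix. Features modeled:

- **Ground-truth influence** `A` with spectral radius of the transition
  matrix < 1, enforced at construction (rejection names the radius).
  Default cross-coefficients in examples are 0.2–0.5 — chosen for test
  power, not as a claim about real between-network effect sizes, which no
  reference quantifies.
- **Shared global signal**: an AR(1) process (coefficient 0.9, unit
  stationary variance) injected additively into each component through a
  per-component gain. AR(1) mimics slow whole-brain drift and makes the
  effect of global signal regression measurable.
- **Subject heterogeneity**: independent Gaussian jitter (sd
  `subject_jitter_sd`) on every coefficient per subject. A jittered matrix
  that leaves the stationary region (radius ≥ 0.999) is rescaled to radius
  0.95 with a logged notice rather than rejected, so large-jitter runs do
  not fail stochastically.
- **Burn-in**: 100 samples discarded so recorded samples are approximately
  stationary draws; negligible cost, removes initial-condition transients.
- Series are generated mean-zero; GSR's mean-preservation is therefore
  testable without confounding offsets.

Not modeled: hemodynamic convolution, cardiac/respiratory noise, scanner
artifacts, motion. Passing tests on synthetic data demonstrate that the
*estimation chain* recovers a known linear generative structure; they do
not certify behavior under hemodynamic blurring or physiological
confounds, where lag-1 coefficients on a 2.5 s sampling grid are known to
be a coarse instrument.

The volumetric generator composes Gaussian-blob spatial maps (pairwise
correlation < 0.5, enforced by redrawing centers) with the VAR time
courses plus voxel noise, returning the true courses for oracle comparison
with stage-1 dual regression.

## Numerical choices

- All regressions solve via `numpy.linalg.lstsq`/`solve`; oracle tests pin
  them to explicit normal-equations solutions within 1e-8.
- Determinism: one `numpy` Generator seeded from `GroundTruth.seed` drives
  all randomness in generation; identical parameters and seed reproduce
  outputs bit for bit, and the pipeline manifest hashes outputs to prove
  it.
- TSV is the canonical dialect (UTF-8, '.' decimal, tab separator); floats
  are written with `repr` so read→write round trips are byte-identical.
- Ties in rank-based selection break by ascending component id; target
  lists sort by descending weight then ascending id — all orderings are
  deterministic.
- Zero-variance series are detected by exact range (`ptp == 0`), not by a
  tolerance on the standard deviation, and raise errors naming the subject
  and component.

## Problem sizes in the test suite

Unit and property tests run at small K (2–10) and T (50–5000). The
Monte-Carlo ranking check uses 50 replicates of 20 subjects × 1000 volumes
× 10 components with one dominant source and 0.05 coefficient jitter, a
size at which the source's aggregated score separates from the noise floor
by an order of magnitude. The packaged worked-example tables (12 causal
components, 28 × 12 influence grid) exercise the selection, edge-table and
class-summary stages at the full 114-component scale without any imaging
data.

## Known limitations

- Lag-1 coefficients conflate direct and hemodynamically delayed
  influence; no deconvolution is attempted (out of scope).
- Only order 1 is implemented; higher orders, spectral causality, and
  significance testing (F-tests, permutation nulls, FDR) are explicitly
  out of scope.
- The exact preprocessing of the coefficient-mode reference tool is
  undocumented; this package's definition — demeaned columns, joint OLS,
  minimum-norm fallback — is declared rather than reverse-engineered, and
  discrepancies with that tool are possible.
- Anatomical labeling (cortical/subcortical/artifact) is user input; the
  shipped label table classes white matter, putamen and cerebellum as
  subcortical, recorded in the data file, not in code.
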