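# Methods

## Model and procedure

`cpmkit` implements connectome-based predictive modelling (CPM) for a
continuous behaviour change score. The assumptions are the standard CPM
ones: the behaviour is (monotonically) related to the *sum* of a sparse set
of connectivity edges; the relation is stable enough across subjects that
masks selected on n − 1 subjects transfer to the held-out subject; and
nuisance covariates (age, sex, education) may correlate with both edges and
behaviour and must be partialled out *of the selection statistic* (the
strength→behaviour model itself is deliberately unadjusted, matching how
the procedure is used in the field).

### Partial Spearman selection

The selection statistic is the partial Spearman correlation: rank-transform
the edge, the behaviour and each covariate (average ranks on ties), regress
the ranked edge and ranked behaviour on the ranked covariates plus an
intercept, and take the Pearson correlation of the two residual vectors.
The two-sided p-value uses Student's t with n − C − 2 degrees of freedom.
This is the standard construction; with C = 0 it reduces exactly to the
plain Spearman coefficient with its usual t-approximation p-value (verified
against scipy and a brute-force oracle to 1e−12). Selection is strict
(p < threshold, not ≤): with thresholds drawn from a fine grid the boundary
case has measure zero, and a fixed convention makes runs reproducible.

A constant edge (or constant behaviour after ranking) has no defined rank
correlation; it is assigned ρ = 0, p = 1 so it is never selected, with a
warning on the user-facing path.

### Degenerate folds

A fold whose training strengths are constant — an empty mask is the common
case — predicts the training-behaviour mean, the no-information optimum for
squared error. Degeneracy is detected by an exact zero range of the
training strengths (empty masks produce exact zeros, so no tolerance is
needed). If *every* prediction is constant, ρ_true is defined as 0 rather
than NaN so permutation counting stays total. These conventions keep the
pipeline total on tiny cohorts at stringent thresholds.

### Threshold tuning and permutation scope

Both networks' ρ_true curves are read from a single sweep of the grid
(the networks never interact within a run, so this is mathematically
identical to two sweeps at half the cost); each network's argmax is taken
independently, with exact ties broken to the smallest threshold.

Tuning the threshold on the data at which ρ_true is then evaluated is
optimistic. The permutation test therefore has two modes:

* `reoptimize=True` (recommended): the grid search is re-run inside every
  permutation and the observed statistic is itself the grid-maximized
  ρ_true. Observed and null statistics are exchangeable, so the test is
  exactly calibrated — the test suite measures a rejection rate
  statistically indistinguishable from the nominal 5% over 200 null cohorts.
* `reoptimize=False`: permutations are run at the supplied fixed
  thresholds. If those thresholds were pre-tuned on the observed data this
  test is anti-conservative; the suite asserts that its null rejection rate
  strictly exceeds the re-optimized test's on the same cohorts. The
  pipeline surfaces this caveat in its provenance block.

The permutation p-value is (#{ρ_new ≥ ρ_true} + 1)/(N + 1) — with the
conventional ≥ and the +1 in both numerator and denominator, giving the
familiar denominator 5001 at N = 5000 and a smallest attainable p of
1/5001. Only the behaviour vector is shuffled; covariates stay attached to
their subjects' connectomes, so the permutation null preserves the
edge–covariate structure.

Benjamini–Hochberg FDR correction (via `statsmodels.stats.multitest`) is
applied across all (contrast × network) p-values computed in one pipeline
invocation; the family is therefore explicit in the output, since
conventions differ on whether the two contrasts form one family.

### Motion QC

Framewise displacement is the Power-style sum of absolute backward
differences of the six rigid-body parameters, with rotations converted to
arc length at a configurable head radius (default 50 mm; the dominant
convention in the scrubbing literature — the alternative Jenkinson form is
not implemented, but the radius and rotation units are explicit and
logged). Exclusion rules: (a) fewer than 20% of volumes with FD > 0.5 mm,
(b) maximum absolute translation ≤ 3 mm and rotation ≤ 3°, (c) mean
FD < 0.2 mm. The module only *reports* QC; scrubbing-as-regressors belongs
to upstream preprocessing.

## Synthetic cohorts

The generator emulates the statistical regime of a small surgical cohort:
n ≈ 9–20 subjects, correlation-valued edges (AAL-116's 6670-edge space by
default), a behaviour delta linearly coupled to a sparse planted edge set
with additive Gaussian noise, and three nuisance covariates (age uniform on
23–50 years, sex Bernoulli(9/12) mirroring a 9/3 female/male split,
education 9–19 years).

Design choices, fixed once:

* **Direct edge-space generation.** Background edges are i.i.d.
  tanh(N(0.15, 0.3²)) — bounded in (−1, 1) with a realistic positive mean;
  tanh was chosen over clipping so tests cannot depend on an atom at ±1.
  Edges are *not* derived from a common latent time series;
  `generate_timeseries` exists separately (multivariate Gaussian with a
  specified population correlation, 155 volumes by default, mirroring a
  160-volume scan with five dummy volumes discarded) for end-to-end tests
  of connectivity construction. Direct generation gives exact control over
  planted effects.
* **Coherent signal network.** The planted signal edges share a
  subject-level latent factor (`latent_share`, default 0.5 of their
  pre-bound variance). This is deliberate realism: CPM's summed-strength
  model presumes the selected edges covary as a network. It is also what
  makes the planted-recovery regime well-posed — with 10 *independent*
  equal-effect edges at population R² = 0.5, each edge's marginal
  correlation with behaviour is 1/√20 ≈ 0.22, undetectable at n = 20 at
  any sensible threshold; with a shared factor at 0.5 the marginal
  correlation rises to ≈ 0.52 while total signal R² is unchanged.
* **Behaviour is linear in the stored edge values** (post-tanh), so at
  noise_sd = 0 an OLS regression of behaviour on the true signal edges
  recovers the planted coefficients to numerical precision — the exact
  recovery oracle the tests use.
* **Noise calibration.** `calibrate_noise_sd` targets a population
  R² = var(signal)/(var(signal) + σ²) by Monte-Carlo estimation of the
  signal-combination variance (no closed form under tanh); the estimate is
  deterministic given its seed.
* All randomness flows through one `numpy.random.default_rng(seed)` per
  call; identical arguments reproduce a cohort bit for bit, and the
  serialized truth record is sufficient to regenerate it.

What the generator does **not** emulate: haemodynamic autocorrelation,
vascular pathology, realistic fMRI noise spectra, site/scanner effects, or
any specific non-Gaussian behaviour-score shape. Passing tests therefore
demonstrate the *statistical machinery* — calibration, recovery,
invariances — not performance on real patient data.

## Problem sizes used in tests

The verification suite runs at reduced but statistically meaningful sizes,
chosen so the whole suite completes in a few minutes: null calibration uses
200 cohorts (n = 12, 30 nodes → 435 edges) × 200 permutations; signal
recovery 50 cohorts (n = 20, 10 planted edges, R² = 0.5) against the full
500-point grid; the optimism comparison 40 cohorts × 80 permutations. The
acceptance script uses comparable sizes (30/15/100 cohorts) and reports the
size next to every value.

## Numerical conventions

* Edge order: row-major strict upper triangle, 0-based node indices, fixed
  everywhere (files, masks, labels).
* No Fisher z-transform anywhere: network strengths sum raw correlations.
* Grid values are integer multiples of the step (no floating accumulation);
  the default grid is exactly 500 values, both endpoints included.
* OLS strength models use the closed-form two-parameter solution; the QR-
  based covariate residualization drops collinear covariate columns.
* Rotations are radians on input (degrees via a flag); the 3° rule is
  evaluated in degrees.

## Known limitations

* Only leave-one-out CV and the two-network (positive/negative) CPM variant
  are implemented — no k-fold, ridge, or combined-strength models.
* The partial-Spearman p-value is the usual t-approximation; at n ≈ 12 its
  tails are approximate, which is visible as a selection type-I rate
  slightly above nominal (≈ 1.1% at p < 0.01 in the suite). Selection
  thresholds are tuning parameters, not inferential claims, so this bias is
  absorbed by the permutation test.
* `reoptimize=False` permutation p-values at data-tuned thresholds are
  optimistic by construction; they are provided because the convention is
  widespread, and the bias is measured rather than hidden.
* NIfTI ingestion, parcellation and nuisance regression are out of scope;
  inputs are parcel time series or precomputed connectivity/edge tables.
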