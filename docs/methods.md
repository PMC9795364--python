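# Methods

`spotcorr` detects *spatially varying correlation* within gene sets in
spatial transcriptomics (ST) data. This note documents the statistical
model, the estimation and inference machinery, the simulator the benchmarks
run on, and the numerical and design choices a maintainer should know
about.

## Problem and model

An ST slide yields an `n × m` normalized expression matrix `Y` (spots ×
genes), 2-D spot coordinates `s_i`, and a per-spot region label `c_i`
(cluster id or annotated tissue domain). The question is whether the
*correlation structure* of a designated gene set changes across space —
within a region (WR-test) or between regions (BR-test) — as distinct from
changes in mean expression or variance, which are ubiquitous and not of
interest here.

Both tests model expression rows as independent multivariate normals,

    y_i ~ MVN(μ_i, S_i R_i S_i),

where `μ_i` is a spot-specific mean vector, `S_i` a diagonal matrix of
spot-specific standard deviations, and `R_i` a spot-specific correlation
matrix. The null and alternative differ **only** in `R_i`:

* **WR-test** (one region at a time). Alternative: `S_i R_i S_i` is the
  full kernel covariance at spot *i* (local correlation free to vary).
  Null: the diagonal keeps the kernel variances, while every off-diagonal
  is the region-wide Pearson correlation scaled by the kernel standard
  deviations, `Σ_null,i[g,g'] = R_C[g,g'] · σ_i,g · σ_i,g'`.
* **BR-test** (a region pair, or all surviving regions). Alternative: each
  spot uses its own region's Pearson correlation. Null: a single Pearson
  correlation pooled over the scope. Kernel variances on the diagonal in
  both.

The statistic is the log likelihood ratio `T(Y) = Σ_i [log p_alt(y_i) −
log p_null(y_i)]`. Because means and variances are shared between the two
models, `T` responds to correlation structure only; mean or variance
gradients cancel. `T = 0` exactly when the models coincide.

The MVN is a working model, not an assumption we rely on: significance is
calibrated by permutation (below), so miscalibration of the MVN costs
sensitivity, never validity. Analytic (asymptotic χ²) p-values are
deliberately out of scope.

## Kernel estimation

All spot-level quantities are region-masked kernel estimates. With
distance `D(s_i, s_j)` and bandwidth `γ`, the weight of spot *j* in spot
*i*'s estimate is `1[c_i = c_j] · K(D(s_i,s_j); γ)`. Kernels:

| family | form | default |
|---|---|---|
| gaussian | `exp(−D/γ)` | γ = 5 |
| triangular | `max(1 − D/γ, 0)` | γ = 8 gives a similar neighbor mass |
| uniform | `1[D < γ]` (boundary excluded) | — |

The Gaussian test kernel decays with the **unsquared** distance — do not
confuse it with the simulator's squared-exponential RBF. The default γ = 5
is calibrated to 10x Visium array row/column coordinates; coordinates are
never rescaled, so users of other platforms (or of precomputed graph
distances, supported through `DistanceProvider`) should set γ in their own
units. Whether Visium's hexagonal geometry rather than array indices should
drive distances is left to the caller; array indices are the default
convention here.

Kernel means use the weighted average of same-region rows; kernel
variances/covariances average residual squares/outer products where **each
contributing spot's residual is taken against its own kernel mean** `μ_j`
(the formula's literal reading; it also makes the covariance a weighted
sum of outer products, hence PSD). Spot *i* is included in its own
estimate, so the weight sum is always ≥ 1.

The weight sum at a spot is its **effective neighbors** — a continuous
neighborhood size. Spots below the threshold (default 10) are removed
before any estimation, and weights are recomputed on the survivors in a
single pass (removal changes every neighborhood; iterating the filter to a
fixed point was considered and rejected as unspecified and rarely
different).

Degenerate genes (zero variance within a scope, detected against a
float-rounding floor) raise errors instead of being dropped: silently
removing a gene would silently change the tested hypothesis.

## Permutation inference

* **WR null**: no spatially varying correlation within a region means the
  region's normalized rows are exchangeable; rows are shuffled within the
  region. All kernel estimates (means, variances, covariances, Pearson
  matrices) are refit on every permuted dataset — nothing is frozen.
* **BR null**: rows are first mean-centered per region (removing the
  between-region mean differences that would otherwise leak into the
  pooled correlation), then residual rows are shuffled across the scope.
  The observed statistic is computed on the same centered data, so the
  identity permutation reproduces it exactly.

P-values use **sequential Monte Carlo (SMC)** early stopping: permutations
are drawn until `t` null statistics reach the observed value, giving
`p = t/l` with `l` the number of draws; if `g − 1` draws pass first,
`p = (u+1)/g` with `u` the exceedance count. Defaults `t = 20`,
`g = 10,000`. Ties count as exceedances — the conservative direction.
Draws are evaluated in chunks for speed but always reduced in draw order,
so results are bit-reproducible from the seed. A Monte-Carlo check of the
stopping rule (uniform nulls) puts its rejection rate at α = 0.05 within
±0.001 of nominal.

Benjamini-Hochberg FDR is applied across regions (WR) or region pairs
(BR). The BR-test is undefined for regions whose correlation already
varies internally, so regions with WR `q < α` (default α = 0.05) are
screened out first; the screen threshold is exposed in `SMCConfig.alpha`.
Gene pairs within a set can be ranked by their minimum per-pair p-value
(`rank_gene_pairs`), ties broken lexicographically.

## Correlation fields, CIs, pattern clustering

`correlation_field` evaluates `r̂_i = cov_i[g,g'] / (σ_i,g σ_i,g')`,
clipped to [−1, 1], at every spot. Bootstrap CIs resample the focal spot's
same-region neighborhood within a fixed radius (default 2γ — the radius is
a free choice; twice the kernel scale covers essentially all the weight
mass) with replacement, recompute the kernel estimate at the focal
location per resample (kernel weights recomputed within each resample, not
reused), and take empirical percentiles. Neighborhoods under 3 spots are
not estimable. Pattern clustering stacks per-pair correlation vectors and
applies hierarchical agglomerative clustering; Euclidean distance with
average linkage is the default (the choice is open — both are exposed as
arguments).

## Simulator

The simulator generates UMI counts with controlled, smoothly varying
latent correlation — the ground truth the tests are benchmarked against.
Counts follow a Poisson-lognormal model: `y_{i,g} ~ Poisson(s_i λ_{i,g})`
with `log λ_i ~ MVN(μ, Σ_i)`, spots independent, and `s_i` a per-spot
exposure (library size). Two latent constructions:

* **pair mode**: Fisher-transformed correlations are a Gaussian-process
  draw, `atanh(r) ~ MVN(0, cK)`, with `K_{ij} = exp(−‖s_i−s_j‖²/γ_sim)`
  and `c` the covariance strength; `σ_{12,i} = r_i σ_1 σ_2` (the only
  reading of the covariance formula that yields a valid matrix).
* **multi-gene mode**: one GP vector `v_g ~ MVN(0, cK)` per gene, stacked
  into `z_i`; `Σ_i = Φ + z_i z_iᵀ` with `Φ` a positive diagonal — PSD by
  construction, smooth elementwise. The construction is zero-mean, so the
  per-region means `μ_g` are added to the draw (without the shift, counts
  could not match per-region marginals). `Φ` defaults to the per-gene
  latent variances.

Defaults (units and rationale):

| parameter | default | meaning |
|---|---|---|
| lattice | 32 × 32 (≈1,000 spots) | benchmark slide; five vertical-band regions |
| γ_sim | 25 (squared-distance units) | GP length ≈ 5 lattice units, matching region scale |
| c | scenario-specific | 0/0.05/0.1/0.2/0.4 span null→strong variation |
| latent σ² | 0.25 | per-gene biological log-variance (CV ≈ 0.5) |
| expression tiers | mean counts 30/15/6/2 | high → low expression at the median library |
| library sizes | lognormal, median 10⁴, log-sd 0.25 | Visium-like depth variation |

Scenario presets: `SimI` (pair, GP field per region; `c=0` is the WR
null), `SimII` (multi-gene GP fields), `SimIII` (pair, constant
within-region correlation, two region groups differing by 0/0.2/0.4/0.8;
0 is the BR null), `SimIV` (multi-gene, one group equicorrelation 0 vs
`diff` in the other — expressed exactly in the rank-one form with
`z_g = σ_g√ρ`, `Φ_g = σ_g²(1−ρ)`), `SimV` (two half-slide regions, no
correlation, strongly differing means — the mean-shift robustness null),
`SimVI` (single region, whole-slide GP field, `c` ∈ {0.025, 0.05, 0.1}).
Region layouts are fixed vertical bands / half-splits / whole slide;
real-tissue cluster geometries require an external sample and are not
emulated.

**Marginal estimation** (`estimate_marginals`) recovers per-region,
per-gene `(μ_g, σ_g²)` from raw counts by a small hierarchical Bayes fit:
normal prior on `μ` centered at the log naive rate (scale 2), half-Cauchy
prior on `σ` truncated to (0, 5] (scale 1), Poisson-lognormal likelihood
integrated per spot by 25-node Gauss-Hermite quadrature, posterior means
taken over a 41 × 41 grid centered at method-of-moments estimates. The
prior hyperparameters are conventions, exposed as keyword arguments.
All-zero genes fall back to the prior center and are flagged. On
self-simulated data (1,200 spots, μ = 1, σ² = 0.25) the posterior means
land within ~1% of truth; the test suite enforces 10%.

`correlation_level_diagnostic` reproduces the calibration procedure for
matching simulated to experimental correlation levels: the variance over
spots of the kernel correlation estimates, tabulated for simulated
replicates against reference gene pairs.

### What the simulator does and does not emulate

It emulates count noise at realistic depths, library-size variation,
region-structured means, and smooth latent correlation fields. It does
**not** emulate hexagonal Visium geometry (square lattice instead),
segmentation errors, spatial autocorrelation of library size, zero
inflation beyond Poisson-lognormal, or real cluster shapes. Passing
benchmarks therefore demonstrate statistical correctness of the tests
under the stated generative model, not performance on any particular
tissue.

## Benchmarks (`spotcorr.benchmarks`)

False-positive rates are the fraction of scope-level p-values below 0.05
over null replicates (SimI `c=0` for WR, SimIII `diff=0` for BR); power is
the fraction of replicate datasets with any scope-level p < 0.05.
Replicates cycle the four expression tiers. Problem sizes: 32 × 32 lattice;
200 replicates for null calibration (`g = 1,000` permutations) and 30 per
power setting (`g = 500` — the p = 0.05 decision needs resolution well
below 0.05, not the full analysis-grade 10,000). The test suite runs the
null calibrations at a further reduced 22 × 23 lattice with 50 replicates.
Measured behavior: WR FPR ≈ 0.04–0.06, BR FPR ≈ 0.04–0.05, WR power
rising steeply from pairs to 4-gene sets at weak correlation, BR power
increasing monotonically with set size at a 0.2 between-group difference —
the exact numbers are recomputed by `scripts/acceptance.py` and the
acceptance tests, never hard-coded.

## Numerical choices

* Covariance stacks get a symmetric diagonal jitter of 1e−10 applied to
  null **and** alternative, preserving `T ≈ 0` under model equality;
  kernel covariances with eigenvalues below −1e−8 × (largest eigenvalue)
  are additionally lifted to a 1e−10 floor.
* MVN log-densities use Cholesky (public scalar path) and batched
  solve/slogdet (statistic engines); singular covariances after jitter
  raise rather than pseudo-invert.
* Degeneracy floor for zero-variance genes: 1e−24 × mean squared
  expression (a constant gene's float residuals sit ~1e−32).
* P/q-values are written with 6 significant digits — SMC resolution is
  bounded by 1/g.
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning; identical seed + config gives bit-identical results, including
  under chunked permutation evaluation.

## Known limitations

* Normalization: the package accepts pre-normalized input and offers only
  an explicit log-CPM fallback (counts per 10k, `log1p`); model-based
  normalization of the input counts is out of scope.
* The WR/BR tests require every tested scope to hold ≥ 3 spots after
  filtering and every gene to be non-degenerate there.
* The BR screen depends on the WR results for the same gene set; a gene
  set whose correlation varies inside every region is not BR-testable.
* Single-slide analysis only; no multi-sample integration.
* Permutation p-values only; no asymptotic reference distribution.
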