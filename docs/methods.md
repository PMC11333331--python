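# Methods

This note records the models implemented in `herbniche`, their
assumptions, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices a maintainer
would want to know about.

## Presence-background maximum entropy

The species distribution model estimates the distribution q over the
background cells that maximises entropy subject to (softly) matching the
presence means of a feature expansion of the covariates. Equivalently, it
maximises the L1-penalised average presence log-likelihood

    G(λ) = (1/m) Σᵢ log q(xᵢ) − Σⱼ βⱼ|λⱼ|,   q(x) = exp(λ·f(x)) / Z.

Assumptions: presences are an unbiased (if noisy) sample of where the
species occurs; covariates are observed at every background cell; the
response is representable by the feature classes below. No attempt is
made to correct sampling bias or detectability.

**Features.** Per variable, scaled to [0, 1] by the training min/max:
linear, quadratic, pairwise products, and forward + reverse hinges on a
fixed grid of 50 knots placed strictly inside (0, 1). Threshold features
are omitted; dense hinges span the same step-like responses with better
regularisation behaviour. At prediction time covariates are clamped to
the training range (no extrapolation of features).

**Regularisation.** βⱼ = r · Λ_class(m) · sⱼ / √m, where m is the
presence count, sⱼ is the presence standard deviation of feature j
(floored at 10⁻³), Λ interpolates the canonical per-class default
schedule over m (linear/quadratic/product: 1.0 at m ≤ 10 down to 0.05 at
m ≥ 100; hinge: 0.5), and r is the user's global multiplier (default 1).

**Optimisation.** The objective is convex; the fit is full-gradient
proximal descent with FISTA momentum, backtracking line search, soft
thresholding for the L1 term, and momentum restart (with step damping)
when a step fails to improve the gain. Stopping: once the per-iteration
gain improvement falls below `tol` (default 1e-5, cap 500 iterations,
matching common practice for this model family), the fit additionally
confirms stationarity via the KKT residual of the L1 problem
(`max(|gradⱼ| − βⱼ, 0)` on inactive weights, `|gradⱼ + sign(λⱼ)βⱼ|` on
active ones) below `tol^0.75` — a single tiny momentum step cannot stop
the fit prematurely. The gain trajectory is non-decreasing by
construction.

**Outputs.** Raw output is q normalised over the training background
(presence rows are duplicated into the background by default, the
conventional setup; switchable). The logistic output is
p = e^H q / (1 + e^H q) with H the entropy of q over the background — a
strictly monotone transform of q, so AUC is identical on either scale.

**Contributions.** The canonical contribution statistic assumes
per-feature sequential updates; this optimiser updates all features at
once, so each accepted iteration's gain increase is attributed to
features in proportion to |Δλⱼ · gradⱼ| (the first-order decomposition of
the step) and mapped to variables, with product features split evenly
between their two variables. Percentages are normalised to 100.

**Replication.** Bootstrap mode permutes the occurrences, takes the
first 75% as the training pool, resamples that pool with replacement to
the same size, and scores the held-out 25% against the background sample
by rank-based AUC (ties ½). The ensemble map is the cell-wise mean of
the replicates' logistic outputs. Defaults follow the standard protocol:
10,000 background points sampled uniformly without replacement from the
jointly valid cells (all cells, with a warning, when fewer exist), 75/25
train/test, 100 replicates.

**Jackknife.** Per variable, a with-only and a leave-one-out model are
refitted; the reported statistic is the unpenalised training gain
(1/m) Σ log q(xᵢ) + ln n_bg, the improvement in average presence
log-probability over a uniform background.

## Variable screening

Pearson correlations are computed on pairwise-complete rows of a seeded
random sample of at most 10,000 valid cells (constant variables are
reported as undefined, not zero). Retention is greedy in descending
contribution order: a variable is kept iff |r| < 0.8 against every
already-kept variable; ties break alphabetically so the outcome is
deterministic, and the drop log names the kept variable that excluded
each dropped one.

## Zoning, areas, and centroid migration

Suitability grades default to the fixed edges 0.2/0.4/0.6
(no/low/medium/high), with intervals left-closed/right-open except the
last (a value exactly on an edge belongs to the upper class). A
data-driven alternative computes optimal Fisher–Jenks natural breaks by
dynamic programming (exact, verified against exhaustive partition search
on small instances); returned breaks are the smallest member of each
upper class, so the same classification convention reproduces the
optimal partition.

Cell areas use a spherical Earth, R = 6371.0 km:
area = (πR/180 · cellsize)² · cos φ at the row's centre latitude. The
suitable range is p ≥ threshold (default 0.04, configurable; thresholds
like 0.4 are equally valid and a matter of study design), its centroid
is the cell-area-weighted mean of cell-centre coordinates, and scenario
displacement is the haversine distance from the *baseline* centroid to
each scenario centroid (not chained between periods), with the initial
great-circle azimuth as bearing. The same spherical radius is used for
areas and distances throughout.

## Fingerprints

Peak detection is local-maxima search (height and prominence thresholds)
with bounds at the flanking signal minima and the area as the trapezoid
of signal minus the straight baseline between the bounds. Retention-time
correction maps each sample's anchor peaks (by default the reference's
five largest, mirroring a five-marker-compound anchor set) onto the
reference axis piecewise-linearly, with constant-offset extrapolation
beyond the outermost anchors; areas are never altered. Common peaks are
the reference peaks matched in every sample within the tolerance
(default 0.2 min). Similarity is the congruence (cosine) coefficient on
common-peak area vectors — the convention of the standard similarity
software for herbal fingerprints — with a Pearson-correlation mode as an
alternative; the matrix is symmetric with unit diagonal by construction.
RSD uses the sample (n−1) standard deviation, the method-validation
convention. Quantification is one-point external standard:
content = area/area_std × conc_std × volume/mass (defaults 50 mL, 1.0 g).

## Environment → quality

Per-compound contents are regressed on site-level ecological factors by
stepwise OLS (directions forward/backward/both; criterion AIC by default,
BIC available — BIC is the appropriate choice when the question is
whether *any* factor matters, since AIC admits each spurious factor with
probability ≈ 0.16). The search stops when no single add/remove improves
the criterion, skips rank-deficient candidate designs with a warning,
and stops early once the fit is numerically exact (zero residual), where
further likelihood gains are meaningless. Compound×factor Pearson
correlations carry two-sided t-test p-values with 0.05/0.01 stars.

Predicted content surfaces (β·x + intercept, negatives floored at zero
and counted) are min–max normalised over the suitable region
(suitability ≥ 0.2 by default, i.e. everything above "no suitability")
and combined as an unweighted mean — the simplest order-free choice,
configurable with per-compound weights, since no canonical combination
rule exists. Cynaroside is excluded from the default overlay (no clear
environmental signal). The combined score is graded by Jenks into four
classes; a constant content surface scores 0.5 by convention, and cells
below the suitability threshold are nodata in both score and grade maps.

## Synthetic generators

Environmental layers are mean-0, sd-1 Gaussian random fields (spectral
synthesis with a Gaussian kernel; correlation length in cells), mixed
through the Cholesky factor of a target cross-correlation matrix. The
default seven-layer scene (bio4, bio6, bio12, elev, s_oc, srad2, srad4)
plants moderate collinearity (bio4–bio6 −0.4, srad2–srad4 0.6,
bio12–s_oc 0.3) to exercise screening.

Occurrences follow a logistic law p = σ(β₀ + β·x) with defaults
β = {bio6: 2.5, bio12: 1.5, bio4: −0.8} and β₀ = −5. The intercept
matters: with β₀ = 0 half the landscape is suitable and the achievable
AUC of *any* model is capped near 0.75; β₀ = −5 restricts the species to
roughly a tenth of the landscape, giving the generating law itself an
AUC near 0.89 — the discriminability of a real specialist range model.
Cells are drawn with probability ∝ p and points jittered uniformly
within the cell; the default 298 presences match a realistic
national-scale occurrence compilation.

Chromatograms are sums of Gaussian peaks over a 50-minute run plus
linear drift and white noise; the fingerprint scene plants 21 shared
peaks (≥ 1 min apart) with log-normal area variation, small per-sample
retention shifts, and per-sample spurious peaks across 11 samples.
Contents are linear in the environment plus Gaussian noise, floored at
zero.

What the generators do **not** emulate: real bioclimatic marginal
distributions and spatial trends, sampling bias and spatial clustering
of occurrence records, chromatographic tailing/co-elution/baseline
artefacts, and measurement error structure in compound quantification.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated statistical structure, not performance on
real survey data.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng(seed)`; outputs
are bit-reproducible given a seed. The recovery experiments in the test
suite and the acceptance script run on scaled-down scenes chosen as the
package's own test-scene sizes — 60×60 grids (3,600 background cells,
which is the full valid-cell set, taken deterministically), 298
presences, 5 bootstrap replicates, 20 stepwise replications — keeping
the full chain's runtime around half a minute while leaving every
statistical conclusion (driver ranking, AUC level, recovery rates)
stable across seeds. The pipeline defaults remain the full-size settings
(100 replicates, 10,000 background points, 500 iterations, tol 1e-5).

## Known limitations

- No clamping/novel-climate (MESS) diagnostics and no categorical
  features; covariates outside the training range are clamped silently.
- No reprojection or resampling: all rasters must share one
  geographic grid.
- Fisher–Jenks is exact but O(k·n²); for large rasters the grading is
  applied to the scored cells directly (fine up to ~10⁵ values), not to
  a subsample.
- The stepwise quality models are ordinary least squares on
  spatially-indexed data; spatial autocorrelation of residuals is not
  modelled, so p-values at clustered sites are optimistic.
- One permutation per variable (the conventional default) makes
  permutation importance noisy for weak variables; increase
  `n_repeats` for stable estimates.
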