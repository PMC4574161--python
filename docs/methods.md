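# Methods

This note documents the models, priors, numerical choices and limitations
of `macrogen`.  Notation follows the README.

## Data model and filtering

A record is one population × one study × one marker: diversity `H` in
[0, 1], sample size `n ≥ 5`, five non-empty Linnaean ranks, one of six
marker categories (mtDNA sequence, mtDNA restriction, allozyme,
microsatellite, nuclear sequence, other), coordinates and a region id.
Records are grouped by `dataID` (study × marker).  Regional filtering
(`filter_regions`) keeps a set of regions — typically the coastal ones —
and then drops any dataID left with fewer than 3 populations, the minimum
for a meaningful within-study contrast.  All categorical indices (regions,
species, dataIDs, marker levels) are sorted lexicographically so design
matrices are reproducible byte-for-byte.

Boundary diversity values (exactly 0 or 1) are incompatible with a beta
likelihood.  They are compressed with `(y (n−1) + 0.5)/n` **only at the
boundary**, using the population's own sample size; interior values are
never touched.  (Compressing all values would shrink logit-scale
coefficients and — because the compression depends on `n` — bias the
dispersion sub-model.)  Raw values are preserved in the dataset; the
transform is applied when the beta likelihood is built.

## Standardisation (Z family)

`z = (H − mean(H)) / sd(H)` within each dataID, with the sample (n−1)
standard deviation.  Groups with one member or zero variance have no
defined z-score; they are excluded and reported in a skip list rather than
imputed.  Z-scoring removes study- and marker-level location, which is why
the Gaussian ladder carries no marker term.

## Species prior from taxonomy

Without a dated phylogeny, species similarity is read off the Linnaean
classification.  The ranked tree (unary rank nodes collapsed — they change
no ancestor relations) gets Grafen heights: each internal node at
`(descendant tips − 1)/(T − 1)`, root 1, tips 0, optionally raised to a
power `rho` (default 1).  Under Brownian motion the tip correlation is the
shared root-to-ancestor depth, `1 − height(MRCA)`.  The species effect
prior is `S ~ MVN(0, sigma_S^2 C)` with a Half-Normal(1) hyperprior on
`sigma_S`; the scale is separated from the correlation so the data decide
how much species-level pooling occurs.

## Spatial prior

Region effects carry an intrinsic CAR prior with precision
`tau_R (D − W)`, where `W` is a symmetric nonnegative adjacency-weight
matrix (e.g. shared-boundary extent) and `D` its row-sum diagonal.  The
prior is improper — flat along the constant vector of each connected
component — so effects are kept sum-to-zero and the mean is carried by the
intercept.  `tau_R` has a vague Gamma(0.5, 0.0005) prior and a conjugate
Gibbs update.  A path-graph fixture stands in for coastal adjacency
(regions ordered along the coast); any user-supplied `W` is accepted, and
isolated regions are an error unless an independent-normal fallback is
requested.

## Likelihoods and dispersion

Beta family: `H_i ~ Beta(mu_i delta_i, (1−mu_i) delta_i)` so `E H = mu`
and `Var H = mu(1−mu)/(1+delta)`.  Sample size enters the dispersion as
`log delta_i = gamma_0 + gamma_1 log n_i` (log n centered internally for
sampler stability; `gamma_1` is unaffected) — a log-log form keeps `delta`
positive and scale-stable, so better-sampled populations can have less
noisy diversity estimates.  The Gaussian family mirrors this with
`log sigma_i = gamma_0 + gamma_1 log n_i`; with `gamma_1 = 0` it reduces
to a homoskedastic linear mixed model.

Fixed effects and dispersion coefficients have Normal(0, 10²) priors.
Latitude is centered and scaled to unit sd *before* squaring, so both
latitude coefficients are O(1) and only mildly correlated.

## Sampler

Posterior exploration uses adaptive random-walk Metropolis-within-Gibbs
(numba-compiled): scalar updates for each fixed effect and dispersion
coefficient (full-likelihood), each species effect and each region effect
(likelihood restricted to that group's rows; prior increments via one
precision row), a scalar update for `log sigma_S`, and a conjugate Gibbs
draw for `tau_R`.  Proposal scales adapt toward 44% acceptance during
burn-in only, so retained draws come from a valid Markov chain.

Three structural moves matter for this posterior's geometry:

* **Region recentring** — the mean of `R` is shifted into the intercept
  (likelihood- and CAR-invariant; accepted by the intercept prior ratio).
* **Ridge moves** — region effects and the latitude coefficients are
  partially confounded (a latitude-patterned component of `R` mimics the
  latitude terms).  A joint proposal adds `dz ×` (per-region mean latitude
  pattern, linear or squared) to `R` while subtracting `dz` from the
  corresponding coefficient, traversing the ridge that single-site updates
  cannot.
* **Species-mean shift** — the mean of `S` trades against the intercept.

Chains start overdispersed (all blocks jittered) so between-chain R-hat
can detect any direction that still mixes slowly.  Everything is
deterministic given the seed; two runs with equal seeds produce identical
draws.  Default ("desk") settings are 2 chains × 4000 iterations (burn-in
1000, thin 3); `study-test` (3 × 100k, burn-in 5k, thin 100) and
`study-final` (3 × 500k, burn-in 50k, thin 100) presets reproduce the long
schedules used for real-data runs.  The fit warns — without failing — when
any parameter's R-hat exceeds 1.1.

## Model assessment

DIC uses the classic decomposition `Dbar + pD` with `Dhat` evaluated at
the posterior mean of all parameters; DIC weights are
`100 · exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.  PPP simulates a replicate response per
retained draw and reports the fraction whose discrepancy reaches the
observed one; the default discrepancy is the response standard deviation
(sensitive to the dispersion structure), with `mean` and a chi-square-style
standardised residual sum also available.  Values outside (0.05, 0.95) are
flagged as model-data contradiction.  R-hat uses the two-variance
Brooks–Gelman–Rubin form, floored at 1 (sub-1 values are finite-sample
noise).

Cross-model regional agreement is summarised by the **adjusted** squared
Pearson correlation of regional means, `1 − (1 − r²)(n−1)/(n−2)` — the
convention of standard regression summaries, which published comparisons
of this kind report — restricted to regions with at least a minimum number
of populations in the restricting subset; the raw `r²` and the two-sided
p-value are also returned.

## Co-sampling clustering

Regions (rows) × species (columns) presence/absence; regions with fewer
than five species dropped.  Ward's minimum-variance agglomeration runs on
squared Euclidean distances via the Lance–Williams update with merge
heights square-rooted afterwards, so heights are on the distance scale and
guaranteed monotone.  Ties break toward the smallest row-index pair,
making output deterministic; the implementation is cross-checked against
an independent brute-force agglomerator and against scipy's Ward linkage
in the test suite.

## Synthetic data

The generator is the generative mirror of the beta model at the coastal
scale (defaults: 84 species, 959 populations, 17 chain-adjacent regions,
marker frequencies allozyme 32.8%, microsatellite 31.4%, mtDNA sequence
23.5%, mtDNA restriction 8.0%, nuclear 1.2%, other 2.9%).  Species get
random ranked taxonomies with geometric clade sizes; species effects are
drawn from the Brownian correlation at `sigma_S = 0.5`.  Studies (dataIDs)
are blocks of ≥ 3 populations placed in a contiguous window of regions —
species ranges are contiguous along a coast — with latitude = region
centre ± jitter on a −9.4° to −43.7° gradient, so region and latitude are
correlated but separable.  Default fixed effects use a latitudinal hump
(latitude +0.558, latitude² −0.920 on the standardized scale, matching the
magnitudes reported for the system this emulates) and marker offsets with
microsatellites most diverse and allozymes least.

Truth region effects are drawn from the intrinsic CAR via its spectral
pseudo-inverse and then **projected off the regional constant/linear/
quadratic latitude patterns** before rescaling to a marginal sd of 0.3.
Unprojected intrinsic-CAR draws on a path graph are dominated by the
smoothest eigenmodes and are therefore nearly collinear with latitude in
every replicate, which would make "region" and "latitude" formally
indistinguishable; the projection encodes the scientific meaning of the
region term — regional deviations *net of* the latitudinal trend — at the
spread seen in regional summaries of comparable data.

What the generator does **not** emulate: real marker-specific error
distributions, uneven study quality, spatial gaps, cryptic species, or any
sequence-level process (diversity is simulated at the summary-statistic
level the models consume).  Passing recovery/calibration tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to real-data misspecification.

## Experiment scales

Reduced-scale experiments (tests and acceptance script) use 20 species /
160 populations / 17 regions with 2 chains × 8000 iterations (burn-in
3000, thin 5): 100 replicates for latitude-coefficient coverage and PPP
calibration, 10 replicates of the six-model beta ladder for selection
consistency, and one full-scale run (84 / 959) for sign recovery.  These
sizes give stable results while keeping the whole suite in a few minutes
on one CPU.

## Numerical choices and degenerate inputs

* Species correlation inverted with a 1e-8 diagonal jitter; PSD verified
  (eigenvalues ≥ −1e-10) at construction.
* Beta likelihood guards `a, b > 0` and rejects non-finite proposals; a
  non-finite overdispersed start falls back to a flat start.
* Marker dummy columns are built only for categories present in the data;
  singular designs raise immediately.
* `dic_weights` subtracts the minimum DIC before exponentiating.
* Degenerate posterior draws (zero variance) give `pD = 0` and R-hat 1.

## Known limitations

* The region term's posterior is only weakly separated from latitude when
  adjacency is a chain; inference about "region vs latitude" leans on the
  CAR prior.  This mirrors the scientific reality that a smooth coastal
  gradient is observationally close to a latitudinal one.
* Table-3-style regional "means" are reported as region *effects* on the
  linear-predictor scale (logit for the beta family), not back-transformed
  fitted diversities; the choice is documented here because published
  tables of this kind are ambiguous between the two.
* DIC with `Dhat` at the posterior mean can misbehave for strongly
  non-Gaussian marginals; WAIC/LOO are deliberately out of scope.
* No GIS: region membership must be supplied, and the shipped adjacency is
  a chain fixture, not true shared-boundary lengths.
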