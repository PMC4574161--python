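# macrogen

Bayesian meta-analysis of multi-species population genetic diversity across
marine bioregions.

## The problem

Population genetic surveys report within-species diversity — expected
heterozygosity `H_E` for nuclear markers, haplotype diversity `h` for
mitochondrial ones, both on [0, 1] — one value per sampled population.
Pooling hundreds of such values across species, genetic markers and studies
makes it possible to ask a macrogenetic question: *which regions of a
seascape harbour systematically high or low within-species diversity, and
how much of the pattern is latitude rather than region?*  Doing this
honestly requires dealing with three kinds of heterogeneity at once:
markers differ in typical diversity, related species resemble each other,
and neighbouring regions are spatially autocorrelated.

`macrogen` implements the full pipeline for this question, aimed at the
Australian coastal setting (17 coastal bioregions ordered along the coast,
latitudes from about −9.4° to −43.7°): data validation and filtering,
within-study standardisation, two Bayesian mixed-model families, model
selection and checking, regional posterior summaries, a region co-sampling
cluster analysis, and a synthetic-data generator with ground truth so every
stage is testable without any data download.

## The models

For population *i* with diversity `H_i`, species `s(i)`, region `r(i)`,
sample size `n_i` and design row `X_i` (intercept, marker dummies with
allozyme as reference, standardized latitude and latitude squared):

**Beta family (raw diversity, "H"):**

    H_i ~ Beta(a_i, b_i),   a_i = mu_i * delta_i,   b_i = (1 - mu_i) * delta_i
    logit(mu_i)  = X_i beta + R_{r(i)} + S_{s(i)}
    log(delta_i) = gamma_0 + gamma_1 * log n_i

**Gaussian family (within-study z-scores, "Z"):**

    Z_i ~ Normal(m_i, sigma_i^2),   m_i = X_i beta + R_{r(i)} + S_{s(i)}
    log(sigma_i) = gamma_0 + gamma_1 * log n_i

with two structured random effects:

* **Species** `S ~ MVN(0, sigma_S^2 C)`, where `C` is the Brownian-motion
  correlation implied by the Linnaean taxonomy (class/order/family/genus/
  species) under Grafen branch lengths: `C[i,j] = 1 - height(MRCA(i,j))`.
* **Region** `R` with an intrinsic CAR prior on the region-adjacency graph:
  precision `tau_R (D - W)`, sum-to-zero constrained.

Each family is fitted over a six-model ladder (adding latitude, latitude²
and region terms) by an adaptive Metropolis-within-Gibbs sampler; models
are compared by DIC and DIC weights and checked with posterior predictive
p-values (PPP) and Brooks–Gelman–Rubin R-hat.  Region co-sampling (which
regions were surveyed for the same species) is summarised by Ward
minimum-variance clustering of binary region×species profiles with squared
input distances and square-rooted output heights.

## Worked example

```python
import numpy as np
import macrogen as mg
from macrogen.models import ModelSpec, fit, McmcSettings, regional_summary
from macrogen.evaluation import dic, posterior_predictive_p

graph = mg.chain_adjacency_fixture(17)          # coastal chain adjacency
ds, truth = mg.simulate_dataset(n_species=20, n_populations=160,
                                n_regions=17, graph=graph, seed=42)

spec = ModelSpec("H", include_latitude=True, include_latitude_sq=True,
                 include_region=True)           # S + M + n + L + L2 + R
samples = fit(ds, spec, mcmc=McmcSettings(chains=2, iterations=8000,
                                          burnin=3000, thin=5),
              seed=0, region_graph=graph)

bl, bl2 = samples.get("latitude").ravel(), samples.get("latitude_sq").ravel()
print(bl.mean(), np.quantile(bl, [0.025, 0.975]))
print(dic(samples).dic, posterior_predictive_p(samples, seed=1))
print(regional_summary(samples).head(4).round(3))
```

prints (seed 42 / 0 as above):

```
beta_lat  post mean 0.701  95% CI [0.175, 1.467]   (truth 0.558)
beta_lat2 post mean -0.776  95% CI [-1.067, -0.407] (truth -0.920)
DIC -193.1  (pD 20.7)
PPP 0.395
         mean     sd   q2.5  q97.5  significant  n_pops  low_support
region
25     -0.938  0.846 -2.843  0.319        False       4         True
26     -0.903  0.749 -2.584  0.204        False      10        False
27     -0.460  0.570 -1.763  0.435        False       5         True
28      0.043  0.403 -0.839  0.792        False      15        False
```

The latitude coefficients recover the simulated "hump" (positive latitude,
negative latitude² on the standardized scale) within their credible
intervals; the PPP near 0.5 says replicate data from the fitted model look
like the observed data; `regional_summary` flags regions whose effect's 95%
interval excludes zero and regions with fewer than 10 sampled populations.

A command-line interface mirrors the library:
`macrogen simulate | ladder | cluster | weights | crosscorr`.

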