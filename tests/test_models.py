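import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import macrogen as mg
from macrogen.models import (
    BetaDiversityModel,
    McmcSettings,
    ModelSpec,
    design_matrix,
    eta_from_params,
    fit,
    h_ladder,
    log_joint_beta,
    loglik_at,
    regional_summary,
    z_ladder,
    _prepare,
    _param_names,
)
from macrogen.records import from_frame
from macrogen.standardize import add_zscores
from macrogen.synthetic_data import SimulationTruth, simulate_dataset
from conftest import SP_A, toy_frame


def test_model_spec_invariants():
    with pytest.raises(ValueError):
        ModelSpec("H", include_latitude=False, include_latitude_sq=True)
    assert ModelSpec("H").include_marker
    assert not ModelSpec("Z").include_marker
    names = [s.name for s in h_ladder()]
    assert names == ["S + M + n", "S + M + n + L", "S + M + n + L + L2",
                     "S + M + n + R", "S + M + n + L + R", "S + M + n + L + L2 + R"]
    znames = [s.name for s in z_ladder()]
    assert all("M" not in n for n in znames)
    assert len(set(znames)) == 6


def test_design_matrix_reference_level_and_scaling(small_sim):
    ds, _ = small_sim
    spec = ModelSpec("H", include_latitude=True, include_latitude_sq=True)
    X, names, scaling = design_matrix(ds, spec)
    assert names[0] == "intercept"
    assert not any("allozyme" in n for n in names)  # reference level dropped
    lat_col = X[:, names.index("latitude")]
    assert abs(lat_col.mean()) < 1e-10
    assert lat_col.std(ddof=0) == pytest.approx(1.0)
    np.testing.assert_allclose(X[:, names.index("latitude_sq")], lat_col ** 2)
    assert np.linalg.matrix_rank(X) == X.shape[1]


def _tiny_beta_md():
    rows = [
        ("a:m", SP_A, "allozyme", -20.0, "25", 10, 0.62),
        ("a:m", SP_A, "allozyme", -25.0, "25", 20, 0.55),
        ("a:m", SP_A, "allozyme", -30.0, "26", 15, 0.71),
        ("a:m", SP_A, "allozyme", -35.0, "26", 30, 0.50),
        ("a:m", SP_A, "allozyme", -40.0, "26", 12, 0.44),
    ]
    ds = from_frame(toy_frame(rows))
    spec = ModelSpec("H")
    md = _prepare(ds, spec, None, 1e-8)
    return md, _param_names(md)


def test_beta_loglik_uniform_density_is_zero():
    # a single H = 0.5 observation with mu = 0.5, delta = 2 is Beta(1, 1)
    md, names = _tiny_beta_md()
    md.y = np.array([0.5])
    md.X = np.ones((1, 1))
    md.colnames = ["intercept"]
    md.sp_idx = np.zeros(1, dtype=np.int64)
    md.logn_c = np.zeros(1)
    theta = np.zeros(len(["intercept"] + [f"S[{s}]" for s in md.species]) + 4)
    names = ["intercept"] + [f"S[{s}]" for s in md.species] + \
        ["gamma0", "gamma1", "sigma_S", "tau_R"]
    theta[names.index("gamma0")] = np.log(2.0)
    theta[names.index("sigma_S")] = 1.0
    assert loglik_at(md, theta, names) == pytest.approx(0.0, abs=1e-12)


def test_beta_loglik_matches_per_term_oracle():
    md, names = _tiny_beta_md()
    rng = np.random.default_rng(2)
    theta = np.zeros(len(names))
    theta[0] = 0.3
    theta[names.index("S[Pagrus auratus]")] = 0.2
    theta[names.index("gamma0")] = 1.2
    theta[names.index("gamma1")] = 0.4
    theta[names.index("sigma_S")] = 0.7
    theta[names.index("tau_R")] = 1.0
    got = loglik_at(md, theta, names)
    # independent per-observation sum with scipy.stats.beta
    eta = md.X @ theta[:md.X.shape[1]] + 0.2
    mu = expit(eta)
    delta = np.exp(1.2 + 0.4 * md.logn_c)
    expect = sum(
        stats.beta.logpdf(y, m * d, (1 - m) * d)
        for y, m, d in zip(md.y, mu, delta)
    )
    assert got == pytest.approx(expect, rel=1e-10)


def test_log_joint_region_shift_invariance(small_sim, chain17):
    ds, _ = small_sim
    spec = ModelSpec("H", include_region=True)
    md = _prepare(ds, spec, chain17, 1e-8)
    names = _param_names(md)
    rng = np.random.default_rng(0)
    theta = rng.normal(0, 0.1, len(names))
    theta[names.index("sigma_S")] = 0.5
    theta[names.index("tau_R")] = 2.0
    lj = log_joint_beta(md, theta, names)
    assert np.isfinite(lj)
    # shifting region effects by +c and the intercept by -c leaves the
    # likelihood and CAR prior unchanged; only the intercept prior moves
    theta2 = theta.copy()
    nr = len(md.region_ids)
    p = md.X.shape[1]
    ns = len(md.species)
    c = 0.37
    theta2[p + ns:p + ns + nr] += c
    theta2[0] -= c
    ll1 = loglik_at(md, theta, names)
    ll2 = loglik_at(md, theta2, names)
    assert ll2 == pytest.approx(ll1, rel=1e-10)


def test_fit_determinism(small_sim, chain17):
    ds, _ = small_sim
    spec = ModelSpec("H", include_latitude=True, include_region=True)
    mc = McmcSettings(chains=2, iterations=1500, burnin=500, thin=2)
    s1 = fit(ds, spec, mcmc=mc, seed=5, region_graph=chain17)
    s2 = fit(ds, spec, mcmc=mc, seed=5, region_graph=chain17)
    np.testing.assert_array_equal(s1.params, s2.params)
    np.testing.assert_array_equal(s1.loglik, s2.loglik)
    s3 = fit(ds, spec, mcmc=mc, seed=6, region_graph=chain17)
    assert not np.array_equal(s1.params, s3.params)


def test_estimator_sklearn_protocol(small_sim, chain17):
    ds, _ = small_sim
    est = BetaDiversityModel(include_latitude=True, include_region=True,
                             mcmc=McmcSettings(chains=2, iterations=1500,
                                               burnin=500, thin=3), seed=1)
    params = est.get_params()
    assert params["include_latitude"] and params["seed"] == 1
    est.set_params(seed=2)
    est.fit(ds, region_graph=chain17)
    assert hasattr(est, "samples_") and hasattr(est, "dic_")
    mu = est.predict(ds)
    assert mu.shape == (len(ds),)
    assert np.all((mu > 0) & (mu < 1))


def test_beta_dispersion_moments():
    # Beta(mu delta, (1-mu) delta): mean mu, var mu(1-mu)/(1+delta)
    rng = np.random.default_rng(17)
    for mu in (0.2, 0.5, 0.8):
        for delta in (2.0, 10.0, 50.0):
            draws = rng.beta(mu * delta, (1 - mu) * delta, size=100_000)
            se_mean = draws.std() / np.sqrt(draws.size)
            assert abs(draws.mean() - mu) < 3 * se_mean
            target_var = mu * (1 - mu) / (1 + delta)
            assert draws.var() == pytest.approx(target_var, rel=0.05)


def test_gaussian_model_reduces_to_least_squares():
    tr = SimulationTruth(region_scale=0.0, sigma_s=0.01)
    ds, _ = simulate_dataset(12, 100, 8, truth=tr, seed=11)
    dz, _ = add_zscores(ds)
    spec = ModelSpec("Z", include_latitude=True)
    s = fit(dz, spec, mcmc=McmcSettings(chains=2, iterations=6000,
                                        burnin=2000, thin=4), seed=3)
    lat = dz.df["lat"].to_numpy()
    X = np.column_stack([np.ones(len(dz)), (lat - lat.mean()) / lat.std(ddof=0)])
    b_ols = np.linalg.lstsq(X, dz.df["z"].to_numpy(), rcond=None)[0]
    bl = s.get("latitude").ravel()
    assert abs(bl.mean() - b_ols[1]) < 2 * bl.std()


def test_missing_z_column_errors(small_sim):
    ds, _ = small_sim
    with pytest.raises(ValueError, match="z column"):
        fit(ds, ModelSpec("Z"), mcmc=McmcSettings(chains=2, iterations=200,
                                                  burnin=100, thin=1), seed=0)


def test_region_spec_needs_graph(small_sim):
    ds, _ = small_sim
    with pytest.raises(ValueError, match="RegionGraph"):
        fit(ds, ModelSpec("H", include_region=True), seed=0)


def test_regional_summary_flags(fitted_full_h):
    samples, _ = fitted_full_h
    tab = regional_summary(samples)
    assert len(tab) == 17
    assert set(["mean", "sd", "q2.5", "q97.5", "significant", "n_pops",
                "low_support"]) <= set(tab.columns)
    # significance flag matches the interval by definition on real draws
    for r, row in tab.iterrows():
        assert row["significant"] == (row["q2.5"] > 0 or row["q97.5"] < 0)
    # quantile oracle on raw draws
    r0 = samples.data.region_ids[0]
    draws = samples.get(f"R[{r0}]").ravel()
    np.testing.assert_allclose(
        [tab.loc[r0, "q2.5"], tab.loc[r0, "q97.5"]],
        np.quantile(draws, [0.025, 0.975]), rtol=1e-12)
    # degenerate constant draws: mean, zero sd, significant
    import dataclasses
    frozen = dataclasses.replace(samples, params=samples.params.copy())
    frozen.params[:, :, frozen.param_names.index(f"R[{r0}]")] = 0.5
    tab2 = regional_summary(frozen)
    assert tab2.loc[r0, "mean"] == pytest.approx(0.5)
    assert tab2.loc[r0, "sd"] == 0.0
    assert bool(tab2.loc[r0, "significant"])


def test_regional_summary_requires_region_term(small_sim):
    ds, _ = small_sim
    s = fit(ds, ModelSpec("H"), mcmc=McmcSettings(chains=2, iterations=600,
                                                  burnin=200, thin=2), seed=0)
    with pytest.raises(ValueError):
        regional_summary(s)


def test_null_region_effects_mostly_cover_zero(chain17):
    # data simulated without regional signal: the fitted region effects'
    # 95% intervals should include 0 for nearly all regions
    tr = SimulationTruth(region_scale=0.0)
    ds, _ = simulate_dataset(20, 160, 17, truth=tr, seed=77)
    spec = ModelSpec("H", include_latitude=True, include_latitude_sq=True,
                     include_region=True)
    s = fit(ds, spec, mcmc=McmcSettings(chains=2, iterations=8000,
                                        burnin=3000, thin=5),
            seed=78, region_graph=chain17)
    tab = regional_summary(s)
    assert (~tab["significant"]).sum() >= 15
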