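import numpy as np
import pytest

from macrogen.evaluation import (
    dic,
    dic_weights,
    gelman_rubin,
    posterior_predictive_p,
    ppp_flag,
)
from macrogen.models import McmcSettings, ModelData, ModelSpec, PosteriorSamples, PriorConfig


def _gaussian_samples(params, loglik, names, md):
    return PosteriorSamples(
        params=params, param_names=names, loglik=loglik, data=md,
        settings=McmcSettings(), priors=PriorConfig(), seed=0)


def _normal_mean_model(n=40, sigma=1.0, seed=0):
    """Conjugate normal-mean toy wrapped in the Gaussian model's containers."""
    rng = np.random.default_rng(seed)
    y = rng.normal(1.3, sigma, size=n)
    md = ModelData(
        spec=ModelSpec("Z"), y=y, X=np.ones((n, 1)), colnames=["intercept"],
        sp_idx=np.zeros(n, dtype=np.int64), reg_idx=None,
        logn_c=np.zeros(n), logn_center=0.0, species=["sp"],
        region_ids=None, scaling={}, n_pops_per_region=None,
        Cs=np.eye(1), car=None)
    names = ["intercept", "S[sp]", "gamma0", "gamma1", "sigma_S", "tau_R"]
    return md, names, y


def test_dic_degenerate_posterior_has_zero_pd():
    md, names, y = _normal_mean_model()
    theta = np.zeros(len(names))
    theta[0] = y.mean()
    params = np.tile(theta, (2, 100, 1))
    from macrogen.models import loglik_at
    ll = loglik_at(md, theta, names)
    lls = np.full((2, 100), ll)
    s = _gaussian_samples(params, lls, names, md)
    res = dic(s)
    assert res.pd == pytest.approx(0.0, abs=1e-9)
    assert res.dic == pytest.approx(res.dhat)


def test_dic_effective_parameters_conjugate_oracle():
    # flat-prior normal mean with known sigma: posterior mu ~ N(ybar, s^2/n);
    # pD converges to 1 (one effective parameter)
    md, names, y = _normal_mean_model(n=60, sigma=1.0, seed=4)
    n = len(y)
    rng = np.random.default_rng(9)
    mus = y.mean() + rng.standard_normal((2, 40_000)) / np.sqrt(n)
    params = np.zeros((2, 40_000, len(names)))
    params[:, :, 0] = mus
    # per-draw log-likelihood of the same model (sigma known = 1, gamma0 = 0)
    resid2 = ((y[None, None, :] - mus[..., None]) ** 2).sum(axis=-1)
    lls = -0.5 * n * np.log(2 * np.pi) - 0.5 * resid2
    s = _gaussian_samples(params, lls, names, md)
    res = dic(s)
    assert res.pd == pytest.approx(1.0, abs=0.1)


def test_dic_recomputation_from_exported_draws(fitted_full_h):
    samples, _ = fitted_full_h
    res = dic(samples)
    # independent recomputation from the exported draw table
    from macrogen.models import loglik_at
    dbar = float(np.mean(-2.0 * samples.loglik))
    theta_bar = samples.to_frame().mean(axis=0).to_numpy()
    dhat = -2.0 * loglik_at(samples.data, theta_bar, samples.param_names)
    assert res.dbar == pytest.approx(dbar, abs=1e-8)
    assert res.dic == pytest.approx(dbar + (dbar - dhat), abs=1e-8)


def test_dic_weights_stability_properties():
    base = np.array([100.0, 102.0, 110.0])
    w = dic_weights(base)
    assert w.sum() == pytest.approx(100.0, abs=1e-9)
    np.testing.assert_allclose(dic_weights(base + 1e6), w, atol=1e-9)
    # adding an irrelevant model leaves the others unchanged to 4 decimals
    w4 = dic_weights(np.append(base, 1e5))
    np.testing.assert_allclose(w4[:3], w, atol=1e-4)
    assert dic_weights([42.0])[0] == pytest.approx(100.0)
    with pytest.raises(ValueError):
        dic_weights([np.nan, 1.0])
    with pytest.raises(ValueError):
        dic_weights([])


def test_ppp_requires_draws_and_known_discrepancy(fitted_full_h):
    samples, _ = fitted_full_h
    with pytest.raises(ValueError, match="discrepancy"):
        posterior_predictive_p(samples, discrepancy="median")
    with pytest.raises(ValueError, match="draws"):
        posterior_predictive_p(samples, min_draws=10 ** 9)


def test_ppp_extreme_when_observed_impossible(fitted_full_h):
    import dataclasses

    samples, _ = fitted_full_h
    md = samples.data
    # constant observed response: sd discrepancy far below any replicate
    md2 = dataclasses.replace(md, y=np.full_like(md.y, 0.537))
    s2 = dataclasses.replace(samples, data=md2)
    p = posterior_predictive_p(s2, discrepancy="sd", seed=3)
    assert p > 0.99
    assert ppp_flag(p)


def test_ppp_reasonable_for_self_consistent_fit(fitted_full_h):
    samples, _ = fitted_full_h
    p = posterior_predictive_p(samples, seed=11)
    assert 0.0 <= p <= 1.0
    assert not ppp_flag(p)
    p_mean = posterior_predictive_p(samples, discrepancy="mean", seed=11)
    assert 0.0 <= p_mean <= 1.0


def test_gelman_rubin_identical_chains_is_one():
    md, names, y = _normal_mean_model()
    draws = np.random.default_rng(1).standard_normal((1, 200, len(names)))
    params = np.repeat(draws, 3, axis=0)
    s = _gaussian_samples(params, np.zeros((3, 200)), names, md)
    rh = gelman_rubin(s)
    for v in rh.values():
        assert v == pytest.approx(1.0, abs=1e-12)


def test_gelman_rubin_offset_chains_large():
    md, names, y = _normal_mean_model()
    rng = np.random.default_rng(2)
    params = rng.standard_normal((2, 300, len(names)))
    params[1, :, 0] += 100.0
    s = _gaussian_samples(params, np.zeros((2, 300)), names, md)
    rh = gelman_rubin(s)
    assert rh["intercept"] > 10


def test_gelman_rubin_matches_textbook_formula():
    md, names, _ = _normal_mean_model()
    rng = np.random.default_rng(3)
    params = rng.standard_normal((4, 250, len(names)))
    s = _gaussian_samples(params, np.zeros((4, 250)), names, md)
    rh = gelman_rubin(s)
    m, n = 4, 250
    for j, name in enumerate(names):
        x = params[:, :, j]
        W = x.var(axis=1, ddof=1).mean()
        B = n / (m - 1) * ((x.mean(axis=1) - x.mean()) ** 2).sum()
        expect = max(np.sqrt(((n - 1) / n * W + B / n) / W), 1.0)
        assert rh[name] == pytest.approx(expect, rel=1e-12)


def test_gelman_rubin_single_chain_errors():
    md, names, _ = _normal_mean_model()
    params = np.zeros((1, 50, len(names)))
    s = _gaussian_samples(params, np.zeros((1, 50)), names, md)
    with pytest.raises(ValueError):
        gelman_rubin(s)
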