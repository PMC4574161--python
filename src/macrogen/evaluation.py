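"""Model assessment: DIC, DIC weights, posterior predictive p-values, R-hat.

DIC follows the classic decomposition: Dbar is the posterior mean deviance
(-2 log-likelihood averaged over draws), Dhat the deviance at the posterior
mean of the parameters, pD = Dbar - Dhat the effective number of parameters,
and DIC = Dbar + pD.  DIC weights transform a set of DICs into relative
support exactly as AIC weights do: w_i = exp(-Delta_i / 2) normalised, here
reported in percent.  Posterior predictive p-values simulate replicate
datasets from the fitted likelihood, draw by draw, and report the fraction
whose discrepancy reaches the observed one; values near 0 or 1 flag misfit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DicResult:
    dbar: float
    dhat: float
    pd: float
    dic: float


@dataclass
class ModelComparison:
    """Per-model DIC / delta / weight / PPP table for one response family."""

    table: pd.DataFrame  # index: model name; columns DIC, delta, DIC_w, PPP

    @property
    def best(self) -> str:
        return str(self.table["DIC"].idxmin())

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def dic(samples) -> DicResult:
    """Deviance information criterion from stored per-draw log-likelihoods.

    Dhat is evaluated at the posterior mean of *all* parameters (the WinBUGS
    convention).
    """
    from .models import loglik_at

    ll = np.asarray(samples.loglik, dtype=float)
    if ll.size == 0:
        raise ValueError("no log-likelihood draws stored")
    dbar = float(np.mean(-2.0 * ll))
    theta_bar = samples.posterior_mean()
    dhat = -2.0 * loglik_at(samples.data, theta_bar, samples.param_names)
    pd_ = dbar - dhat
    return DicResult(dbar=dbar, dhat=dhat, pd=pd_, dic=dbar + pd_)


def dic_weights(dics) -> np.ndarray:
    """DIC weights in percent: 100 * exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

    Delta_i is each DIC minus the smallest, so the computation is invariant
    to adding a constant and numerically stable.
    """
    d = np.asarray(list(dics), dtype=float)
    if d.size == 0 or not np.all(np.isfinite(d)):
        raise ValueError("DIC values must be finite and non-empty")
    delta = d - d.min()
    w = np.exp(-delta / 2.0)
    return 100.0 * w / w.sum()


DISCREPANCIES = {
    "sd": lambda y, mu, var: float(np.std(y, ddof=1)),
    "mean": lambda y, mu, var: float(np.mean(y)),
    "chisq": lambda y, mu, var: float(np.sum((y - mu) ** 2 / var)),
}


def posterior_predictive_p(samples, discrepancy: str = "sd",
                           min_draws: int = 200, seed: int = 0) -> float:
    """Posterior predictive p-value for a fitted model.

    For every retained draw, a replicate response vector is simulated from
    the likelihood at that draw's parameters (covariates untouched); the PPP
    is the fraction of draws whose replicate discrepancy is >= the observed
    one.  Default discrepancy is the response standard deviation; "mean" and
    a chi-square-style standardised residual sum are also available.
    """
    from .models import eta_from_params, simulate_response_from
    from scipy.special import expit

    if discrepancy not in DISCREPANCIES:
        raise ValueError(
            f"unknown discrepancy {discrepancy!r}; choose from {sorted(DISCREPANCIES)}")
    flat = samples.flat()
    if flat.shape[0] < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, have {flat.shape[0]}")
    md = samples.data
    names = samples.param_names
    disc = DISCREPANCIES[discrepancy]
    rng = np.random.default_rng(seed)
    y = md.y
    count = 0
    for t in range(flat.shape[0]):
        theta = flat[t]
        eta = eta_from_params(md, theta, names)
        g0 = theta[names.index("gamma0")]
        g1 = theta[names.index("gamma1")]
        if md.spec.response == "H":
            mu = expit(eta)
            delta = np.exp(g0 + g1 * md.logn_c)
            var = mu * (1 - mu) / (1 + delta)
            rep = rng.beta(mu * delta, (1 - mu) * delta)
        else:
            sig = np.exp(g0 + g1 * md.logn_c)
            mu, var = eta, sig ** 2
            rep = eta + sig * rng.standard_normal(eta.size)
        if disc(rep, mu, var) >= disc(y, mu, var):
            count += 1
    return count / flat.shape[0]


def ppp_flag(p: float, low: float = 0.05, high: float = 0.95) -> bool:
    """True when a PPP indicates contradiction between model and data."""
    return p < low or p > high


def gelman_rubin(samples) -> dict[str, float]:
    """Potential scale reduction (Brooks-Gelman-Rubin) per parameter.

    Classic two-variance form: with m chains of length n, within-chain
    variance W and between-chain variance B, R-hat = sqrt(((n-1)/n * W +
    B/n) / W), floored at 1 (values below 1 are finite-sample noise with no
    diagnostic meaning, so identical chains give exactly 1).  Requires
    >= 2 chains.
    """
    params = np.asarray(samples.params, dtype=float)
    m, n, P = params.shape
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains")
    out = {}
    for j, name in enumerate(samples.param_names):
        x = params[:, :, j]
        means = x.mean(axis=1)
        W = float(np.mean(x.var(axis=1, ddof=1)))
        B = n * float(np.var(means, ddof=1))
        if W == 0.0:
            out[name] = 1.0 if B == 0.0 else np.inf
            continue
        var_plus = (n - 1) / n * W + B / n
        out[name] = float(max(np.sqrt(var_plus / W), 1.0))
    return out
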