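"""Bayesian mixed models for multi-species diversity: Gaussian (Z) and beta (H).

Both families share the linear predictor

    eta_i = X_i beta + R_{region(i)} + S_{species(i)}

with X holding the intercept, genetic-marker dummies (beta family only;
reference level allozyme), and standardized latitude and latitude-squared
where included.  Region effects R carry an intrinsic CAR prior on the
region-adjacency graph; species effects S are multivariate normal with the
Brownian taxonomy correlation and scale sigma_S.  Per-population sample
size n enters the dispersion: the beta family has H_i ~ Beta(mu_i delta_i,
(1 - mu_i) delta_i) with logit(mu_i) = eta_i and log delta_i = g0 + g1
log n_i; the Gaussian family has Z_i ~ Normal(eta_i, sigma_i^2) with
log sigma_i = g0 + g1 log n_i.

Estimators follow the scikit-learn protocol: configure in ``__init__``,
``fit`` on a dataset, read fitted attributes with trailing underscores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betaln, expit
from sklearn.base import BaseEstimator

from ._sampler import run_chain
from .records import DiversityDataset, MARKER_CATEGORIES, squeeze_unit_interval
from .spatial_prior import CarStructure, RegionGraph, build_car
from .taxonomy_prior import build_taxonomy, brownian_correlation

REFERENCE_MARKER = "allozyme"


@dataclass(frozen=True)
class ModelSpec:
    """Which terms a model includes.  Species (S) and sample size (n) are
    always present; the beta (H) family always carries marker (M), the
    Gaussian (Z) family never does."""

    response: str = "H"
    include_latitude: bool = False
    include_latitude_sq: bool = False
    include_region: bool = False

    def __post_init__(self):
        if self.response not in ("H", "Z"):
            raise ValueError("response must be 'H' or 'Z'")
        if self.include_latitude_sq and not self.include_latitude:
            raise ValueError("latitude-squared requires the latitude term")

    @property
    def include_marker(self) -> bool:
        return self.response == "H"

    @property
    def name(self) -> str:
        parts = ["S"]
        if self.include_marker:
            parts.append("M")
        parts.append("n")
        if self.include_latitude:
            parts.append("L")
        if self.include_latitude_sq:
            parts.append("L2")
        if self.include_region:
            parts.append("R")
        return " + ".join(parts)


def h_ladder() -> list[ModelSpec]:
    """The six beta-family specs, in increasing-complexity order."""
    return [
        ModelSpec("H"),
        ModelSpec("H", include_latitude=True),
        ModelSpec("H", include_latitude=True, include_latitude_sq=True),
        ModelSpec("H", include_region=True),
        ModelSpec("H", include_latitude=True, include_region=True),
        ModelSpec("H", include_latitude=True, include_latitude_sq=True, include_region=True),
    ]


def z_ladder() -> list[ModelSpec]:
    """The six Gaussian-family specs (no marker term)."""
    return [replace(s, response="Z") for s in h_ladder()]


@dataclass
class PriorConfig:
    """Prior hyperparameters (all configurable; defaults are vague)."""

    beta_sd: float = 10.0
    gamma_sd: float = 10.0
    sigma_s_scale: float = 1.0  # half-normal scale for sigma_S
    tau_r_shape: float = 0.5
    tau_r_rate: float = 0.0005
    jitter: float = 1e-8


@dataclass
class McmcSettings:
    chains: int = 2
    iterations: int = 4000
    burnin: int = 1000
    thin: int = 3

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burnin) // self.thin


#: named presets: quick desk runs vs the long schedules used for real data
MCMC_PRESETS = {
    "desk": McmcSettings(chains=2, iterations=4000, burnin=1000, thin=3),
    "study-test": McmcSettings(chains=3, iterations=100_000, burnin=5000, thin=100),
    "study-final": McmcSettings(chains=3, iterations=500_000, burnin=50_000, thin=100),
}


@dataclass
class ModelData:
    """Frozen design arrays for one fit (enough to recompute likelihoods)."""

    spec: ModelSpec
    y: np.ndarray              # response on the likelihood scale
    X: np.ndarray
    colnames: list[str]
    sp_idx: np.ndarray
    reg_idx: np.ndarray | None
    logn_c: np.ndarray
    logn_center: float
    species: list[str]
    region_ids: list[str] | None
    scaling: dict
    n_pops_per_region: dict | None
    Cs: np.ndarray             # species correlation
    car: CarStructure | None


@dataclass
class PosteriorSamples:
    """MCMC draws with per-draw log-likelihood and the design they came from."""

    params: np.ndarray          # (chains, draws, P)
    param_names: list[str]
    loglik: np.ndarray          # (chains, draws)
    data: ModelData
    settings: McmcSettings
    priors: PriorConfig
    seed: int
    rhat: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[1]

    def flat(self) -> np.ndarray:
        return self.params.reshape(-1, self.params.shape[2])

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, draws)."""
        return self.params[:, :, self.param_names.index(name)]

    def posterior_mean(self) -> np.ndarray:
        return self.flat().mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat(), columns=self.param_names)


def design_matrix(ds: DiversityDataset, spec: ModelSpec) -> tuple[np.ndarray, list[str], dict]:
    """Fixed-effects design: intercept, marker dummies, scaled latitude terms.

    Latitude is centered and scaled to unit sd before squaring, so both
    latitude coefficients are O(1) and nearly orthogonal.  The returned
    scaling dict records the transform.  Raises if the matrix is singular.
    """
    n = len(ds.df)
    cols = [np.ones(n)]
    names = ["intercept"]
    if spec.include_marker:
        present = [m for m in MARKER_CATEGORIES if m in set(ds.df["marker"])]
        for m in present:
            if m == REFERENCE_MARKER:
                continue
            cols.append((ds.df["marker"] == m).to_numpy(float))
            names.append(f"marker[{m}]")
    lat = ds.df["lat"].to_numpy(float)
    scaling = {"lat_mean": float(lat.mean()), "lat_sd": float(lat.std(ddof=0)) or 1.0}
    if spec.include_latitude:
        lat_std = (lat - scaling["lat_mean"]) / scaling["lat_sd"]
        cols.append(lat_std)
        names.append("latitude")
        if spec.include_latitude_sq:
            cols.append(lat_std ** 2)
            names.append("latitude_sq")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear columns)")
    return X, names, scaling


def _prepare(ds: DiversityDataset, spec: ModelSpec, graph: RegionGraph | None,
             jitter: float) -> ModelData:
    df = ds.df
    if spec.response == "Z":
        if "z" not in df.columns:
            raise ValueError("Z-family models need a z column; run add_zscores first")
        y = df["z"].to_numpy(float)
    else:
        # squeeze only exact-boundary values into (0, 1); interior values are
        # already valid beta observations and must not be compressed
        y = df["H"].to_numpy(float).copy()
        edge = (y <= 0.0) | (y >= 1.0)
        if edge.any():
            nvec = df["n"].to_numpy(float)
            y[edge] = squeeze_unit_interval(y[edge], nvec[edge])
    X, names, scaling = design_matrix(ds, spec)
    species = ds.species
    sp_idx = df["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    tree = build_taxonomy(ds.species_paths())
    Cs, tips = brownian_correlation(tree)
    order = [tips.index(s) for s in species]
    Cs = Cs[np.ix_(order, order)]
    reg_idx, region_ids, car, npops = None, None, None, None
    if spec.include_region:
        if graph is None:
            raise ValueError("region models need a RegionGraph")
        region_ids = graph.region_ids
        missing = set(df["region"].astype(str)) - set(region_ids)
        if missing:
            raise ValueError(f"dataset regions missing from graph: {sorted(missing)}")
        reg_idx = df["region"].astype(str).map(
            {r: i for i, r in enumerate(region_ids)}).to_numpy()
        car = build_car(graph, allow_isolated=True)
        counts = df.groupby(df["region"].astype(str)).size()
        npops = {r: int(counts.get(r, 0)) for r in region_ids}
    logn = np.log(df["n"].to_numpy(float))
    center = float(logn.mean())
    return ModelData(
        spec=spec, y=y, X=X, colnames=names, sp_idx=sp_idx.astype(np.int64),
        reg_idx=None if reg_idx is None else reg_idx.astype(np.int64),
        logn_c=logn - center, logn_center=center,
        species=list(species), region_ids=region_ids, scaling=scaling,
        n_pops_per_region=npops, Cs=Cs, car=car,
    )


def _group_rows(idx: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(idx, kind="stable").astype(np.int64)
    ptr = np.zeros(k + 1, dtype=np.int64)
    counts = np.bincount(idx, minlength=k)
    ptr[1:] = np.cumsum(counts)
    return order, ptr


def eta_from_params(md: ModelData, theta: np.ndarray, names: list[str]) -> np.ndarray:
    p = md.X.shape[1]
    ns = len(md.species)
    beta = theta[:p]
    S = theta[p:p + ns]
    eta = md.X @ beta + S[md.sp_idx]
    if md.spec.include_region:
        nr = len(md.region_ids)
        R = theta[p + ns:p + ns + nr]
        eta = eta + R[md.reg_idx]
    return eta


def loglik_at(md: ModelData, theta: np.ndarray, names: list[str]) -> float:
    """Total log-likelihood at a parameter vector (numpy path, used for DIC)."""
    eta = eta_from_params(md, theta, names)
    g0 = theta[names.index("gamma0")]
    g1 = theta[names.index("gamma1")]
    if md.spec.response == "H":
        mu = expit(eta)
        delta = np.exp(g0 + g1 * md.logn_c)
        a, b = mu * delta, (1 - mu) * delta
        return float(np.sum(
            (a - 1) * np.log(md.y) + (b - 1) * np.log1p(-md.y) - betaln(a, b)))
    sig = np.exp(g0 + g1 * md.logn_c)
    r = (md.y - eta) / sig
    return float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sig) - 0.5 * r * r))


def log_joint_beta(md: ModelData, theta: np.ndarray, names: list[str],
                   priors: PriorConfig | None = None) -> float:
    """Log posterior density (unnormalised) for the beta family.

    Likelihood plus: normal priors on fixed and dispersion coefficients,
    MVN (taxonomy correlation, scale sigma_S) on species effects, intrinsic
    CAR on region effects, half-normal on sigma_S and gamma on tau_R.
    """
    priors = priors or PriorConfig()
    ll = loglik_at(md, theta, names)
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood at supplied parameters")
    p = md.X.shape[1]
    ns = len(md.species)
    beta = theta[:p]
    S = theta[p:p + ns]
    g = np.array([theta[names.index("gamma0")], theta[names.index("gamma1")]])
    ll += -0.5 * np.sum(beta ** 2) / priors.beta_sd ** 2
    ll += -0.5 * np.sum(g ** 2) / priors.gamma_sd ** 2
    sigS = theta[names.index("sigma_S")]
    Pm = np.linalg.inv(md.Cs + priors.jitter * np.eye(ns))
    ll += -ns * math.log(sigS) - 0.5 * S @ Pm @ S / sigS ** 2
    ll += -0.5 * sigS ** 2 / priors.sigma_s_scale ** 2
    if md.spec.include_region:
        nr = len(md.region_ids)
        R = theta[p + ns:p + ns + nr]
        tauR = theta[names.index("tau_R")]
        rank = md.car.rank
        ll += 0.5 * rank * math.log(tauR) - 0.5 * tauR * R @ md.car.Q0 @ R
        ll += ((priors.tau_r_shape - 1) * math.log(tauR)
               - priors.tau_r_rate * tauR)
    return float(ll)


def _param_names(md: ModelData) -> list[str]:
    names = list(md.colnames)
    names += [f"S[{s}]" for s in md.species]
    if md.spec.include_region:
        names += [f"R[{r}]" for r in md.region_ids]
    names += ["gamma0", "gamma1", "sigma_S", "tau_R"]
    return names


class _DiversityModelBase(BaseEstimator):
    """Shared fit machinery; subclasses pin the response family."""

    _response = "H"

    def __init__(self, include_latitude=False, include_latitude_sq=False,
                 include_region=False, priors=None, mcmc=None, seed=0):
        self.include_latitude = include_latitude
        self.include_latitude_sq = include_latitude_sq
        self.include_region = include_region
        self.priors = priors
        self.mcmc = mcmc
        self.seed = seed

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            response=self._response,
            include_latitude=self.include_latitude,
            include_latitude_sq=self.include_latitude_sq,
            include_region=self.include_region,
        )

    def fit(self, ds: DiversityDataset, region_graph: RegionGraph | None = None):
        """Run the MCMC and populate fitted attributes.

        Sets ``samples_`` (:class:`PosteriorSamples`), ``rhat_`` (per-parameter
        potential scale reduction), ``dic_`` and ``param_names_``.  Warns,
        without failing, if any R-hat exceeds 1.1.
        """
        from .evaluation import dic, gelman_rubin

        priors = self.priors or PriorConfig()
        mcmc = self.mcmc or MCMC_PRESETS["desk"]
        if isinstance(mcmc, str):
            mcmc = MCMC_PRESETS[mcmc]
        md = _prepare(ds, self.spec, region_graph, priors.jitter)
        names = _param_names(md)
        ns = len(md.species)
        Pm = np.linalg.inv(md.Cs + priors.jitter * np.eye(ns))
        sp_rows, sp_ptr = _group_rows(md.sp_idx, ns)
        if md.spec.include_region:
            nr = len(md.region_ids)
            reg_rows, reg_ptr = _group_rows(md.reg_idx, nr)
            Q0, rank = md.car.Q0, md.car.rank
        else:
            reg_rows = np.zeros(0, dtype=np.int64)
            reg_ptr = np.zeros(1, dtype=np.int64)
            Q0, rank = np.zeros((0, 0)), 0
        kind = 0 if md.spec.response == "H" else 1
        y = md.y
        if kind == 0:
            ly, l1y = np.log(y), np.log1p(-y)
            mbar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
            b0 = math.log(mbar / (1 - mbar))
            v = max(float(y.var()), 1e-4)
            g0 = math.log(max(mbar * (1 - mbar) / v - 1.0, 1.5))
        else:
            ly, l1y = np.zeros_like(y), np.zeros_like(y)
            b0 = float(y.mean())
            g0 = 0.5 * math.log(max(float(y.var()), 1e-6))
        # per-region mean latitude patterns for the ridge moves
        lat_col = names.index("latitude") if "latitude" in md.colnames else -1
        lat2_col = names.index("latitude_sq") if "latitude_sq" in md.colnames else -1
        if md.spec.include_region:
            nr = len(md.region_ids)
            regc1 = np.zeros(nr)
            regc2 = np.zeros(nr)
            if lat_col >= 0:
                latstd = md.X[:, md.colnames.index("latitude")]
                for k in range(nr):
                    rows = md.reg_idx == k
                    if rows.any():
                        regc1[k] = latstd[rows].mean()
                        regc2[k] = (latstd[rows] ** 2).mean()
        else:
            regc1 = np.zeros(0)
            regc2 = np.zeros(0)
        chains, lls = [], []
        for c in range(mcmc.chains):
            chain_seed = (self.seed * 1009 + 7919 * c + 1) % (2 ** 31)
            out, out_ll = run_chain(
                kind, y, ly, l1y, md.X, md.logn_c,
                sp_rows, sp_ptr, reg_rows, reg_ptr,
                Pm, Q0, rank, md.spec.include_region,
                mcmc.iterations, mcmc.burnin, mcmc.thin, chain_seed,
                priors.beta_sd, priors.gamma_sd, priors.sigma_s_scale,
                priors.tau_r_shape, priors.tau_r_rate,
                b0, g0,
                lat_col, lat2_col, regc1, regc2,
            )
            if not np.all(np.isfinite(out_ll)):
                raise RuntimeError("non-finite log-likelihood during sampling")
            chains.append(out)
            lls.append(out_ll)
        params = np.stack(chains)
        loglik = np.stack(lls)
        if not md.spec.include_region:  # drop the unused tau_R column
            keep = [i for i, nm in enumerate(names) if nm != "tau_R"]
            params = params[:, :, keep]
            names = [names[i] for i in keep]
        self.samples_ = PosteriorSamples(
            params=params, param_names=names, loglik=loglik, data=md,
            settings=mcmc, priors=priors, seed=self.seed,
        )
        self.rhat_ = gelman_rubin(self.samples_) if mcmc.chains >= 2 else {}
        self.samples_.rhat = self.rhat_
        bad = {k: v for k, v in self.rhat_.items() if v > 1.1}
        if bad:
            worst = max(bad.values())
            warnings.warn(
                f"{len(bad)} parameters with R-hat > 1.1 (worst {worst:.3f}); "
                "consider longer chains", stacklevel=2)
        self.param_names_ = names
        self.dic_ = dic(self.samples_).dic
        return self

    def predict(self, ds: DiversityDataset) -> np.ndarray:
        """Posterior-mean response for each row of a dataset sharing this
        fit's species/regions (mu for the beta family, m for the Gaussian)."""
        if not hasattr(self, "samples_"):
            raise RuntimeError("model is not fitted")
        md_new = _prepare(ds, self.spec,
                          self.samples_.data.car.graph if self.spec.include_region else None,
                          (self.priors or PriorConfig()).jitter)
        theta = self.samples_.posterior_mean()
        eta = eta_from_params(md_new, theta, self.param_names_)
        return expit(eta) if self.spec.response == "H" else eta

    def simulate_response(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one replicate response vector from the likelihood at theta."""
        md = self.samples_.data
        return simulate_response_from(md, theta, self.param_names_, rng)


def simulate_response_from(md: ModelData, theta: np.ndarray, names: list[str],
                           rng: np.random.Generator) -> np.ndarray:
    eta = eta_from_params(md, theta, names)
    g0 = theta[names.index("gamma0")]
    g1 = theta[names.index("gamma1")]
    if md.spec.response == "H":
        mu = expit(eta)
        delta = np.exp(g0 + g1 * md.logn_c)
        return rng.beta(mu * delta, (1 - mu) * delta)
    sig = np.exp(g0 + g1 * md.logn_c)
    return eta + sig * rng.standard_normal(eta.size)


class BetaDiversityModel(_DiversityModelBase):
    """Beta-regression mixed model on raw diversity H (logit link,
    sample-size-dependent dispersion, marker fixed effects)."""

    _response = "H"


class GaussianDiversityModel(_DiversityModelBase):
    """Gaussian mixed model on within-study z-scored diversity Z
    (identity link, sample-size-dependent residual sd, no marker term)."""

    _response = "Z"


def fit(ds: DiversityDataset, spec: ModelSpec, priors: PriorConfig | None = None,
        mcmc: McmcSettings | str | None = None, seed: int = 0,
        region_graph: RegionGraph | None = None) -> PosteriorSamples:
    """Functional wrapper: fit one :class:`ModelSpec` and return the draws."""
    cls = BetaDiversityModel if spec.response == "H" else GaussianDiversityModel
    est = cls(include_latitude=spec.include_latitude,
              include_latitude_sq=spec.include_latitude_sq,
              include_region=spec.include_region,
              priors=priors, mcmc=mcmc, seed=seed)
    est.fit(ds, region_graph=region_graph)
    return est.samples_


def regional_summary(samples: PosteriorSamples, low_support_min_pops: int = 10) -> pd.DataFrame:
    """Posterior summary of region effects.

    One row per region: posterior mean, sd, equal-tailed 95% interval of the
    region effect (logit scale for H models, z scale for Z models), a
    significance flag (interval excludes zero), the number of sampled
    populations and a low-support flag for regions with fewer than
    ``low_support_min_pops`` populations.
    """
    md = samples.data
    if not md.spec.include_region:
        raise ValueError("model spec does not include a region term")
    rows = []
    for r in md.region_ids:
        draws = samples.get(f"R[{r}]").ravel()
        lo, hi = np.quantile(draws, [0.025, 0.975])
        rows.append({
            "region": r,
            "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)),
            "q2.5": float(lo),
            "q97.5": float(hi),
            "significant": bool(lo > 0 or hi < 0),
            "n_pops": md.n_pops_per_region[r],
            "low_support": md.n_pops_per_region[r] < low_support_min_pops,
        })
    return pd.DataFrame(rows).set_index("region")
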