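"""Orchestration: the 12-model ladder, comparison tables, regional reports.

``run_ladder`` fits the six Gaussian (Z) specs and the six beta (H) specs in
increasing-complexity order, collects DIC / delta / DIC weight / PPP per
family, marks each family's best model and attaches regional summaries for
every region-containing model.  ``cross_model_correlation`` computes the
squared Pearson correlation between two sets of regional means, restricted
to regions with enough populations in the restricting subset — the
cross-model / cross-taxon consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import ModelComparison, dic, dic_weights, posterior_predictive_p, ppp_flag
from .models import (
    MCMC_PRESETS,
    McmcSettings,
    PriorConfig,
    fit,
    h_ladder,
    regional_summary,
    z_ladder,
)
from .records import DiversityDataset
from .spatial_prior import RegionGraph
from .standardize import add_zscores


@dataclass
class LadderResult:
    """Everything the model ladder produces, per response family."""

    z_comparison: ModelComparison
    h_comparison: ModelComparison
    regional: dict = field(default_factory=dict)  # model name -> DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def best_h(self) -> str:
        return self.h_comparison.best

    @property
    def best_z(self) -> str:
        return self.z_comparison.best


def _family_table(names, dics, ppps) -> ModelComparison:
    dics = np.asarray(dics, dtype=float)
    w = dic_weights(dics)
    tab = pd.DataFrame({
        "DIC": dics,
        "delta": dics - dics.min(),
        "DIC_w": w,
        "PPP": ppps,
    }, index=pd.Index(names, name="model"))
    tab["contradiction"] = [ppp_flag(p) for p in tab["PPP"]]
    return ModelComparison(tab)


def run_ladder(
    ds: DiversityDataset,
    graph: RegionGraph,
    priors: PriorConfig | None = None,
    mcmc: McmcSettings | str | None = None,
    seed: int = 0,
    taxon_filter: dict | None = None,
    compute_ppp: bool = True,
) -> LadderResult:
    """Fit both families' six-model ladders and assemble the comparison.

    ``taxon_filter`` optionally restricts the dataset before fitting, e.g.
    ``{"class": ["Actinopterygii", "Chondrichthyes"]}`` for a fish-only
    rerun; the full model ladder is reused on the filtered data.
    """
    if taxon_filter:
        mask = np.zeros(len(ds.df), dtype=bool)
        for rank, values in taxon_filter.items():
            mask |= ds.df[rank].isin(list(values)).to_numpy()
        ds = DiversityDataset(ds.df[mask].copy())
    ds_z, skipped = add_zscores(ds)
    regional = {}
    results = {}
    for fam, specs, data in (("Z", z_ladder(), ds_z), ("H", h_ladder(), ds)):
        names, dics, ppps = [], [], []
        for k, spec in enumerate(specs):
            samples = fit(data, spec, priors=priors, mcmc=mcmc,
                          seed=seed + 13 * k, region_graph=graph)
            names.append(spec.name)
            dics.append(dic(samples).dic)
            ppps.append(
                posterior_predictive_p(samples, seed=seed + 13 * k)
                if compute_ppp else np.nan)
            if spec.include_region:
                regional[spec.name] = regional_summary(samples)
        results[fam] = _family_table(names, dics, ppps)
    return LadderResult(
        z_comparison=results["Z"],
        h_comparison=results["H"],
        regional=regional,
        meta={"seed": seed, "skipped_data_ids": skipped,
              "mcmc": str(mcmc or "desk"), "n_records": len(ds.df)},
    )


@dataclass
class CrossModelCorrelation:
    """Regional-mean agreement between two models or data subsets.

    ``r_squared`` is the sample-size-adjusted squared Pearson correlation,
    1 - (1 - r^2)(n - 1)/(n - 2) (the convention of standard regression
    summaries, which regional comparisons of this kind are reported with);
    ``r_squared_raw`` is the plain r^2 (sign-blind); ``p_value`` is the
    two-sided correlation test.
    """

    n_regions: int
    r_squared: float
    r_squared_raw: float
    r: float
    p_value: float

    def __iter__(self):  # allows n, r2, p = cross_model_correlation(...)
        return iter((self.n_regions, self.r_squared, self.p_value))


def cross_model_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    min_pops: int = 0,
    mean_col_a: str = "mean",
    mean_col_b: str = "mean",
    pops_col_b: str = "n_pops",
) -> CrossModelCorrelation:
    """Correlation between two regional-mean tables.

    Regions are matched on index; when ``min_pops`` > 0, only regions where
    the *restricting* table ``b`` has at least that many populations are
    used (e.g. comparing all-taxa means with a fish-only rerun over regions
    with >= 10 fish populations).
    """
    shared = a.index.intersection(b.index)
    sub_a = a.loc[shared]
    sub_b = b.loc[shared]
    if min_pops > 0:
        keep = sub_b[pops_col_b] >= min_pops
        sub_a, sub_b = sub_a[keep], sub_b[keep]
    x = sub_a[mean_col_a].to_numpy(float)
    y = sub_b[mean_col_b].to_numpy(float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 shared regions, have {n}")
    r, p_two = stats.pearsonr(x, y)
    r2 = float(r ** 2)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CrossModelCorrelation(
        n_regions=n, r_squared=float(r2_adj), r_squared_raw=r2,
        r=float(r), p_value=float(p_two))
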