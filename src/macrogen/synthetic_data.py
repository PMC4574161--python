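"""Synthetic multi-species diversity datasets with known ground truth.

The generator is the generative mirror of the beta mixed model: it invents a
ranked taxonomy, assigns species to studies (dataIDs) and marker categories,
places populations in coastal regions ordered along a latitudinal gradient
(-9.4 to -43.7 degrees, region and latitude correlated but separable through
within-region jitter), then draws diversity from Beta(mu delta, (1-mu) delta)
with logit(mu) = X beta + R + S and log delta = g0 + g1 log n.  Defaults
emulate the scale and structure of the Australian coastal compilation the
models were built for: 84 species, 959 populations, 17 regions, the six
marker categories at their observed frequencies, and a latitudinal "hump"
(positive latitude, negative latitude-squared coefficients on the
standardized scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .records import DiversityDataset, MARKER_CATEGORIES, from_frame
from .spatial_prior import RegionGraph, build_car, chain_adjacency_fixture, sample_car
from .taxonomy_prior import build_taxonomy, brownian_correlation

#: marker-category sampling frequencies observed in the compiled database
MARKER_FREQS = {
    "allozyme": 0.328,
    "microsatellite": 0.314,
    "mtDNA_sequence": 0.235,
    "mtDNA_restriction": 0.080,
    "nuclear_sequence": 0.012,
    "other": 0.029,
}

LAT_NORTH = -9.4
LAT_SOUTH = -43.7


@dataclass
class SimulationTruth:
    """Ground-truth parameters used to generate a dataset."""

    intercept: float = 0.405  # logit(0.6)
    marker_effects: dict = field(default_factory=lambda: {
        "allozyme": 0.0,          # reference level
        "microsatellite": 1.0,
        "mtDNA_sequence": 0.6,
        "mtDNA_restriction": 0.3,
        "nuclear_sequence": 0.4,
        "other": 0.2,
    })
    beta_lat: float = 0.558       # on standardized latitude
    beta_lat_sq: float = -0.920   # hump: diversity peaks inside the range
    sigma_s: float = 0.5
    region_scale: float = 0.3     # marginal sd target for CAR draws
    gamma0: float = 1.8           # log-dispersion at the mean log n
    gamma1: float = 0.5
    region_effects: dict = field(default_factory=dict)
    species_effects: dict = field(default_factory=dict)
    lat_mean: float = 0.0
    lat_sd: float = 1.0
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _random_taxonomy(n_species: int, rng: np.random.Generator,
                     mean_clade: float = 3.0) -> list[tuple]:
    """Random ranked paths: species nested in genera/families/orders/classes
    with geometric-ish clade sizes (a few large clades, many small ones)."""
    paths = []
    labels = {r: 0 for r in "cofg"}

    def take(rank: str) -> str:
        labels[rank] += 1
        names = {"c": "Class", "o": "Order", "f": "Family", "g": "Genus"}
        return f"{names[rank]}{labels[rank]:02d}"

    remaining = n_species
    sp = 0
    while remaining > 0:
        ncl = min(remaining, 1 + rng.geometric(1.0 / (mean_clade ** 3)))
        cl = take("c")
        left_c = ncl
        while left_c > 0:
            nor = min(left_c, 1 + rng.geometric(1.0 / (mean_clade ** 2)))
            orl = take("o")
            left_o = nor
            while left_o > 0:
                nfa = min(left_o, 1 + rng.geometric(1.0 / mean_clade))
                fal = take("f")
                left_f = nfa
                while left_f > 0:
                    nge = min(left_f, 1 + rng.geometric(0.55))
                    gel = take("g")
                    for _ in range(nge):
                        sp += 1
                        paths.append((cl, orl, fal, gel, f"species{sp:03d}"))
                    left_f -= nge
                left_o -= nfa
            left_c -= nor
        remaining -= ncl
    return paths[:n_species]


def simulate_dataset(
    n_species: int = 84,
    n_populations: int = 959,
    n_regions: int = 17,
    graph: RegionGraph | None = None,
    truth: SimulationTruth | str = "random",
    seed: int = 0,
) -> tuple[DiversityDataset, SimulationTruth]:
    """Generate a dataset plus the truth that produced it.

    Species get random Linnaean paths; each species is split into 1-2
    dataIDs (study x marker blocks of at least 3 populations); populations
    sit in a contiguous window of regions (species ranges are contiguous
    along the coast) with latitude = region centre + jitter; n >= 5.
    Deterministic given ``seed``.
    """
    if n_species < 1 or n_populations < n_species:
        raise ValueError("need n_populations >= n_species >= 1")
    rng = np.random.default_rng(seed)
    if graph is None:
        graph = chain_adjacency_fixture(n_regions)
    if len(graph.region_ids) != n_regions:
        raise ValueError("graph size must match n_regions")
    if isinstance(truth, str):
        truth = SimulationTruth(seed=seed)

    paths = _random_taxonomy(n_species, rng)
    species_names = [p[-1] for p in paths]

    # species effects from the Brownian taxonomy correlation
    if not truth.species_effects:
        tree = build_taxonomy(paths)
        C, tips = brownian_correlation(tree)
        order = [tips.index(s) for s in sorted(species_names)]
        C = C[np.ix_(order, order)]
        L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
        S = truth.sigma_s * (L @ rng.standard_normal(len(C)))
        truth.species_effects = {s: float(v) for s, v in zip(sorted(species_names), S)}

    # Region effects from the intrinsic CAR, restricted to the orthogonal
    # complement of the regional linear/quadratic latitude patterns and
    # scaled to the target marginal sd.  The latitudinal trend itself belongs
    # to the latitude coefficients; region effects represent regional
    # deviations *net of* that trend, which keeps region and latitude
    # correlated through geography but separable in the model — the contrast
    # the model ladder is built to detect.
    if not truth.region_effects:
        car = build_car(graph)
        draw = sample_car(car, tau=1.0, size=1, rng=rng)[0]
        c = np.linspace(-1.0, 1.0, n_regions)
        B = np.column_stack([np.ones(n_regions), c, c ** 2])
        draw = draw - B @ np.linalg.lstsq(B, draw, rcond=None)[0]
        sd = draw.std()
        if sd > 0 and truth.region_scale > 0:
            draw = draw * (truth.region_scale / sd)
        else:
            draw = np.zeros_like(draw)
        draw = draw - draw.mean()
        truth.region_effects = {r: float(v) for r, v in zip(graph.region_ids, draw)}

    centers = np.linspace(LAT_NORTH, LAT_SOUTH, n_regions)
    span = abs(LAT_SOUTH - LAT_NORTH) / n_regions

    # dataID blocks: ~1-2 per species, each with >= 3 populations
    blocks = []  # (data_id, species index, marker)
    budget = n_populations
    markers = list(MARKER_FREQS)
    probs = np.array([MARKER_FREQS[m] for m in markers])
    probs = probs / probs.sum()
    study = 0
    sizes = []
    per_species = max(3, n_populations // n_species)
    for si in range(n_species):
        nblocks = 1 if per_species < 6 or rng.random() < 0.5 else 2
        for _ in range(nblocks):
            study += 1
            m = markers[rng.choice(len(markers), p=probs)]
            blocks.append((f"study{study:03d}:{m}", si, m))
            sizes.append(3)
            budget -= 3
    if budget < 0:
        raise ValueError("infeasible block constraints: too few populations "
                         "for one >=3-population dataID per species")
    # distribute remaining populations over blocks
    while budget > 0:
        i = int(rng.integers(len(sizes)))
        sizes[i] += 1
        budget -= 1

    rows = []
    for (did, si, m), sz in zip(blocks, sizes):
        width = int(min(n_regions, 1 + rng.integers(2, max(3, n_regions // 2))))
        start = int(rng.integers(0, n_regions - width + 1))
        regs = rng.integers(start, start + width, size=sz)
        for rix in regs:
            lat = float(centers[rix] + rng.normal(0.0, span * 0.6))
            lat = float(np.clip(lat, LAT_SOUTH - 1.5, LAT_NORTH + 1.5))
            n = int(5 + rng.poisson(20))
            rows.append({
                "dataID": did,
                "class": paths[si][0], "order": paths[si][1],
                "family": paths[si][2], "genus": paths[si][3],
                "species": paths[si][4],
                "marker": m, "lat": lat,
                "lon": float(135.0 + rng.normal(0, 10)),
                "region": graph.region_ids[rix], "n": n,
            })
    df = pd.DataFrame(rows)

    lat = df["lat"].to_numpy()
    truth.lat_mean = float(lat.mean())
    truth.lat_sd = float(lat.std(ddof=0))
    lat_std = (lat - truth.lat_mean) / truth.lat_sd
    eta = (
        truth.intercept
        + df["marker"].map(truth.marker_effects).to_numpy(float)
        + truth.beta_lat * lat_std
        + truth.beta_lat_sq * lat_std ** 2
        + df["region"].map(truth.region_effects).to_numpy(float)
        + df["species"].map(truth.species_effects).to_numpy(float)
    )
    mu = 1.0 / (1.0 + np.exp(-eta))
    logn = np.log(df["n"].to_numpy(float))
    delta = np.exp(truth.gamma0 + truth.gamma1 * (logn - logn.mean()))
    df["H"] = rng.beta(mu * delta, (1.0 - mu) * delta)
    truth.seed = seed
    return from_frame(df), truth


def simulate_null_for_ppp(md, theta: np.ndarray, names: list[str],
                          seed: int = 0) -> np.ndarray:
    """Replicate responses from the likelihood at given parameters.

    Covariates, species and region assignments come from the fitted design
    ``md`` (a :class:`~macrogen.models.ModelData`); only the response is
    redrawn.  Deterministic given ``seed``.
    """
    from .models import simulate_response_from

    rng = np.random.default_rng(seed)
    return simulate_response_from(md, np.asarray(theta, float), names, rng)
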