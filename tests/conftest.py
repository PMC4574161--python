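import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import macrogen as mg
from macrogen.models import McmcSettings, ModelSpec, fit
from macrogen.synthetic_data import SimulationTruth

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def toy_frame(rows):
    """Build a canonical-columns frame from (dataID, species5, marker, lat,
    region, n, H) shorthand tuples."""
    recs = []
    for did, sp5, marker, lat, region, n, h in rows:
        recs.append({
            "dataID": did, "class": sp5[0], "order": sp5[1], "family": sp5[2],
            "genus": sp5[3], "species": sp5[4], "marker": marker,
            "lat": lat, "lon": 140.0, "region": region, "n": n, "H": h,
        })
    return pd.DataFrame(recs)


SP_A = ("Actinopterygii", "Perciformes", "Sparidae", "Pagrus", "Pagrus auratus")
SP_B = ("Actinopterygii", "Perciformes", "Sparidae", "Pagrus", "Pagrus major")
SP_C = ("Mollusca", "Ostreida", "Ostreidae", "Saccostrea", "Saccostrea glomerata")


@pytest.fixture
def toy_dataset():
    rows = [
        ("a:msat", SP_A, "microsatellite", -20.0, "25", 30, 0.80),
        ("a:msat", SP_A, "microsatellite", -22.0, "26", 25, 0.75),
        ("a:msat", SP_A, "microsatellite", -24.0, "27", 20, 0.70),
        ("b:mt", SP_B, "mtDNA_sequence", -30.0, "27", 15, 0.90),
        ("b:mt", SP_B, "mtDNA_sequence", -32.0, "28", 15, 0.60),
        ("b:mt", SP_B, "mtDNA_sequence", -34.0, "28", 18, 0.72),
        ("c:allo", SP_C, "allozyme", -36.0, "25", 40, 0.30),
        ("c:allo", SP_C, "allozyme", -38.0, "26", 40, 0.35),
        ("c:allo", SP_C, "allozyme", -40.0, "27", 40, 0.25),
    ]
    from macrogen.records import from_frame
    return from_frame(toy_frame(rows))


@pytest.fixture(scope="session")
def small_sim():
    """One reduced-scale synthetic dataset with its truth (shared)."""
    return mg.simulate_dataset(20, 160, 17, seed=1234)


@pytest.fixture(scope="session")
def chain17():
    return mg.chain_adjacency_fixture(17)


@pytest.fixture(scope="session")
def fitted_full_h(small_sim, chain17):
    """Full beta-family model fitted once, reused by several tests."""
    ds, truth = small_sim
    spec = ModelSpec("H", include_latitude=True, include_latitude_sq=True,
                     include_region=True)
    samples = fit(ds, spec,
                  mcmc=McmcSettings(chains=2, iterations=8000, burnin=3000, thin=5),
                  seed=99, region_graph=chain17)
    return samples, truth
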