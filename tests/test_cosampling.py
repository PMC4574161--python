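import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from macrogen.cosampling import presence_matrix, ward_cluster
from macrogen.records import from_frame
from conftest import toy_frame


def _ds_with_memberships(memberships):
    """memberships: dict region -> list of species names (each >= 3 pops
    would be overkill here; presence only needs one record)."""
    rows = []
    k = 0
    for region, sps in memberships.items():
        for sp in sps:
            k += 1
            sp5 = ("C1", "O1", "F1", f"G_{sp}", sp)
            rows.append((f"d{sp}:m", sp5, "allozyme", -20.0 - k * 0.1, region, 10, 0.5))
    return from_frame(toy_frame(rows))


def test_presence_matrix_counts_and_threshold():
    memberships = {
        "r1": ["s1", "s2", "s3", "s4", "s5"],
        "r2": ["s1", "s2", "s3", "s4", "s5", "s6"],
        "r3": ["s1", "s2", "s3", "s4"],  # only 4 species: dropped
    }
    ds = _ds_with_memberships(memberships)
    pm = presence_matrix(ds, min_species=5)
    assert pm.dropped == ["r3"]
    assert pm.region_ids == ["r1", "r2"]
    # brute-force tally
    for i, r in enumerate(pm.region_ids):
        for j, s in enumerate(pm.species):
            assert pm.M[i, j] == int(s in memberships[r])


def test_presence_is_idempotent_under_duplicates():
    rows = [
        ("a:m", ("C1", "O1", "F1", "G1", "s1"), "allozyme", -20.0, "r1", 10, 0.5)
    ] * 4 + [
        ("b:m", ("C1", "O1", "F1", "G2", f"s{i}"), "allozyme", -21.0, "r1", 10, 0.5)
        for i in range(2, 7)
    ] + [
        ("c:m", ("C1", "O1", "F1", "G3", f"s{i}"), "allozyme", -30.0, "r2", 10, 0.5)
        for i in range(1, 7)
    ]
    ds = from_frame(toy_frame(rows))
    pm = presence_matrix(ds)
    assert pm.M.max() == 1
    assert pm.M[pm.region_ids.index("r1"), pm.species.index("s1")] == 1


def test_too_few_regions_errors(toy_dataset):
    with pytest.raises(ValueError):
        presence_matrix(toy_dataset, min_species=5)


def brute_force_ward(X):
    """Independent Lance-Williams enumeration on squared distances."""
    X = np.asarray(X, float)
    n = X.shape[0]
    d2 = {(i, j): ((X[i] - X[j]) ** 2).sum() for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    nid = n
    while len(active) > 1:
        key = min(d2, key=lambda k: (round(d2[k], 12), k))
        a, b = key
        h2 = d2[key]
        heights.append(np.sqrt(h2))
        for c in sorted(active - {a, b}):
            na, nb, nc = sizes[a], sizes[b], sizes[c]
            dac = d2[(min(a, c), max(a, c))]
            dbc = d2[(min(b, c), max(b, c))]
            d2[(c, nid)] = ((na + nc) * dac + (nb + nc) * dbc - nc * h2) / (na + nb + nc)
        for k in list(d2):
            if a in k or b in k:
                del d2[k]
        active -= {a, b}
        active.add(nid)
        sizes[nid] = sizes[a] + sizes[b]
        nid += 1
    return np.array(heights)


def test_identical_rows_merge_first_at_zero():
    X = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0], [1, 1, 1]], float)
    dg = ward_cluster(X, labels=list("abcd"))
    assert dg.linkage[0, 2] == 0.0
    assert sorted(dg.linkage[0, :2]) == [0, 1]


def test_ward_matches_brute_force_lance_williams():
    rng = np.random.default_rng(9)
    for trial in range(5):
        X = rng.integers(0, 2, size=(6, 8)).astype(float)
        X += rng.normal(0, 1e-6, X.shape)  # break ties so orders align
        dg = ward_cluster(X)
        np.testing.assert_allclose(dg.heights, brute_force_ward(X), rtol=1e-8)


def test_ward_matches_scipy_cophenetic():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(9, 5))
    dg = ward_cluster(X)
    Z_ref = hierarchy.linkage(X, method="ward")
    coph_mine = hierarchy.cophenet(dg.linkage)
    coph_ref = hierarchy.cophenet(Z_ref)
    np.testing.assert_allclose(coph_mine, coph_ref, rtol=1e-8)


def test_heights_nondecreasing_and_duplicate_twin(small_sim):
    ds, _ = small_sim
    pm = presence_matrix(ds, min_species=1)
    dg = ward_cluster(pm)
    assert np.all(np.diff(dg.heights) >= -1e-12)
    # adding a duplicate region profile: the twin pair merges first at 0
    M2 = np.vstack([pm.M, pm.M[0]])
    dg2 = ward_cluster(M2, labels=pm.region_ids + ["twin"])
    assert dg2.linkage[0, 2] == 0.0
    assert sorted(dg2.linkage[0, :2]) == [0, len(M2) - 1]


def test_permutation_invariance_of_heights():
    rng = np.random.default_rng(33)
    X = rng.normal(size=(7, 4))
    perm = rng.permutation(7)
    h1 = ward_cluster(X).heights
    h2 = ward_cluster(X[perm]).heights
    np.testing.assert_allclose(np.sort(h1), np.sort(h2), rtol=1e-9)


def test_newick_export():
    X = np.array([[0, 0], [0, 0.1], [5, 5]], float)
    dg = ward_cluster(X, labels=["a", "b", "c"])
    nwk = dg.to_newick()
    assert nwk.count("(") == 2 and nwk.endswith(";")
    assert nwk.index("a") < nwk.index("c") or "a" in nwk
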