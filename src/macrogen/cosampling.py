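"""Region co-sampling cluster analysis.

Which regions have been surveyed for the same species?  Each region becomes
a binary presence/absence profile over species; regions are clustered by
Ward's minimum-variance criterion on Euclidean distances, with input
distances squared during agglomeration and output heights square-rooted
(the Murtagh-Legendre correction), so heights are on the original distance
scale.  Only regions with at least five sampled species are considered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DiversityDataset


@dataclass
class PresenceMatrix:
    """Binary region-by-species matrix; 1 = species sampled in region."""

    M: np.ndarray
    region_ids: list[str]
    species: list[str]
    dropped: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.region_ids, columns=self.species)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-style linkage plus leaf labels.

    ``linkage`` rows are (cluster a, cluster b, height, size); leaves are
    numbered 0..n-1 in ``labels`` order, merged clusters n, n+1, ...
    Heights are nondecreasing.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string; a child's branch length is the height drop to it."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: f"{self.labels[i]}" for i in range(n)}
        for m, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = f"{node[a]}:{h - height[a]:.6g}"
            lb = f"{node[b]}:{h - height[b]:.6g}"
            node[n + m] = f"({la},{lb})"
            height[n + m] = h
        return node[n + len(self.linkage) - 1] + ";"


def presence_matrix(ds: DiversityDataset, min_species: int = 5) -> PresenceMatrix:
    """Region x species presence/absence from a dataset.

    Regions with fewer than ``min_species`` distinct species are dropped and
    reported; duplicate records of a species in a region still count once.
    """
    tab = pd.crosstab(ds.df["region"].astype(str), ds.df["species"])
    M = (tab.to_numpy() > 0).astype(int)
    rich = M.sum(axis=1)
    keep = rich >= min_species
    dropped = [str(r) for r, k in zip(tab.index, keep) if not k]
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 regions with >= {min_species} species sampled"
        )
    return PresenceMatrix(
        M=M[keep],
        region_ids=[str(r) for r, k in zip(tab.index, keep) if k],
        species=list(tab.columns),
        dropped=dropped,
    )


def ward_cluster(pm: PresenceMatrix | np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Ward minimum-variance clustering of region profiles.

    Pairwise Euclidean distances between rows are squared, agglomerated with
    the Lance-Williams Ward update, and merge heights square-rooted.  Ties in
    the merge criterion break toward the smallest (row-index) pair, making
    the output deterministic.
    """
    if isinstance(pm, PresenceMatrix):
        X = pm.M.astype(float)
        labels = list(pm.region_ids)
    else:
        X = np.asarray(pm, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    # squared Euclidean distances
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    # current distance store keyed by frozenset pair of active cluster ids
    dist = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for m in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (a, b) if a < b else (b, a)
                d = dist[key]
                if best is None or d < best[0] - 1e-15 or (
                    abs(d - best[0]) <= 1e-15 and key < best[1]
                ):
                    best = (d, key)
        d, (a, b) = best
        na, nb = size[a], size[b]
        # Lance-Williams Ward update to every other active cluster
        for c in active:
            if c in (a, b):
                continue
            nc = size[c]
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            dnew = ((na + nc) * dac + (nb + nc) * dbc - nc * d) / (na + nb + nc)
            dist[(min(c, next_id), max(c, next_id))] = dnew
        active = [c for c in active if c not in (a, b)] + [next_id]
        size[next_id] = na + nb
        Z[m] = [a, b, np.sqrt(max(d, 0.0)), na + nb]
        next_id += 1
    return Dendrogram(linkage=Z, labels=labels)
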