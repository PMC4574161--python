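"""Region adjacency and the intrinsic CAR prior for spatial region effects.

Regional diversity effects may be spatially autocorrelated, so the region
term R carries an intrinsic conditional-autoregressive (CAR) prior: given
its neighbours, a region's effect is normal around their weighted mean,

    R_i | R_-i  ~  Normal( sum_j w_ij R_j / w_i+ ,  1 / (tau_R * w_i+) ),

with w_i+ the row sum of the symmetric adjacency-weight matrix W.  Jointly
this is the improper Gaussian with precision tau_R * (D - W) (a graph
Laplacian), proper on the subspace orthogonal to the per-component constant
vector — identifiability comes from a sum-to-zero constraint per connected
component.  Weights can encode shared-boundary extent; a simple chain
adjacency emulating coastal regions ordered along the coastline is provided
as a fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd


@dataclass
class RegionGraph:
    """Ordered region ids and a symmetric nonnegative weight matrix W."""

    region_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.region_ids = [str(r) for r in self.region_ids]
        self.W = np.asarray(self.W, dtype=float)
        k = len(self.region_ids)
        if self.W.shape != (k, k):
            raise ValueError(f"W must be {k}x{k}")
        if np.any(self.W < 0):
            raise ValueError("adjacency weights must be nonnegative")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("adjacency matrix must have zero diagonal")

    @property
    def isolated(self) -> list[str]:
        return [r for r, s in zip(self.region_ids, self.W.sum(1)) if s == 0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.W, index=self.region_ids, columns=self.region_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionGraph":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(dtype=float))


@dataclass
class CarStructure:
    """Precision structure of the intrinsic CAR on a :class:`RegionGraph`.

    ``Q0 = D - W`` is the unscaled precision (graph Laplacian); the full
    precision is ``tau_R * Q0``.  ``rank`` is k minus the number of
    connected components; ``components`` labels each region's component.
    """

    graph: RegionGraph
    Q0: np.ndarray
    components: np.ndarray
    neighbors: list[list[int]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1

    @property
    def rank(self) -> int:
        return len(self.graph.region_ids) - self.n_components

    def neighbors_json(self) -> str:
        ids = self.graph.region_ids
        return json.dumps({ids[i]: [ids[j] for j in nb] for i, nb in enumerate(self.neighbors)})


def _components(W: np.ndarray) -> np.ndarray:
    k = W.shape[0]
    comp = -np.ones(k, dtype=int)
    c = 0
    for s in range(k):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = c
        while stack:
            i = stack.pop()
            for j in np.nonzero(W[i] > 0)[0]:
                if comp[j] < 0:
                    comp[j] = c
                    stack.append(j)
        c += 1
    return comp


def build_car(graph: RegionGraph, allow_isolated: bool = False) -> CarStructure:
    """Build the intrinsic CAR precision structure from region adjacency.

    Raises for isolated regions unless ``allow_isolated`` (the fallback gives
    such regions an independent-normal effect, handled by the models module
    through the zero Laplacian row).
    """
    if graph.isolated and not allow_isolated:
        raise ValueError(
            f"isolated regions {graph.isolated}; pass allow_isolated=True for an "
            "independent-normal fallback"
        )
    W = graph.W
    Q0 = np.diag(W.sum(axis=1)) - W
    comp = _components(W)
    neighbors = [list(np.nonzero(W[i] > 0)[0]) for i in range(W.shape[0])]
    return CarStructure(graph=graph, Q0=Q0, components=comp, neighbors=neighbors)


def chain_adjacency_fixture(
    k: int, weights: Sequence[float] | None = None, region_ids: Sequence[str] | None = None
) -> RegionGraph:
    """Path-graph adjacency for ``k`` regions ordered along a coastline.

    Region i is adjacent to i-1 and i+1, emulating coastal bioregions
    numbered consecutively along the coast.  ``weights`` optionally gives
    the k-1 edge weights (default all 1).
    """
    if k < 2:
        raise ValueError("need at least two regions")
    if weights is None:
        weights = [1.0] * (k - 1)
    if len(weights) != k - 1:
        raise ValueError(f"need {k - 1} edge weights, got {len(weights)}")
    W = np.zeros((k, k))
    for i, w in enumerate(weights):
        W[i, i + 1] = W[i + 1, i] = float(w)
    if region_ids is None:
        region_ids = [str(25 + i) for i in range(k)]  # coastal ids start at 25
    return RegionGraph(list(region_ids), W)


def sample_car(
    car: CarStructure, tau: float, size: int = 1, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw region effects from the intrinsic CAR via its spectral pseudo-inverse.

    Samples live on the sum-to-zero subspace of each connected component;
    covariance is the Moore-Penrose pseudo-inverse of ``tau * Q0``.
    Returns an array of shape ``(size, k)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    vals, vecs = np.linalg.eigh(car.Q0)
    pos = vals > 1e-10
    z = rng.standard_normal((size, pos.sum()))
    draws = z / np.sqrt(tau * vals[pos]) @ vecs[:, pos].T
    return draws
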