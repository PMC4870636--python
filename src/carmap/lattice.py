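"""Areal lattices: adjacency matrices for small-area models.

The spatial skeleton of the analysis is a set of ``n`` areal units together
with a binary, symmetric, zero-diagonal adjacency matrix ``W`` (``w_ij = 1``
iff areas *i* and *j* share a border).  Conditional autoregressive (CAR)
priors and Moran's I are both defined with respect to ``W``.

Real census micro-neighbourhoods have irregular contiguity; for synthetic
studies a rectangular grid with rook or queen contiguity is the standard
stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["AreaLattice", "LatticeSpec", "make_grid_adjacency"]


def _validate_adjacency(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.array_equal(W, W.T):
        raise ValueError("adjacency matrix must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("adjacency matrix must have a zero diagonal")
    if not np.isin(W, (0.0, 1.0)).all():
        raise ValueError("adjacency matrix must be binary")
    return W


@dataclass(frozen=True)
class AreaLattice:
    """A set of areal units with binary contiguity.

    Parameters
    ----------
    W
        Binary, symmetric, zero-diagonal ``(n, n)`` adjacency matrix.
    coords
        Optional ``(n, 2)`` array of (row, col) grid positions, used only for
        GeoJSON export of synthetic lattices.
    """

    W: np.ndarray
    coords: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "W", _validate_adjacency(self.W))
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (self.n_areas, 2):
                raise ValueError("coords must be (n_areas, 2)")
            object.__setattr__(self, "coords", coords)

    @property
    def n_areas(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Neighbour count ``d_k`` per area."""
        return self.W.sum(axis=1)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(csr_matrix(self.W), directed=False)
        return bool(n_comp == 1)

    def edge_list(self) -> pd.DataFrame:
        """Undirected edges (i < j) as a two-column frame."""
        i, j = np.nonzero(np.triu(self.W))
        return pd.DataFrame({"area_i": i, "area_j": j})

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper vertex colouring.

        Areas of one colour are pairwise non-adjacent, so their CAR full
        conditionals given the rest of the field are independent; MCMC site
        updates can then be vectorised colour by colour.
        """
        n = self.n_areas
        order = np.argsort(-self.degrees, kind="stable")
        color = np.full(n, -1, dtype=int)
        neighbours = [np.nonzero(self.W[k])[0] for k in range(n)]
        for k in order:
            used = {color[j] for j in neighbours[k] if color[j] >= 0}
            c = 0
            while c in used:
                c += 1
            color[k] = c
        return [np.nonzero(color == c)[0] for c in range(color.max() + 1)]

    @classmethod
    def from_edge_list(cls, n_areas: int, edges: pd.DataFrame) -> "AreaLattice":
        """Build a lattice from an edge-list frame with columns area_i, area_j."""
        W = np.zeros((n_areas, n_areas))
        i = np.asarray(edges["area_i"], dtype=int)
        j = np.asarray(edges["area_j"], dtype=int)
        W[i, j] = 1.0
        W[j, i] = 1.0
        return cls(W=W)

    def to_geojson(self) -> dict:
        """Unit-square polygons for grid lattices, as a GeoJSON mapping."""
        if self.coords is None:
            raise ValueError("lattice has no grid coordinates to export")
        features = []
        for k, (r, c) in enumerate(self.coords):
            ring = [[c, -r], [c + 1, -r], [c + 1, -r - 1], [c, -r - 1], [c, -r]]
            features.append(
                {
                    "type": "Feature",
                    "id": int(k),
                    "properties": {"area_id": int(k)},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        return {"type": "FeatureCollection", "features": features}


@dataclass(frozen=True)
class LatticeSpec:
    """Specification of a rectangular synthetic lattice."""

    n_rows: int
    n_cols: int
    adjacency_rule: str = "rook"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows * self.n_cols < 2:
            raise ValueError("degenerate 1x1 grid rejected")
        if self.adjacency_rule not in ("rook", "queen"):
            raise ValueError("adjacency_rule must be 'rook' or 'queen'")


def make_grid_adjacency(spec: LatticeSpec) -> AreaLattice:
    """Contiguity matrix of a rectangular grid.

    Rook contiguity joins cells sharing an edge (<= 4 neighbours); queen
    additionally joins diagonal cells (<= 8 neighbours).  Areas are numbered
    row-major.
    """
    nr, nc = spec.n_rows, spec.n_cols
    n = nr * nc
    W = np.zeros((n, n))
    if spec.adjacency_rule == "rook":
        steps = [(0, 1), (1, 0)]
    else:
        steps = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for r in range(nr):
        for c in range(nc):
            k = r * nc + c
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    j = rr * nc + cc
                    W[k, j] = W[j, k] = 1.0
    coords = np.array([(r, c) for r in range(nr) for c in range(nc)], dtype=float)
    return AreaLattice(W=W, coords=coords)
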