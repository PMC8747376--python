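"""Texture indicator channels: local Moran's I (LISA) and local binary patterns.

Both operators run on a scalar plane restricted to a boolean plot mask.
Adjacency is queen contiguity (the 8 surrounding pixels), restricted to
masked pixels; plots are irregular, so edge pixels simply keep their actual
neighbours and masked-out neighbours are excluded (no fill values).

Local Moran's I at pixel i is

    I_i = (x_i - mean) / var * sum_j w_ij (x_j - mean)

with mean and (population) variance taken over the plot's masked pixels and
w_ij one of four weight schemes on the neighbour graph:

* ``W`` row-standardised: w_ij = 1/deg(i); each row sums to 1.
* ``C`` globally standardised: w_ij = n / (total directed edge count);
  all weights sum to n.
* ``U``: w_ij = 1 / (total directed edge count); all weights sum to 1.
* ``B`` binary: w_ij = 1 on edges.

The LBP code of an interior masked pixel compares each of its 8 neighbours
g_p with the centre g_c and sets bit p when g_p - g_c >= 0 (note: ties set
the bit, so a constant plane codes 255 everywhere).  Bit 0 is the east
neighbour and bits proceed counter-clockwise (E, NE, N, NW, W, SW, S, SE);
for radius R > 1 the same 8 directions are taken at offset R (no
interpolation).  Pixels lacking a complete masked 8-neighbourhood are
excluded and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .exceptions import DegenerateInputError, GraphError

WeightScheme = Literal["W", "C", "U", "B"]

#: queen-contiguity offsets; also the LBP bit order (E, then counter-clockwise)
NEIGHBOR_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


@dataclass
class NeighborGraph:
    """Queen-contiguity graph over the masked pixels of a window.

    ``index`` maps grid positions to node ids (-1 outside the mask);
    ``adjacency`` is a symmetric boolean CSR matrix without self-edges.
    """

    mask: np.ndarray
    index: np.ndarray
    adjacency: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    @property
    def isolated(self) -> np.ndarray:
        """Boolean flag per node: True when the pixel has no masked neighbour."""
        return self.degrees == 0


def build_neighbor_graph(mask: np.ndarray) -> NeighborGraph:
    """8-connectivity adjacency restricted to the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise GraphError("empty mask")
    index = np.full(mask.shape, -1, dtype=np.int64)
    index[mask] = np.arange(n)
    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    h, w = mask.shape
    for dr, dc in NEIGHBOR_OFFSETS:
        sr = slice(max(dr, 0), h + min(dr, 0))
        sc = slice(max(dc, 0), w + min(dc, 0))
        tr = slice(max(-dr, 0), h + min(-dr, 0))
        tc = slice(max(-dc, 0), w + min(-dc, 0))
        both = mask[sr, sc] & mask[tr, tc]
        rows_i.append(index[sr, sc][both])
        rows_j.append(index[tr, tc][both])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    adjacency = sp.csr_matrix(
        (np.ones(i.size, dtype=bool), (i, j)), shape=(n, n)
    )
    return NeighborGraph(mask=mask, index=index, adjacency=adjacency)


def build_weights(graph: NeighborGraph, scheme: WeightScheme = "W") -> sp.csr_matrix:
    """Sparse weight matrix w_ij for the chosen scheme on ``graph``.

    Isolated pixels get an all-zero row under every scheme (flagged via
    ``graph.isolated``).
    """
    adj = graph.adjacency.astype(float)
    if scheme == "B":
        return adj
    total_edges = adj.nnz  # directed count: each neighbour pair twice
    if scheme == "C":
        return adj * (graph.n / total_edges)
    if scheme == "U":
        return adj * (1.0 / total_edges)
    if scheme == "W":
        deg = graph.degrees.astype(float)
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return sp.diags(inv) @ adj
    raise ValueError(f"unknown weight scheme {scheme!r}")


@dataclass
class LisaPlane:
    """Local Moran's I values over a plot window (NaN outside the mask)."""

    values: np.ndarray
    mask: np.ndarray
    scheme: WeightScheme
    global_mean: float
    global_variance: float
    n: int


def local_moran(
    plane: np.ndarray,
    mask: np.ndarray,
    scheme: WeightScheme = "W",
    graph: NeighborGraph | None = None,
) -> LisaPlane:
    """Per-pixel local Moran's I of ``plane`` over ``mask``.

    The "global" mean and population variance (divide by n) are taken over
    the masked pixels of this window.  A constant plane has zero variance
    and raises :class:`DegenerateInputError`; callers substitute a zero
    plane and flag the feature.
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(plane, dtype=float)[mask]
    n = x.size
    if n < 2:
        raise DegenerateInputError("local Moran's I needs >= 2 masked pixels")
    if np.ptp(x) == 0.0:  # exact check: summation noise can make var > 0
        raise DegenerateInputError("constant plane: zero global variance")
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))  # population variance
    if var == 0.0:
        raise DegenerateInputError("constant plane: zero global variance")
    if graph is None:
        graph = build_neighbor_graph(mask)
    weights = build_weights(graph, scheme)
    z = x - mean
    ii = (z / var) * (weights @ z)
    values = np.full(mask.shape, np.nan)
    values[mask] = ii
    return LisaPlane(
        values=values, mask=mask, scheme=scheme,
        global_mean=mean, global_variance=var, n=n,
    )


@dataclass
class LbpPlane:
    """LBP codes over a plot window; invalid pixels are -1 and excluded."""

    codes: np.ndarray
    valid: np.ndarray
    P: int
    R: int


def lbp(plane: np.ndarray, mask: np.ndarray, P: int = 8, R: int = 1) -> LbpPlane:
    """8-neighbour LBP codes of the masked pixels with full neighbourhoods."""
    if P != 8:
        raise ValueError("only the 8-neighbour configuration is supported")
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(plane, dtype=float)
    h, w = x.shape
    if h < 2 * R + 1 or w < 2 * R + 1:
        raise DegenerateInputError(
            f"window {h}x{w} smaller than the {2*R+1}x{2*R+1} LBP neighbourhood"
        )
    codes = np.zeros((h, w), dtype=np.int64)
    valid = mask.copy()
    for p, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        dr, dc = dr * R, dc * R
        shifted = np.full((h, w), np.nan)
        shifted_mask = np.zeros((h, w), dtype=bool)
        # shifted[r, c] = x[r + dr, c + dc] (the neighbour in direction p)
        tr = slice(max(-dr, 0), h + min(-dr, 0))
        tc = slice(max(-dc, 0), w + min(-dc, 0))
        sr = slice(max(dr, 0), h + min(dr, 0))
        sc = slice(max(dc, 0), w + min(dc, 0))
        shifted[tr, tc] = x[sr, sc]
        shifted_mask[tr, tc] = mask[sr, sc]
        valid &= shifted_mask
        with np.errstate(invalid="ignore"):
            bit = (shifted - x) >= 0
        codes |= np.where(bit, 1 << p, 0)
    codes = np.where(valid, codes, -1)
    return LbpPlane(codes=codes, valid=valid, P=P, R=R)
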