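"""Structural connectivity from voxel cost fields: minimum-cost-path networks.

Given a voxel label image (regions), a non-negative local cost image and a
fractional-anisotropy (FA) image, two networks are extracted per subject:

* **DMC** — for each region pair, the minimum cumulative cost to travel
  between the regions through the voxel grid. The search front is seeded at
  every source-region voxel with cost 0 (travel within the source region is
  free) and stops at the cheapest-reached target voxel, so adjacent regions
  get near-zero cost. The transition cost of a step u -> v is the physical
  step length (mm) times the mean of the two voxel costs.
* **DFA** — the sum of FA over the voxels of that optimal path (endpoints
  inclusive) divided by the straight-line distance (mm) between the path's
  endpoints (optionally by the path's arc length instead).

The local cost is a pluggable input; the default derives it from FA as
``c(v) = clip(1 - FA(v), eps, 1)`` so that coherent white-matter tracts
(high FA) are cheap to traverse.

Voxel neighbourhood is 26-connectivity; shortest paths use
:func:`scipy.sparse.csgraph.dijkstra` with a multi-source seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .atlas import RegionAtlas
from .network import ConnectivityNetwork, NetworkError

__all__ = [
    "VoxelGrid",
    "PathRecord",
    "cost_from_fa",
    "min_cost_path_network",
    "symmetrize_directed",
    "dfa_of_path",
]

COST_EPSILON = 1e-3


def cost_from_fa(fa: np.ndarray, eps: float = COST_EPSILON) -> np.ndarray:
    """Default local cost field: 1 - FA, clipped to [eps, 1]."""
    return np.clip(1.0 - np.asarray(fa, dtype=float), eps, 1.0)


@dataclass
class VoxelGrid:
    """Aligned voxel images feeding the minimum-cost-path extraction.

    Parameters
    ----------
    labels : (X, Y, Z) int array
        Region label image; 0 (or any value not in ``label_values``) is
        traversable background.
    fa : (X, Y, Z) float array in [0, 1]
    cost : (X, Y, Z) float array >= 0, optional
        Local cost; derived from FA via :func:`cost_from_fa` when omitted.
    voxel_size : (dx, dy, dz) in mm
    label_values : (r,) int array, optional
        Label value of each atlas region in atlas order; defaults to 1..r.
    """

    labels: np.ndarray
    fa: np.ndarray
    cost: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("label image must be 3-D")
        if self.fa.shape != self.labels.shape:
            raise ValueError("fa and labels must share shape")
        if self.cost is None:
            self.cost = cost_from_fa(self.fa)
        else:
            self.cost = np.asarray(self.cost, dtype=float)
            if self.cost.shape != self.labels.shape:
                raise ValueError("cost and labels must share shape")
            if np.nanmin(self.cost) < 0:
                raise ValueError("local cost must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be three positive lengths (mm)")

    def region_voxels(self, r: int) -> list[np.ndarray]:
        """Flat voxel indices of each of r regions, in atlas order."""
        values = (
            np.arange(1, r + 1)
            if self.label_values is None
            else np.asarray(self.label_values)
        )
        if len(values) != r:
            raise ValueError(f"label_values has {len(values)} entries, need {r}")
        flat = self.labels.ravel()
        return [np.flatnonzero(flat == v) for v in values]


@dataclass
class PathRecord:
    """One minimum-cost route between a region pair."""

    region_a: int
    region_b: int
    voxel_sequence: np.ndarray  # (k, 3) voxel coordinates, source -> target
    cumulative_cost: float
    fa_sum: float
    euclidean_mm: float
    arc_length_mm: float


def _grid_graph(cost: np.ndarray, voxel_size) -> sparse.csr_array:
    """Undirected 26-connectivity graph; w(u,v) = steplen * (c_u + c_v)/2."""
    shape = cost.shape
    idx = np.arange(cost.size).reshape(shape)
    dx, dy, dz = voxel_size
    rows, cols, vals = [], [], []
    offsets = [
        off
        for off in itertools.product((-1, 0, 1), repeat=3)
        if off > (0, 0, 0)  # half-space: each undirected edge once
    ]
    for off in offsets:
        sl_u, sl_v = [], []
        for o, n in zip(off, shape):
            if o == 0:
                sl_u.append(slice(None))
                sl_v.append(slice(None))
            elif o == 1:
                sl_u.append(slice(0, n - 1))
                sl_v.append(slice(1, n))
            else:
                sl_u.append(slice(1, n))
                sl_v.append(slice(0, n - 1))
        u = idx[tuple(sl_u)].ravel()
        v = idx[tuple(sl_v)].ravel()
        step = float(np.sqrt((off[0] * dx) ** 2 + (off[1] * dy) ** 2 + (off[2] * dz) ** 2))
        w = step * (cost.ravel()[u] + cost.ravel()[v]) / 2.0
        rows.append(u)
        cols.append(v)
        vals.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    g = sparse.coo_array(
        (np.concatenate([vals, vals]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(cost.size, cost.size),
    )
    return g.tocsr()


def _reconstruct(pred: np.ndarray, target: int) -> np.ndarray:
    """Flat-index path target -> seeded source, returned source -> target."""
    chain = [target]
    node = target
    while pred[node] >= 0:
        node = pred[node]
        chain.append(node)
    return np.asarray(chain[::-1], dtype=np.intp)


def min_cost_path_network(
    grid: VoxelGrid,
    atlas: RegionAtlas,
    path_length: str = "endpoint",
    keep_paths: bool = True,
):
    """Extract DMC and DFA networks (and the optimal paths) for one subject.

    Parameters
    ----------
    grid : VoxelGrid
    atlas : RegionAtlas
        Supplies r and the subject-independent region order.
    path_length : {"endpoint", "arc"}
        Denominator of DFA: straight-line endpoint distance (default) or the
        arc length of the voxel path.
    keep_paths : bool
        Whether to return per-pair :class:`PathRecord` objects.

    Returns
    -------
    (dmc, dfa, paths) : two :class:`ConnectivityNetwork` and a dict mapping
        region-position pairs (i, j), i < j, to :class:`PathRecord`.
        Empty regions and disconnected pairs come back masked.
    """
    if path_length not in ("endpoint", "arc"):
        raise ValueError("path_length must be 'endpoint' or 'arc'")
    r = atlas.r
    voxels = grid.region_voxels(r)
    empty = [i for i, v in enumerate(voxels) if v.size == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} region(s) have no voxels; their edges are masked",
            RuntimeWarning,
            stacklevel=2,
        )
    graph = _grid_graph(grid.cost, grid.voxel_size)
    shape = grid.labels.shape
    fa_flat = grid.fa.ravel()
    scale = np.asarray(grid.voxel_size)

    dmc = np.full((r, r), np.nan)
    dfa = np.full((r, r), np.nan)
    paths: dict[tuple[int, int], PathRecord] = {}

    for i in range(r - 1):
        if voxels[i].size == 0:
            continue
        dist, pred, sources = csgraph.dijkstra(
            graph,
            directed=False,
            indices=voxels[i],
            min_only=True,
            return_predecessors=True,
        )
        for j in range(i + 1, r):
            if voxels[j].size == 0:
                continue
            dj = dist[voxels[j]]
            k = int(np.argmin(dj))  # ties: first in flat (lexicographic) order
            if not np.isfinite(dj[k]):
                continue  # disconnected: leave masked
            target = int(voxels[j][k])
            chain = _reconstruct(pred, target)
            coords = np.column_stack(np.unravel_index(chain, shape)).astype(float)
            mm = coords * scale
            arc = float(np.linalg.norm(np.diff(mm, axis=0), axis=1).sum())
            euclid = float(np.linalg.norm(mm[-1] - mm[0]))
            fa_sum = float(fa_flat[chain].sum())
            denom = euclid if path_length == "endpoint" else arc
            dmc[i, j] = dmc[j, i] = float(dj[k])
            if denom > 0:
                dfa[i, j] = dfa[j, i] = fa_sum / denom
            rec = PathRecord(
                region_a=i,
                region_b=j,
                voxel_sequence=coords.astype(np.intp),
                cumulative_cost=float(dj[k]),
                fa_sum=fa_sum,
                euclidean_mm=euclid,
                arc_length_mm=arc,
            )
            if keep_paths:
                paths[(i, j)] = rec

    dmc_net = ConnectivityNetwork("DMC", dmc)
    dfa_net = ConnectivityNetwork("DFA", dfa)
    return dmc_net, dfa_net, paths


def symmetrize_directed(
    cost_directed: np.ndarray, dfa_directed: np.ndarray
) -> tuple[ConnectivityNetwork, ConnectivityNetwork]:
    """Fold externally supplied directed cost/DFA matrices to symmetric nets.

    Each unordered pair keeps the minimum of its two directed costs, and the
    DFA value of whichever direction attained it (ties resolved in favour of
    the i -> j direction with i < j).
    """
    c = np.asarray(cost_directed, dtype=float)
    d = np.asarray(dfa_directed, dtype=float)
    if c.shape != d.shape or c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise NetworkError(
            f"directed cost/DFA must be square and matched, got {c.shape} / {d.shape}"
        )
    forward_wins = c <= c.T  # on the upper triangle: i->j wins ties
    dmc = np.minimum(c, c.T)
    dfa = np.where(forward_wins, d, d.T)
    iu = np.triu_indices(c.shape[0], k=1)
    dfa_sym = np.full_like(dfa, np.nan)
    dfa_sym[iu] = dfa[iu]
    dfa_sym.T[iu] = dfa[iu]
    return (
        ConnectivityNetwork("DMC", dmc),
        ConnectivityNetwork("DFA", dfa_sym),
    )


def dfa_of_path(
    path: PathRecord, grid: VoxelGrid, path_length: str = "endpoint"
) -> float:
    """FA sum over a path's voxels divided by its endpoint distance (mm)."""
    coords = np.asarray(path.voxel_sequence, dtype=np.intp)
    if coords.shape[0] < 2:
        raise ValueError("path needs at least 2 voxels")
    mm = coords.astype(float) * np.asarray(grid.voxel_size)
    denom = (
        float(np.linalg.norm(mm[-1] - mm[0]))
        if path_length == "endpoint"
        else float(np.linalg.norm(np.diff(mm, axis=0), axis=1).sum())
    )
    if denom <= 0:
        raise ValueError("degenerate path: coincident endpoints")
    fa_sum = float(grid.fa[tuple(coords.T)].sum())
    return fa_sum / denom
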