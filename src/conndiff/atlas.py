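"""Region atlas, edge indexing and lobe-cluster bookkeeping.

The atlas fixes node identity for every network in an analysis: the order of
its regions defines matrix row/column order, and the strict upper triangle of
that matrix — linearized row-major, 0-based — defines the edge index used by
the statistics and plotting layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionAtlas",
    "EdgeIndex",
    "build_edge_index",
    "cluster_pair_label",
    "cluster_pair_of_edge",
    "edge_cluster_pairs",
    "adjacency_from_labels",
]

VALID_HEMISPHERES = frozenset({"L", "R", "none"})


class AtlasError(ValueError):
    """Invalid atlas definition (duplicate ids, too few regions, ...)."""


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of brain regions with hemisphere and lobe-cluster labels.

    Parameters
    ----------
    region_ids : sequence of str
        Unique identifiers; their order defines matrix row/column order.
    names : sequence of str
        Human-readable region names.
    hemispheres : sequence of str
        One of ``{"L", "R", "none"}`` per region.
    clusters : sequence of str
        Lobe-cluster label per region (e.g. Sub/Occ/Par/Temp/Fro/Cb).
    """

    region_ids: tuple[str, ...]
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    clusters: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        for attr in ("names", "hemispheres", "clusters"):
            if len(getattr(self, attr)) != n:
                raise AtlasError(f"{attr} length {len(getattr(self, attr))} != {n}")
        if len(set(self.region_ids)) != n:
            raise AtlasError("region ids must be unique")
        bad = set(self.hemispheres) - VALID_HEMISPHERES
        if bad:
            raise AtlasError(f"invalid hemisphere labels: {sorted(bad)}")
        object.__setattr__(
            self, "_index", {rid: i for i, rid in enumerate(self.region_ids)}
        )

    @property
    def r(self) -> int:
        """Number of regions."""
        return len(self.region_ids)

    @property
    def cluster_labels(self) -> tuple[str, ...]:
        """Distinct cluster labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.clusters:
            seen.setdefault(c)
        return tuple(seen)

    def position(self, region_id: str) -> int:
        try:
            return self._index[region_id]
        except KeyError:
            raise AtlasError(f"unknown region id {region_id!r}") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        required = {"region_id", "name", "hemisphere", "cluster"}
        missing = required - set(df.columns)
        if missing:
            raise AtlasError(f"atlas table missing columns {sorted(missing)}")
        return cls(
            tuple(df["region_id"].astype(str)),
            tuple(df["name"].astype(str)),
            tuple(df["hemisphere"].astype(str)),
            tuple(df["cluster"].astype(str)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "name": self.names,
                "hemisphere": self.hemispheres,
                "cluster": self.clusters,
            }
        )

    @classmethod
    def from_tsv(cls, path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class EdgeIndex:
    """Bijection between unordered region pairs (i, j), i < j, and [0, M).

    Linearization is row-major over the strict upper triangle, 0-based, so
    edge 0 is (0, 1) and edge M-1 is (r-2, r-1). M = r(r-1)/2.
    """

    def __init__(self, r: int) -> None:
        if r < 2:
            raise AtlasError(f"need at least 2 regions, got r={r}")
        self.r = int(r)
        self.n_edges = self.r * (self.r - 1) // 2
        iu = np.triu_indices(self.r, k=1)
        self._rows = iu[0].astype(np.intp)
        self._cols = iu[1].astype(np.intp)
        lin = np.full((self.r, self.r), -1, dtype=np.intp)
        lin[iu] = np.arange(self.n_edges)
        lin = np.maximum(lin, lin.T)
        self._lin = lin

    @property
    def pairs(self) -> np.ndarray:
        """(M, 2) array of region positions (i, j) with i < j."""
        return np.column_stack([self._rows, self._cols])

    def index_of(self, i: int, j: int) -> int:
        if i == j:
            raise AtlasError("diagonal (i == j) carries no edge")
        if not (0 <= i < self.r and 0 <= j < self.r):
            raise AtlasError(f"region position out of range: ({i}, {j})")
        return int(self._lin[i, j])

    def pair_of(self, e: int) -> tuple[int, int]:
        if not 0 <= e < self.n_edges:
            raise AtlasError(f"edge index {e} out of range [0, {self.n_edges})")
        return int(self._rows[e]), int(self._cols[e])

    def vector_from_matrix(self, mat: np.ndarray) -> np.ndarray:
        """Extract the strict upper triangle as an edge vector."""
        mat = np.asarray(mat)
        if mat.shape[-2:] != (self.r, self.r):
            raise AtlasError(f"matrix shape {mat.shape} does not match r={self.r}")
        return mat[..., self._rows, self._cols]

    def matrix_from_vector(self, vec: np.ndarray, diagonal=np.nan) -> np.ndarray:
        """Rebuild a symmetric matrix from an edge vector."""
        vec = np.asarray(vec)
        if vec.shape[-1] != self.n_edges:
            raise AtlasError(f"edge vector length {vec.shape[-1]} != {self.n_edges}")
        out = np.full(vec.shape[:-1] + (self.r, self.r), diagonal, dtype=vec.dtype)
        out[..., self._rows, self._cols] = vec
        out[..., self._cols, self._rows] = vec
        return out


def build_edge_index(atlas: RegionAtlas | int) -> EdgeIndex:
    """Edge index for an atlas (or a plain region count)."""
    r = atlas if isinstance(atlas, int) else atlas.r
    return EdgeIndex(r)


def cluster_pair_label(cluster_a: str, cluster_b: str) -> str:
    """Canonical unordered cluster-pair label, alphabetical, slash-joined."""
    a, b = sorted((cluster_a, cluster_b))
    return f"{a}/{b}"


def cluster_pair_of_edge(region_a: str, region_b: str, atlas: RegionAtlas) -> str:
    """Lobe-pair label of the edge between two regions (e.g. ``Fro/Temp``)."""
    ca = atlas.clusters[atlas.position(region_a)]
    cb = atlas.clusters[atlas.position(region_b)]
    return cluster_pair_label(ca, cb)


def edge_cluster_pairs(atlas: RegionAtlas, index: EdgeIndex | None = None) -> np.ndarray:
    """Cluster-pair label of every edge, in edge-index order."""
    if index is None:
        index = build_edge_index(atlas)
    clusters = np.asarray(atlas.clusters, dtype=object)
    pairs = index.pairs
    return np.array(
        [cluster_pair_label(clusters[i], clusters[j]) for i, j in pairs],
        dtype=object,
    )


def adjacency_from_labels(labels: np.ndarray, label_values: np.ndarray) -> np.ndarray:
    """Region adjacency from a 3D label image: regions sharing a voxel face.

    Parameters
    ----------
    labels : (X, Y, Z) integer array
        Voxel label image; values not in ``label_values`` are background.
    label_values : (r,) integer array
        Label value of each atlas region, in atlas order.

    Returns
    -------
    (r, r) boolean array, symmetric with zero diagonal.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise AtlasError("label image must be 3-D")
    label_values = np.asarray(label_values)
    r = len(label_values)
    pos = {int(v): i for i, v in enumerate(label_values)}
    adj = np.zeros((r, r), dtype=bool)
    for axis in range(3):
        a = np.moveaxis(labels, axis, 0)
        u, v = a[:-1], a[1:]
        touching = u != v
        for lu, lv in zip(u[touching].ravel(), v[touching].ravel()):
            iu, iv = pos.get(int(lu)), pos.get(int(lv))
            if iu is not None and iv is not None and iu != iv:
                adj[iu, iv] = adj[iv, iu] = True
    return adj
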