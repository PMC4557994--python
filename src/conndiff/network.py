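"""Per-subject connectivity networks: symmetric r x r weight matrices.

A network carries a *kind* tag — DMC (minimum cumulative path cost), DFA
(path fractional anisotropy per Euclidean distance), fMT (Pearson correlation
of mean time series) or fPC (partial correlation) — a symmetric weight matrix
and a symmetric missing-value mask. The diagonal is excluded from every
analysis and round-trips as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, build_edge_index

__all__ = ["NETWORK_KINDS", "ConnectivityNetwork", "filter_adjacent_edges"]

NETWORK_KINDS = ("DMC", "DFA", "fMT", "fPC")

#: kinds whose weights are correlations, bounded in [-1, 1]
CORRELATION_KINDS = frozenset({"fMT", "fPC"})


class NetworkError(ValueError):
    """Malformed connectivity network."""


def _check_symmetric(name: str, a: np.ndarray, mask: np.ndarray) -> None:
    ok = ~mask
    valid_both = ok & ok.T
    if not np.allclose(
        a[valid_both], a.T[valid_both], rtol=1e-10, atol=1e-12, equal_nan=True
    ):
        raise NetworkError(f"{name} must be symmetric on non-missing entries")


@dataclass
class ConnectivityNetwork:
    """One subject's symmetric weighted network of a given kind.

    Parameters
    ----------
    kind : {"DMC", "DFA", "fMT", "fPC"}
    weights : (r, r) float array
        Symmetric; entries under ``missing_mask`` are ignored (stored as NaN).
    missing_mask : (r, r) bool array, optional
        True where the edge is missing. The diagonal is always treated as
        missing. Defaults to NaN entries of ``weights``.
    subject_id : str
    """

    kind: str
    weights: np.ndarray
    missing_mask: np.ndarray | None = None
    subject_id: str = ""
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise NetworkError(f"unknown network kind {self.kind!r}")
        w = np.array(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkError(f"weights must be square, got shape {w.shape}")
        if self.missing_mask is None:
            mask = np.isnan(w)
        else:
            mask = np.array(self.missing_mask, dtype=bool)
            if mask.shape != w.shape:
                raise NetworkError("missing_mask shape must match weights")
            mask |= np.isnan(w)
        np.fill_diagonal(mask, True)
        mask |= mask.T  # an edge is one unordered pair: missing is symmetric
        w[mask] = np.nan
        if self.validate:
            _check_symmetric("weights", w, mask)
            vals = w[~mask]
            if self.kind in CORRELATION_KINDS and vals.size:
                if np.nanmax(np.abs(vals)) > 1 + 1e-8:
                    raise NetworkError(f"{self.kind} weights must lie in [-1, 1]")
            if self.kind == "DMC" and vals.size and np.nanmin(vals) < -1e-12:
                raise NetworkError("DMC weights must be non-negative")
        self.weights = w
        self.missing_mask = mask

    @property
    def r(self) -> int:
        return self.weights.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Strict-upper-triangle weights (NaN where missing), edge-index order."""
        return build_edge_index(self.r).vector_from_matrix(self.weights)

    # ---- I/O ------------------------------------------------------------

    def to_square_frame(self, atlas: RegionAtlas) -> pd.DataFrame:
        if atlas.r != self.r:
            raise NetworkError("atlas size does not match network")
        return pd.DataFrame(
            self.weights, index=atlas.region_ids, columns=atlas.region_ids
        )

    def to_square_csv(self, path, atlas: RegionAtlas) -> None:
        self.to_square_frame(atlas).to_csv(path, index_label="region_id")

    @classmethod
    def from_square_csv(
        cls, path, kind: str, atlas: RegionAtlas, subject_id: str = ""
    ) -> "ConnectivityNetwork":
        df = pd.read_csv(path, index_col=0)
        if list(df.columns) != list(atlas.region_ids) or list(df.index) != list(
            atlas.region_ids
        ):
            raise NetworkError("square CSV region order does not match atlas")
        return cls(kind, df.to_numpy(dtype=float), subject_id=subject_id)

    def to_long_frame(self, atlas: RegionAtlas) -> pd.DataFrame:
        """Long-format edges (region_a, region_b, weight); missing edges kept
        with empty weight so masking survives the round trip."""
        idx = build_edge_index(self.r)
        pairs = idx.pairs
        ids = np.asarray(atlas.region_ids, dtype=object)
        return pd.DataFrame(
            {
                "region_a": ids[pairs[:, 0]],
                "region_b": ids[pairs[:, 1]],
                "weight": self.edge_vector(),
            }
        )

    def to_long_tsv(self, path, atlas: RegionAtlas) -> None:
        self.to_long_frame(atlas).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(
        cls, path, kind: str, atlas: RegionAtlas, subject_id: str = ""
    ) -> "ConnectivityNetwork":
        df = pd.read_csv(path, sep="\t")
        idx = build_edge_index(atlas.r)
        pos = {rid: k for k, rid in enumerate(atlas.region_ids)}
        ia = df["region_a"].astype(str).map(pos)
        ib = df["region_b"].astype(str).map(pos)
        if ia.isna().any() or ib.isna().any():
            bad = df.loc[ia.isna() | ib.isna()].index[0]
            raise NetworkError(f"unknown region id in long TSV at row {bad}")
        vec = np.full(idx.n_edges, np.nan)
        lin = np.array(
            [idx.index_of(int(i), int(j)) for i, j in zip(ia, ib)], dtype=np.intp
        )
        vec[lin] = df["weight"].to_numpy(dtype=float)
        return cls(kind, idx.matrix_from_vector(vec), subject_id=subject_id)


def filter_adjacent_edges(
    network: ConnectivityNetwork, adjacency: np.ndarray
) -> ConnectivityNetwork:
    """Mask every edge whose two regions are spatially adjacent.

    Used to check whether a feature of a weight distribution (e.g. the
    near-zero DMC peak) is driven by neighbouring-region pairs. Non-adjacent
    entries pass through bit-identically.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != network.weights.shape:
        raise NetworkError(
            f"adjacency shape {adjacency.shape} != network {network.weights.shape}"
        )
    if adjacency.diagonal().any():
        raise NetworkError("adjacency diagonal must be zero")
    if not (adjacency == adjacency.T).all():
        raise NetworkError("adjacency must be symmetric")
    out = ConnectivityNetwork(
        network.kind,
        network.weights.copy(),
        network.missing_mask | adjacency,
        subject_id=network.subject_id,
        validate=False,
    )
    return out
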