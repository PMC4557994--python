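"""Deterministic plot-data builders for the three group-difference views.

Every figure is computed in two stages so the visual encodings are testable
without image comparison: a *builder* returns plain data (positions, bins,
RGBA colors) and a thin matplotlib wrapper draws it and writes SVG/PNG plus a
JSON sidecar.

* **Worm plot** — a Manhattan-plot derivative. Edges are grouped by lobe
  pair, sorted within each group by t-statistic, and plotted at
  y = -log10(p) * sign(t) * s. The scale s = log10(alpha)/log10(alpha_adj)
  pins the adjusted significance threshold at the same height,
  -log10(alpha), for every network kind, so one reference line serves all
  panels.
* **Bi-modal comparison plot** — per-kind 1D histograms and structural x
  functional 2D histograms of the two groups' mean networks (blue = group 0,
  red = group 1, magenta = overlap, opacity = count) or of t-statistics
  (green).
* **Connectogram** — regions on a circle grouped by lobe; edges below the
  adjusted threshold drawn as chords, red for positive t, blue for negative,
  opacity increasing with significance; node color saturation increasing
  with significant-edge degree.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless by design; builders never need a display
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb, to_hex

from .atlas import RegionAtlas, edge_cluster_pairs
from .network import ConnectivityNetwork
from .stats import CorrectionSpec, EdgeStatsResult

__all__ = [
    "worm_plot_data",
    "bimodal_plot_data",
    "connectogram_data",
    "matrix_plot_data",
    "draw_worm_plot",
    "draw_bimodal",
    "draw_connectogram",
    "draw_matrix",
    "save_figure",
]

GROUP0_RGB = (0.0, 0.0, 1.0)  # blue
GROUP1_RGB = (1.0, 0.0, 0.0)  # red
T_RGB = (0.0, 0.55, 0.0)  # green, t-statistic mode
CHORD_OPACITY_RANGE = (0.3, 1.0)
NODE_SATURATION_RANGE = (0.25, 1.0)


# --------------------------------------------------------------------------
# worm plot
# --------------------------------------------------------------------------


@dataclass
class WormPlotData:
    points: pd.DataFrame  # cluster_pair, within_index, x, edge, t, p, y
    reference_y: float  # -log10(alpha); lines drawn at +/- this height
    cluster_order: tuple[str, ...]
    kind: str = ""

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "reference_y": self.reference_y,
            "cluster_order": list(self.cluster_order),
            "points": self.points.to_dict(orient="list"),
        }


def worm_plot_data(
    stats: EdgeStatsResult,
    correction: CorrectionSpec,
    cluster_pairs: np.ndarray,
) -> WormPlotData:
    """Worm-plot coordinates: y = -log10(p) * sign(t) * s, sorted by t.

    Within each cluster pair, edges are sorted ascending by t (ties broken by
    edge index, stable) and spread evenly over the cluster's unit-width slot.
    An edge with p exactly at the adjusted threshold lands exactly on the
    reference line |y| = -log10(alpha).
    """
    t = np.asarray(stats.t, dtype=float)
    p = np.asarray(stats.p, dtype=float)
    cluster_pairs = np.asarray(cluster_pairs, dtype=object)
    if not (t.shape == p.shape == cluster_pairs.shape):
        raise ValueError("t, p and cluster_pairs must align")
    if np.any(p == 0):
        warnings.warn(
            "p-value underflow: clipping p=0 to the smallest positive float",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.where(p == 0, np.finfo(float).tiny, p)
    finite = np.isfinite(t) & np.isfinite(p)
    y = -np.log10(p) * np.sign(t) * correction.s

    order = tuple(sorted(set(cluster_pairs[finite])))
    frames = []
    for slot, label in enumerate(order):
        sel = np.flatnonzero((cluster_pairs == label) & finite)
        rank = sel[np.argsort(t[sel], kind="stable")]
        m = len(rank)
        frames.append(
            pd.DataFrame(
                {
                    "cluster_pair": label,
                    "within_index": np.arange(m),
                    "x": slot + (np.arange(m) + 0.5) / m,
                    "edge": rank,
                    "t": t[rank],
                    "p": p[rank],
                    "y": y[rank],
                }
            )
        )
    points = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["cluster_pair", "within_index", "x", "edge", "t", "p", "y"]
        )
    )
    return WormPlotData(
        points=points,
        reference_y=float(-np.log10(correction.alpha)),
        cluster_order=order,
        kind=stats.kind,
    )


# --------------------------------------------------------------------------
# bi-modal comparison plot
# --------------------------------------------------------------------------


def bimodal_rgba(count0: np.ndarray, count1: np.ndarray) -> np.ndarray:
    """Per-bin RGBA: blue for pure group 0, red for pure group 1, blended
    toward magenta in proportion to the mix; opacity = total / max total."""
    count0 = np.asarray(count0, dtype=float)
    count1 = np.asarray(count1, dtype=float)
    total = count0 + count1
    top = total.max() if total.size else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(total > 0, count1 / np.where(total > 0, total, 1.0), 0.0)
    rgb = (
        np.multiply.outer(1.0 - w1, GROUP0_RGB)
        + np.multiply.outer(w1, GROUP1_RGB)
    )
    alpha = total / top if top > 0 else np.zeros_like(total)
    return np.concatenate([rgb, alpha[..., None]], axis=-1)


@dataclass
class BimodalGrid:
    mode: str  # "group_means" | "t_stats"
    hist1d: dict  # kind -> {"bin_edges", "counts"} counts: (2, b) or (b,)
    hist2d: dict  # (structural kind, functional kind) -> {"x_edges",
    #               "y_edges", "counts" (2, bx, by) or (bx, by), "rgba"}
    structural_kinds: tuple[str, ...] = ()
    functional_kinds: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "structural_kinds": list(self.structural_kinds),
            "functional_kinds": list(self.functional_kinds),
            "hist1d": {
                k: {kk: np.asarray(vv).tolist() for kk, vv in v.items()}
                for k, v in self.hist1d.items()
            },
            "hist2d": {
                f"{a}|{b}": {
                    kk: np.asarray(vv).tolist() for kk, vv in v.items()
                }
                for (a, b), v in self.hist2d.items()
            },
        }


def _finite_edge_vectors(pair) -> tuple[np.ndarray, np.ndarray]:
    n0, n1 = pair
    return n0.edge_vector(), n1.edge_vector()


def bimodal_plot_data(
    data: dict,
    structural_kinds=("DMC", "DFA"),
    functional_kinds=("fMT", "fPC"),
    mode: str = "group_means",
    bins_1d: int = 100,
    bins_2d: int = 64,
) -> BimodalGrid:
    """Histograms for the bi-modal network comparison plot.

    Parameters
    ----------
    data : dict
        ``group_means`` mode: kind -> (group0 mean network, group1 mean
        network). ``t_stats`` mode: kind -> :class:`EdgeStatsResult`.
    structural_kinds, functional_kinds
        Which kinds form the rows/columns of the 2D panel grid.
    bins_1d, bins_2d : int
        Histogram resolution (>= 2).
    """
    if mode not in ("group_means", "t_stats"):
        raise ValueError(f"unknown mode {mode!r}")
    if bins_1d < 2 or bins_2d < 2:
        raise ValueError("need at least 2 bins")

    vectors: dict[str, np.ndarray] = {}  # kind -> (2, M) or (M,)
    for kind, payload in data.items():
        if mode == "group_means":
            v0, v1 = _finite_edge_vectors(payload)
            vectors[kind] = np.vstack([v0, v1])
        else:
            vectors[kind] = np.asarray(payload.t, dtype=float)

    hist1d = {}
    for kind, vec in vectors.items():
        flat = vec.ravel()
        finite = flat[np.isfinite(flat)]
        if finite.size == 0:
            raise ValueError(f"no finite values for kind {kind!r}")
        edges = np.histogram_bin_edges(finite, bins=bins_1d)
        if mode == "group_means":
            counts = np.stack(
                [
                    np.histogram(row[np.isfinite(row)], bins=edges)[0]
                    for row in vec
                ]
            )
        else:
            counts = np.histogram(finite, bins=edges)[0]
        hist1d[kind] = {"bin_edges": edges, "counts": counts}

    hist2d = {}
    for sk in structural_kinds:
        for fk in functional_kinds:
            if sk not in vectors or fk not in vectors:
                continue
            xs, ys = vectors[sk], vectors[fk]
            x_edges = hist1d[sk]["bin_edges"]
            y_edges = hist1d[fk]["bin_edges"]
            x_edges = np.histogram_bin_edges(
                x_edges[[0, -1]], bins=bins_2d
            )
            y_edges = np.histogram_bin_edges(y_edges[[0, -1]], bins=bins_2d)
            if mode == "group_means":
                counts = []
                for gi in (0, 1):
                    ok = np.isfinite(xs[gi]) & np.isfinite(ys[gi])
                    counts.append(
                        np.histogram2d(
                            xs[gi][ok], ys[gi][ok], bins=(x_edges, y_edges)
                        )[0]
                    )
                counts = np.stack(counts)
                rgba = bimodal_rgba(counts[0], counts[1])
            else:
                ok = np.isfinite(xs) & np.isfinite(ys)
                counts = np.histogram2d(xs[ok], ys[ok], bins=(x_edges, y_edges))[0]
                top = counts.max() if counts.size else 0.0
                alpha = counts / top if top > 0 else np.zeros_like(counts)
                rgba = np.concatenate(
                    [
                        np.broadcast_to(T_RGB, counts.shape + (3,)),
                        alpha[..., None],
                    ],
                    axis=-1,
                )
            hist2d[(sk, fk)] = {
                "x_edges": x_edges,
                "y_edges": y_edges,
                "counts": counts,
                "rgba": rgba,
            }
    return BimodalGrid(
        mode=mode,
        hist1d=hist1d,
        hist2d=hist2d,
        structural_kinds=tuple(k for k in structural_kinds if k in vectors),
        functional_kinds=tuple(k for k in functional_kinds if k in vectors),
    )


# --------------------------------------------------------------------------
# connectogram
# --------------------------------------------------------------------------


@dataclass
class ConnectogramData:
    nodes: pd.DataFrame  # region_id, cluster, angle_deg, degree, saturation,
    #                      rgba
    edges: pd.DataFrame  # edge, region_a, region_b, t, p, neglog10p, rgba
    alpha_adj: float
    kind: str = ""

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind,
            "alpha_adj": self.alpha_adj,
            "nodes": self.nodes.to_dict(orient="list"),
            "edges": self.edges.to_dict(orient="list"),
        }


def _cluster_hues(clusters) -> dict[str, float]:
    labels = list(dict.fromkeys(clusters))
    return {c: i / max(len(labels), 1) for i, c in enumerate(labels)}


def connectogram_data(
    stats: EdgeStatsResult,
    correction: CorrectionSpec,
    atlas: RegionAtlas,
) -> ConnectogramData:
    """Node layout and chord list for the significant-connection circle.

    Regions sit on a circle, grouped contiguously by cluster, with equal
    angular spacing 360/r. Edges with p < alpha_adj become chords: red for
    t > 0, blue for t < 0, opacity an affine map of -log10(p) from
    [-log10(alpha_adj), max over drawn edges] onto [0.3, 1.0]. Node color
    saturation rises affinely with the node's significant-edge degree
    (0 -> 0.25, max degree -> 1.0). Zero significant edges is a valid,
    nodes-only result.
    """
    r = atlas.r
    if stats.edge_index is None or stats.edge_index.r != r:
        raise ValueError("stats edge index does not match atlas")
    # contiguous cluster grouping, stable within cluster by atlas order
    order = sorted(range(r), key=lambda i: (atlas.clusters[i], i))
    angle = {node: 360.0 * k / r for k, node in enumerate(order)}

    p = np.asarray(stats.p, dtype=float)
    t = np.asarray(stats.t, dtype=float)
    drawn = np.flatnonzero(np.isfinite(p) & np.isfinite(t) & (p < correction.alpha_adj))
    pairs = stats.edge_index.pairs

    neglog = -np.log10(np.maximum(p[drawn], np.finfo(float).tiny))
    lo = -np.log10(correction.alpha_adj)
    hi = neglog.max() if drawn.size else lo
    o_lo, o_hi = CHORD_OPACITY_RANGE
    if hi > lo:
        opacity = o_lo + (o_hi - o_lo) * (neglog - lo) / (hi - lo)
    else:
        opacity = np.full(drawn.shape, o_hi)
    rgba = [
        (
            (*GROUP1_RGB, float(op))
            if t[e] > 0
            else (*GROUP0_RGB, float(op))
        )
        for e, op in zip(drawn, opacity)
    ]
    ids = np.asarray(atlas.region_ids, dtype=object)
    edges = pd.DataFrame(
        {
            "edge": drawn,
            "region_a": ids[pairs[drawn, 0]] if drawn.size else [],
            "region_b": ids[pairs[drawn, 1]] if drawn.size else [],
            "angle_a": [angle[i] for i in pairs[drawn, 0]],
            "angle_b": [angle[j] for j in pairs[drawn, 1]],
            "t": t[drawn],
            "p": p[drawn],
            "neglog10p": neglog,
            "rgba": rgba,
        }
    )

    degree = np.zeros(r, dtype=int)
    for e in drawn:
        degree[pairs[e, 0]] += 1
        degree[pairs[e, 1]] += 1
    s_lo, s_hi = NODE_SATURATION_RANGE
    max_deg = degree.max()
    sat = (
        s_lo + (s_hi - s_lo) * degree / max_deg
        if max_deg > 0
        else np.full(r, s_lo)
    )
    hues = _cluster_hues(atlas.clusters)
    node_rgba = [
        (*hsv_to_rgb((hues[atlas.clusters[i]], sat[i], 0.9)), 1.0)
        for i in range(r)
    ]
    nodes = pd.DataFrame(
        {
            "region_id": ids,
            "cluster": atlas.clusters,
            "angle_deg": [angle[i] for i in range(r)],
            "degree": degree,
            "saturation": sat,
            "rgba": node_rgba,
        }
    )
    return ConnectogramData(
        nodes=nodes,
        edges=edges,
        alpha_adj=float(correction.alpha_adj),
        kind=stats.kind,
    )


# --------------------------------------------------------------------------
# matrix view
# --------------------------------------------------------------------------


def matrix_plot_data(source, atlas: RegionAtlas | None = None) -> dict:
    """Square heatmap grid of weights (network) or t-values (edge stats)."""
    if isinstance(source, ConnectivityNetwork):
        mat = source.weights.copy()
        label = source.kind
    elif isinstance(source, EdgeStatsResult):
        if source.edge_index is None:
            raise ValueError("edge stats carry no edge index")
        mat = source.edge_index.matrix_from_vector(
            np.asarray(source.t, dtype=float)
        )
        label = f"{source.kind} t"
    else:
        raise TypeError("source must be a ConnectivityNetwork or EdgeStatsResult")
    return {
        "matrix": mat,
        "mask": ~np.isfinite(mat),
        "label": label,
        "region_ids": list(atlas.region_ids) if atlas is not None else None,
    }


# --------------------------------------------------------------------------
# drawing wrappers
# --------------------------------------------------------------------------


def save_figure(fig, basepath, data=None, dpi: int = 150) -> list[str]:
    """Write <basepath>.svg and .png (and .json sidecar when data given)."""
    written = []
    for ext in ("svg", "png"):
        out = f"{basepath}.{ext}"
        fig.savefig(out, dpi=dpi, bbox_inches="tight")
        written.append(out)
    if data is not None:
        out = f"{basepath}.json"
        with open(out, "w") as fh:
            json.dump(data.to_json_dict() if hasattr(data, "to_json_dict") else data,
                      fh, indent=1, default=float)
        written.append(out)
    return written


def draw_worm_plot(data: WormPlotData, ax=None, point_size: float = 4.0):
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 1.2 * len(data.cluster_order)), 4))
    pts = data.points
    for label in data.cluster_order:
        sub = pts[pts["cluster_pair"] == label]
        ax.scatter(sub["x"], sub["y"], s=point_size, linewidths=0)
    for sign in (1, -1):
        ax.axhline(sign * data.reference_y, color="0.4", ls="--", lw=0.8)
    ax.axhline(0.0, color="0.8", lw=0.6)
    ax.set_xticks([i + 0.5 for i in range(len(data.cluster_order))])
    ax.set_xticklabels(data.cluster_order, rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10}(p)\,\mathrm{sign}(t)\,s$")
    ax.set_title(f"{data.kind} worm plot")
    return ax


def draw_bimodal(grid: BimodalGrid, fig=None):
    s_kinds, f_kinds = grid.structural_kinds, grid.functional_kinds
    nrow, ncol = len(f_kinds) + 1, len(s_kinds) + 1
    if fig is None:
        fig = plt.figure(figsize=(2.6 * ncol, 2.6 * nrow))
    axes = fig.subplots(nrow, ncol, squeeze=False)
    axes[0][0].axis("off")
    colors = (GROUP0_RGB, GROUP1_RGB) if grid.mode == "group_means" else (T_RGB,)
    for c, sk in enumerate(s_kinds):  # top row: structural 1D
        ax = axes[0][c + 1]
        h = grid.hist1d[sk]
        rows = np.atleast_2d(h["counts"])
        for color, row in zip(colors, rows):
            ax.stairs(row, h["bin_edges"], color=color, alpha=0.6, fill=True)
        ax.set_title(sk, fontsize=9)
    for r_, fk in enumerate(f_kinds):  # left column: functional 1D
        ax = axes[r_ + 1][0]
        h = grid.hist1d[fk]
        rows = np.atleast_2d(h["counts"])
        for color, row in zip(colors, rows):
            ax.stairs(
                row,
                h["bin_edges"],
                color=color,
                alpha=0.6,
                fill=True,
                orientation="horizontal",
            )
        ax.invert_xaxis()
        ax.set_ylabel(fk, fontsize=9)
    for r_, fk in enumerate(f_kinds):
        for c, sk in enumerate(s_kinds):
            ax = axes[r_ + 1][c + 1]
            h = grid.hist2d[(sk, fk)]
            # imshow expects (rows=y, cols=x)
            ax.imshow(
                np.transpose(h["rgba"], (1, 0, 2)),
                origin="lower",
                aspect="auto",
                extent=(
                    h["x_edges"][0],
                    h["x_edges"][-1],
                    h["y_edges"][0],
                    h["y_edges"][-1],
                ),
                interpolation="nearest",
            )
    fig.suptitle(f"bi-modal comparison ({grid.mode})")
    return fig


def draw_connectogram(data: ConnectogramData, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6), subplot_kw={"aspect": "equal"})
    th = np.deg2rad(data.nodes["angle_deg"].to_numpy(dtype=float))
    x, y = np.cos(th), np.sin(th)
    for _, e in data.edges.iterrows():
        a = np.deg2rad(e["angle_a"])
        b = np.deg2rad(e["angle_b"])
        # quadratic Bezier chord through a point pulled toward the centre
        p0 = np.array([np.cos(a), np.sin(a)])
        p2 = np.array([np.cos(b), np.sin(b)])
        p1 = (p0 + p2) / 4.0
        tgrid = np.linspace(0, 1, 32)[:, None]
        curve = (1 - tgrid) ** 2 * p0 + 2 * (1 - tgrid) * tgrid * p1 + tgrid**2 * p2
        ax.plot(curve[:, 0], curve[:, 1], color=e["rgba"], lw=1.0)
    ax.scatter(x, y, c=list(data.nodes["rgba"]), s=30, zorder=3)
    for xi, yi, rid, ang in zip(
        x, y, data.nodes["region_id"], data.nodes["angle_deg"]
    ):
        ax.text(
            1.06 * xi,
            1.06 * yi,
            str(rid),
            fontsize=5,
            rotation=ang if -90 <= ((ang + 90) % 360) - 90 <= 90 else ang + 180,
            ha="center",
            va="center",
        )
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.axis("off")
    ax.set_title(f"{data.kind}: {len(data.edges)} significant connections")
    return ax


def draw_matrix(data: dict, ax=None, cmap: str = "viridis"):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mat = np.ma.masked_invalid(data["matrix"])
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad("0.85")  # distinct null color for masked edges and diagonal
    im = ax.imshow(mat, cmap=cm, interpolation="nearest")
    plt.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(data["label"])
    return ax
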