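"""Plot-data builders: worm plot, bi-modal histograms, connectogram, matrix."""

import numpy as np
import pytest

from conndiff.atlas import build_edge_index, edge_cluster_pairs
from conndiff.network import ConnectivityNetwork
from conndiff.stats import EdgeStatsResult, adjusted_threshold
from conndiff.viz import (
    bimodal_plot_data,
    bimodal_rgba,
    connectogram_data,
    matrix_plot_data,
    worm_plot_data,
)


def _stats(t, p, r=None, kind="DMC"):
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    M = len(t)
    if r is None:
        r = 2
        while r * (r - 1) // 2 < M:
            r += 1
    idx = build_edge_index(r)
    full_t = np.full(idx.n_edges, np.nan)
    full_p = np.full(idx.n_edges, np.nan)
    full_t[:M] = t
    full_p[:M] = p
    return EdgeStatsResult(
        kind=kind,
        beta=full_t.copy(),
        t=full_t,
        p=full_p,
        group_means=np.zeros((2, idx.n_edges)),
        n_used=np.full(idx.n_edges, 10),
        df=np.full(idx.n_edges, 8.0),
        edge_index=idx,
    )


def _labels(stats):
    return np.array(["A/A"] * stats.edge_index.n_edges, dtype=object)


class TestWormPlot:
    def test_edge_at_threshold_lands_on_reference_line(self):
        corr = adjusted_threshold(0.05, 37.3)
        stats = _stats([2.0], [corr.alpha_adj])
        data = worm_plot_data(stats, corr, _labels(stats))
        row = data.points[data.points["edge"] == 0].iloc[0]
        assert abs(row["y"]) == pytest.approx(-np.log10(0.05), abs=1e-12)
        assert data.reference_y == pytest.approx(-np.log10(0.05))

    def test_formula_example_meff_100(self):
        corr = adjusted_threshold(0.05, 100.0)
        stats = _stats([1.7], [0.01])
        data = worm_plot_data(stats, corr, _labels(stats))
        row = data.points[data.points["edge"] == 0].iloc[0]
        assert row["y"] == pytest.approx(2 * 0.3941, abs=2e-4)

    def test_p_of_one_maps_to_zero(self):
        corr = adjusted_threshold(0.05, 10.0)
        for t in (3.0, -3.0):
            stats = _stats([t], [1.0])
            data = worm_plot_data(stats, corr, _labels(stats))
            assert data.points["y"].iloc[0] == 0.0

    def test_sign_follows_t(self):
        corr = adjusted_threshold(0.05, 10.0)
        stats = _stats([2.0, -2.0], [0.01, 0.01])
        data = worm_plot_data(stats, corr, _labels(stats))
        by_edge = data.points.set_index("edge")["y"]
        assert by_edge[0] > 0 > by_edge[1]
        assert by_edge[0] == pytest.approx(-by_edge[1])

    def test_points_sorted_ascending_by_t_within_cluster(self, rng):
        corr = adjusted_threshold(0.05, 5.0)
        t = rng.normal(size=10)
        p = rng.uniform(0.001, 1, size=10)
        stats = _stats(t, p)
        labels = _labels(stats)
        data = worm_plot_data(stats, corr, labels)
        sub = data.points[data.points["cluster_pair"] == "A/A"]
        assert (np.diff(sub["t"]) >= 0).all()
        # x positions are a permutation of the cluster's edges
        finite = np.isfinite(stats.t)
        assert sorted(sub["edge"]) == sorted(np.flatnonzero(finite))

    def test_stable_tie_break_by_edge_index(self):
        corr = adjusted_threshold(0.05, 5.0)
        stats = _stats([1.0, 1.0, 1.0], [0.5, 0.4, 0.3])
        data = worm_plot_data(stats, corr, _labels(stats))
        assert list(data.points["edge"][:3]) == [0, 1, 2]

    def test_p_zero_clipped_with_warning(self):
        corr = adjusted_threshold(0.05, 5.0)
        stats = _stats([2.0], [0.0])
        with pytest.warns(RuntimeWarning, match="underflow"):
            data = worm_plot_data(stats, corr, _labels(stats))
        assert np.isfinite(data.points["y"].iloc[0])


class TestBimodal:
    def _mean_nets(self, rng, r=6):
        idx = build_edge_index(r)
        out = {}
        for kind in ("DMC", "fMT"):
            nets = []
            for _ in range(2):
                vec = (
                    np.abs(rng.normal(size=idx.n_edges))
                    if kind == "DMC"
                    else np.clip(rng.normal(0, 0.3, idx.n_edges), -1, 1)
                )
                nets.append(
                    ConnectivityNetwork(kind, idx.matrix_from_vector(vec))
                )
            out[kind] = tuple(nets)
        return out

    def test_counts_conserved_per_group(self, rng):
        data = self._mean_nets(rng)
        grid = bimodal_plot_data(
            data, structural_kinds=("DMC",), functional_kinds=("fMT",),
            bins_1d=10, bins_2d=8,
        )
        M = 15
        for kind in ("DMC", "fMT"):
            counts = grid.hist1d[kind]["counts"]
            assert counts.shape[0] == 2
            assert counts.sum(axis=1).tolist() == [M, M]
        counts2 = grid.hist2d[("DMC", "fMT")]["counts"]
        assert counts2.sum(axis=(1, 2)).tolist() == [M, M]

    def test_color_rules(self):
        rgba = bimodal_rgba(np.array([4.0, 0.0, 2.0, 0.0]),
                            np.array([0.0, 4.0, 2.0, 0.0]))
        np.testing.assert_allclose(rgba[0], [0, 0, 1, 1])  # pure group0: blue
        np.testing.assert_allclose(rgba[1], [1, 0, 0, 1])  # pure group1: red
        np.testing.assert_allclose(rgba[2], [0.5, 0, 0.5, 1])  # magenta mix
        assert rgba[3][3] == 0.0  # empty bin fully transparent

    def test_t_mode_green(self, rng):
        stats = {
            "DMC": _stats(rng.normal(size=15), rng.uniform(0.01, 1, 15), r=6),
            "fMT": _stats(
                rng.normal(size=15), rng.uniform(0.01, 1, 15), r=6, kind="fMT"
            ),
        }
        grid = bimodal_plot_data(
            stats, structural_kinds=("DMC",), functional_kinds=("fMT",),
            mode="t_stats", bins_1d=8, bins_2d=6,
        )
        rgba = grid.hist2d[("DMC", "fMT")]["rgba"]
        filled = rgba[..., 3] > 0
        assert filled.any()
        np.testing.assert_allclose(
            rgba[filled][:, :3], np.broadcast_to((0.0, 0.55, 0.0), (filled.sum(), 3))
        )

    def test_too_few_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            bimodal_plot_data(self._mean_nets(rng), bins_1d=1)


class TestConnectogram:
    def test_equal_angular_spacing(self, tiny_atlas):
        stats = _stats([1.0], [0.5], r=6)
        corr = adjusted_threshold(0.05, 2.0)
        data = connectogram_data(stats, corr, tiny_atlas)
        angles = np.sort(data.nodes["angle_deg"].to_numpy())
        np.testing.assert_allclose(np.diff(angles), 60.0)

    def test_no_significant_edges_is_valid(self, tiny_atlas):
        stats = _stats(np.ones(15), np.full(15, 0.9), r=6)
        corr = adjusted_threshold(0.05, 2.0)
        data = connectogram_data(stats, corr, tiny_atlas)
        assert len(data.edges) == 0
        assert len(data.nodes) == 6
        assert (data.nodes["saturation"] == 0.25).all()

    def test_drawn_edges_match_threshold_count(self, tiny_atlas, rng):
        p = rng.uniform(0, 1, 15)
        stats = _stats(rng.normal(size=15), p, r=6)
        corr = adjusted_threshold(0.05, 1.5)
        data = connectogram_data(stats, corr, tiny_atlas)
        assert len(data.edges) == int((p < corr.alpha_adj).sum())

    def test_opacity_monotone_in_significance(self, tiny_atlas):
        corr = adjusted_threshold(0.05, 2.0)
        stats = _stats(
            [2.0, 2.0], [corr.alpha_adj * 0.99, corr.alpha_adj / 100], r=6
        )
        data = connectogram_data(stats, corr, tiny_atlas)
        op = data.edges.set_index("edge")["rgba"].map(lambda c: c[3])
        assert op[1] > op[0]

    def test_chord_colors_follow_t_sign(self, tiny_atlas):
        corr = adjusted_threshold(0.05, 2.0)
        stats = _stats([3.0, -3.0], [1e-5, 1e-5], r=6)
        data = connectogram_data(stats, corr, tiny_atlas)
        colors = data.edges.set_index("edge")["rgba"]
        assert colors[0][:3] == (1.0, 0.0, 0.0)  # positive t: red
        assert colors[1][:3] == (0.0, 0.0, 1.0)  # negative t: blue

    def test_node_saturation_affine_in_degree(self, tiny_atlas):
        corr = adjusted_threshold(0.05, 2.0)
        # edges 0 (0-1) and 1 (0-2) significant: node 0 degree 2, 1 and 2
        # degree 1, rest 0
        stats = _stats([3.0, 3.0], [1e-6, 1e-6], r=6)
        data = connectogram_data(stats, corr, tiny_atlas)
        sat = data.nodes.set_index("region_id")["saturation"]
        assert sat["FroL"] == pytest.approx(1.0)
        assert sat["FroR"] == pytest.approx(0.25 + 0.75 * 0.5)
        assert sat["OccR"] == pytest.approx(0.25)

    def test_clusters_contiguous_on_circle(self, tiny_atlas):
        stats = _stats([1.0], [0.9], r=6)
        corr = adjusted_threshold(0.05, 2.0)
        data = connectogram_data(stats, corr, tiny_atlas)
        ordered = data.nodes.sort_values("angle_deg")["cluster"].tolist()
        # each cluster occupies one contiguous arc
        seen, prev = set(), None
        for c in ordered:
            if c != prev:
                assert c not in seen
                seen.add(c)
            prev = c


class TestMatrix:
    def test_symmetric_grid(self, rng):
        idx = build_edge_index(5)
        net = ConnectivityNetwork(
            "DFA", idx.matrix_from_vector(np.abs(rng.normal(size=10)))
        )
        data = matrix_plot_data(net)
        m = data["matrix"]
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_array_equal(m[off], m.T[off])

    def test_diagonal_and_masked_edges_null(self, rng):
        idx = build_edge_index(4)
        vec = np.abs(rng.normal(size=6))
        vec[2] = np.nan
        net = ConnectivityNetwork("DMC", idx.matrix_from_vector(vec))
        data = matrix_plot_data(net)
        assert data["mask"].diagonal().all()
        i, j = idx.pair_of(2)
        assert data["mask"][i, j] and data["mask"][j, i]

    def test_t_matrix_from_stats(self, rng):
        stats = _stats(rng.normal(size=15), rng.uniform(0.1, 1, 15), r=6)
        data = matrix_plot_data(stats)
        assert data["matrix"].shape == (6, 6)
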