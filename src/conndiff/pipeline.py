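"""Staged pipeline over a working directory; the CLI is a thin shell on top.

Stage outputs live in a fixed layout under one output directory::

    atlas.tsv  subjects.tsv  manifest_<stage>.json
    timeseries/<subject>.tsv
    images/<subject>_{labels,fa,cost}.nii.gz
    networks/<kind>/<subject>.tsv        (long-format edges)
    tables/stats_<kind>.tsv  tables/correction.tsv
    tables/cluster_shift_<kind>.tsv
    figures/...

Each stage validates that its upstream stage has run and fails with the name
of the missing file otherwise, so partial runs are resumable per stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import RegionAtlas, build_edge_index, edge_cluster_pairs
from .functional import PartialCorrelationConnectivity, PearsonConnectivity
from .io import (
    load_voxel_grid,
    read_subjects_tsv,
    read_timeseries_tsv,
    save_voxel_grid,
    write_manifest,
    write_subjects_tsv,
    write_timeseries_tsv,
)
from .network import ConnectivityNetwork
from .simulate import (
    ConfigError,
    SimulationConfig,
    simulate_structural_scene,
    simulate_timeseries_cohort,
)
from .stats import (
    CohortStack,
    CorrectionSpec,
    EdgeStatsResult,
    adjusted_threshold,
    cluster_shift_tests,
    edge_regression,
    effective_number_of_tests,
    group_mean_networks,
    handle_missing,
)
from .structural import min_cost_path_network
from .viz import (
    bimodal_plot_data,
    connectogram_data,
    draw_bimodal,
    draw_connectogram,
    draw_worm_plot,
    save_figure,
    worm_plot_data,
)

__all__ = ["RunConfig", "PipelineError", "Workspace", "run_all"]

FUNCTIONAL_KINDS = ("fMT", "fPC")
STRUCTURAL_KINDS = ("DMC", "DFA")
FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage's inputs are missing or a config is invalid."""


@dataclass
class RunConfig:
    """Options of a full pipeline run (simulation plus analysis)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    kinds: tuple = ("DMC", "DFA", "fMT", "fPC")
    covariates: tuple = ()
    alpha: float = 0.05
    missing_policy: str = "exclude"
    shrinkage: float = 0.0
    path_length: str = "endpoint"
    bins_1d: int = 100
    bins_2d: int = 64

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            unknown = set(self.simulation) - set(
                SimulationConfig.__dataclass_fields__
            )
            if unknown:
                raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
            self.simulation = SimulationConfig(**self.simulation)
        self.kinds = tuple(self.kinds)
        self.covariates = tuple(self.covariates)
        bad = set(self.kinds) - set(FUNCTIONAL_KINDS) - set(STRUCTURAL_KINDS)
        if bad:
            raise ConfigError(f"unknown network kinds: {sorted(bad)}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.missing_policy not in ("exclude", "impute_group_mean"):
            raise ConfigError(f"unknown missing policy {self.missing_policy!r}")
        cov_names = {c.name for c in self.simulation.covariates}
        unknown_cov = set(self.covariates) - cov_names
        if unknown_cov:
            raise ConfigError(
                f"covariates not defined by the simulation: {sorted(unknown_cov)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["voxel_size"] = list(d["simulation"]["voxel_size"])
        return d


class Workspace:
    """Path conventions and stage implementations for one output directory."""

    def __init__(self, root) -> None:
        self.root = Path(root)

    # ---- paths -----------------------------------------------------------

    @property
    def atlas_path(self) -> Path:
        return self.root / "atlas.tsv"

    @property
    def subjects_path(self) -> Path:
        return self.root / "subjects.tsv"

    def network_dir(self, kind: str) -> Path:
        return self.root / "networks" / kind

    def stats_path(self, kind: str) -> Path:
        return self.root / "tables" / f"stats_{kind}.tsv"

    @property
    def correction_path(self) -> Path:
        return self.root / "tables" / "correction.tsv"

    def shift_path(self, kind: str) -> Path:
        return self.root / "tables" / f"cluster_shift_{kind}.tsv"

    def _require(self, path: Path, stage: str) -> Path:
        if not path.exists():
            raise PipelineError(
                f"missing {path}: run the '{stage}' stage first"
            )
        return path

    def load_atlas(self) -> RegionAtlas:
        return RegionAtlas.from_tsv(self._require(self.atlas_path, "simulate"))

    def load_subjects(self) -> pd.DataFrame:
        return read_subjects_tsv(self._require(self.subjects_path, "simulate"))

    # ---- stages ----------------------------------------------------------

    def simulate(self, cfg: RunConfig) -> None:
        """Generate the synthetic cohort inputs (time series and images)."""
        sim = cfg.simulation
        self.root.mkdir(parents=True, exist_ok=True)
        series, subjects, truth = simulate_timeseries_cohort(sim)
        truth["atlas"].to_tsv(self.atlas_path)
        write_subjects_tsv(self.subjects_path, subjects)
        ts_dir = self.root / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for df in series:
            write_timeseries_tsv(ts_dir / f"{df.attrs['subject_id']}.tsv", df)
        if set(cfg.kinds) & set(STRUCTURAL_KINDS):
            grids, _, _ = simulate_structural_scene(sim)
            img_dir = self.root / "images"
            img_dir.mkdir(exist_ok=True)
            for grid, sid in zip(grids, subjects["subject_id"]):
                save_voxel_grid(grid, img_dir / sid)
        write_manifest(
            self.root / "manifest_simulate.json", cfg.to_dict(), sim.seed,
            "simulate",
        )

    def _write_networks(self, kind, nets, atlas) -> None:
        d = self.network_dir(kind)
        d.mkdir(parents=True, exist_ok=True)
        for net in nets:
            net.to_long_tsv(d / f"{net.subject_id}.tsv", atlas)

    def build_functional(self, cfg: RunConfig) -> None:
        """fMT and fPC networks from the per-subject time series."""
        atlas = self.load_atlas()
        subjects = self.load_subjects()
        estimators = {
            "fMT": PearsonConnectivity(),
            "fPC": PartialCorrelationConnectivity(shrinkage=cfg.shrinkage),
        }
        wanted = [k for k in cfg.kinds if k in FUNCTIONAL_KINDS]
        nets: dict[str, list] = {k: [] for k in wanted}
        for sid in subjects["subject_id"]:
            path = self._require(
                self.root / "timeseries" / f"{sid}.tsv", "simulate"
            )
            ts = read_timeseries_tsv(path, atlas)
            for k in wanted:
                nets[k].append(estimators[k].network(ts, subject_id=sid))
        for k in wanted:
            self._write_networks(k, nets[k], atlas)
        write_manifest(
            self.root / "manifest_build_functional.json",
            cfg.to_dict(),
            cfg.simulation.seed,
            "build-functional",
        )

    def build_structural(self, cfg: RunConfig) -> None:
        """DMC and DFA networks from the per-subject voxel images."""
        atlas = self.load_atlas()
        subjects = self.load_subjects()
        wanted = [k for k in cfg.kinds if k in STRUCTURAL_KINDS]
        if not wanted:
            return
        nets: dict[str, list] = {k: [] for k in wanted}
        for sid in subjects["subject_id"]:
            prefix = self.root / "images" / sid
            self._require(Path(f"{prefix}_labels.nii.gz"), "simulate")
            grid = load_voxel_grid(prefix)
            dmc, dfa, _ = min_cost_path_network(
                grid, atlas, path_length=cfg.path_length, keep_paths=False
            )
            for k, net in (("DMC", dmc), ("DFA", dfa)):
                if k in nets:
                    net.subject_id = sid
                    nets[k].append(net)
        for k in wanted:
            self._write_networks(k, nets[k], atlas)
        write_manifest(
            self.root / "manifest_build_structural.json",
            cfg.to_dict(),
            cfg.simulation.seed,
            "build-structural",
        )

    def load_stack(self, kind: str) -> CohortStack:
        atlas = self.load_atlas()
        subjects = self.load_subjects()
        nets = []
        for sid in subjects["subject_id"]:
            stage = (
                "build-functional" if kind in FUNCTIONAL_KINDS else "build-structural"
            )
            path = self._require(self.network_dir(kind) / f"{sid}.tsv", stage)
            nets.append(
                ConnectivityNetwork.from_long_tsv(path, kind, atlas, subject_id=sid)
            )
        stack = CohortStack.from_networks(nets, subjects)
        stack.atlas = atlas
        return stack

    def stats(self, cfg: RunConfig) -> None:
        """Per-edge OLS, M_eff correction and cluster shift tests, per kind."""
        atlas = self.load_atlas()
        (self.root / "tables").mkdir(exist_ok=True)
        idx = build_edge_index(atlas)
        clusters = edge_cluster_pairs(atlas, idx)
        correction_rows = []
        for kind in cfg.kinds:
            stack = handle_missing(self.load_stack(kind), cfg.missing_policy)
            res = edge_regression(stack, cfg.covariates)
            m_eff = effective_number_of_tests(stack)
            corr = adjusted_threshold(cfg.alpha, m_eff, m_g=idx.n_edges)
            correction_rows.append(corr.to_frame(kind))
            res.to_frame(atlas).to_csv(
                self.stats_path(kind), sep="\t", index=False,
                float_format=FLOAT_FMT,
            )
            cluster_shift_tests(res.t, clusters).to_csv(
                self.shift_path(kind), sep="\t", index=False,
                float_format=FLOAT_FMT,
            )
        pd.concat(correction_rows, ignore_index=True).to_csv(
            self.correction_path, sep="\t", index=False, float_format=FLOAT_FMT
        )
        write_manifest(
            self.root / "manifest_stats.json", cfg.to_dict(),
            cfg.simulation.seed, "stats",
        )

    # ---- loading stats back for the figures ------------------------------

    def load_stats(self, kind: str) -> tuple[EdgeStatsResult, np.ndarray]:
        atlas = self.load_atlas()
        idx = build_edge_index(atlas)
        df = pd.read_csv(self._require(self.stats_path(kind), "stats"), sep="\t")
        res = EdgeStatsResult(
            kind=kind,
            beta=df["beta"].to_numpy(float),
            t=df["t"].to_numpy(float),
            p=df["p"].to_numpy(float),
            group_means=np.vstack(
                [df["group0_mean"].to_numpy(float), df["group1_mean"].to_numpy(float)]
            ),
            n_used=df["n_used"].to_numpy(int),
            df=np.full(len(df), np.nan),
            edge_index=idx,
        )
        return res, df["cluster_pair"].to_numpy(object)

    def load_correction(self, kind: str) -> CorrectionSpec:
        df = pd.read_csv(
            self._require(self.correction_path, "stats"), sep="\t"
        )
        row = df[df["kind"] == kind]
        if row.empty:
            raise PipelineError(
                f"no correction record for kind {kind!r} in {self.correction_path}"
            )
        row = row.iloc[0]
        return CorrectionSpec(
            alpha=float(row["alpha"]),
            m_g=int(row["M_G"]),
            m_eff=float(row["M_eff"]),
            alpha_adj=float(row["alpha_adj"]),
            s=float(row["s"]),
        )

    def plot_worm(self, cfg: RunConfig) -> None:
        fig_dir = self.root / "figures"
        fig_dir.mkdir(exist_ok=True)
        import matplotlib.pyplot as plt

        for kind in cfg.kinds:
            res, clusters = self.load_stats(kind)
            corr = self.load_correction(kind)
            data = worm_plot_data(res, corr, clusters)
            ax = draw_worm_plot(data)
            save_figure(ax.figure, fig_dir / f"worm_{kind}", data)
            plt.close(ax.figure)

    def plot_bimodal(self, cfg: RunConfig) -> None:
        fig_dir = self.root / "figures"
        fig_dir.mkdir(exist_ok=True)
        import matplotlib.pyplot as plt

        means = {}
        tstats = {}
        for kind in cfg.kinds:
            stack = handle_missing(self.load_stack(kind), cfg.missing_policy)
            means[kind] = group_mean_networks(stack)
            tstats[kind], _ = self.load_stats(kind)
        s_kinds = tuple(k for k in STRUCTURAL_KINDS if k in cfg.kinds)
        f_kinds = tuple(k for k in FUNCTIONAL_KINDS if k in cfg.kinds)
        for mode, payload in (("group_means", means), ("t_stats", tstats)):
            grid = bimodal_plot_data(
                payload,
                structural_kinds=s_kinds,
                functional_kinds=f_kinds,
                mode=mode,
                bins_1d=cfg.bins_1d,
                bins_2d=cfg.bins_2d,
            )
            fig = draw_bimodal(grid)
            save_figure(fig, fig_dir / f"bimodal_{mode}", grid)
            plt.close(fig)

    def plot_connectogram(self, cfg: RunConfig) -> None:
        fig_dir = self.root / "figures"
        fig_dir.mkdir(exist_ok=True)
        import matplotlib.pyplot as plt

        atlas = self.load_atlas()
        for kind in cfg.kinds:
            res, _ = self.load_stats(kind)
            corr = self.load_correction(kind)
            data = connectogram_data(res, corr, atlas)
            ax = draw_connectogram(data)
            save_figure(ax.figure, fig_dir / f"connectogram_{kind}", data)
            plt.close(ax.figure)


def run_all(cfg: RunConfig, outdir) -> Workspace:
    """The full pipeline: simulate, build networks, stats, all figures."""
    ws = Workspace(outdir)
    ws.simulate(cfg)
    if set(cfg.kinds) & set(FUNCTIONAL_KINDS):
        ws.build_functional(cfg)
    if set(cfg.kinds) & set(STRUCTURAL_KINDS):
        ws.build_structural(cfg)
    ws.stats(cfg)
    ws.plot_worm(cfg)
    ws.plot_bimodal(cfg)
    ws.plot_connectogram(cfg)
    return ws
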