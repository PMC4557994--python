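"""Synthetic two-group cohorts with known ground truth.

Three generators cover the pipeline's inputs at three levels:

* :func:`simulate_edge_cohort` draws edge weights directly
  (w = mu + beta*group + gamma.covariates + latent + noise) — the fast route
  for calibration, power and M_eff experiments;
* :func:`simulate_timeseries_cohort` draws per-subject region time series
  from a block-correlated multivariate normal, with group effects injected
  on the Fisher-z scale of the target correlations so the target matrices
  stay valid;
* :func:`simulate_structural_scene` builds small 3D label/FA images with
  high-FA ridges connecting designated region pairs, the group-1 ridge FA
  scaled by a configured factor.

Everything is driven by one :class:`SimulationConfig`; a given seed fully
determines every output. Defaults are desk-scale: 5 lobe clusters of 6
regions (r = 30, M = 435 edges), 30 subjects per group, 200 timepoints and
structural grids of a few thousand voxels — large enough for the statistics
to behave, small enough for minutes-scale test runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .atlas import RegionAtlas, build_edge_index, cluster_pair_label, edge_cluster_pairs
from .stats import CohortStack
from .structural import VoxelGrid, cost_from_fa

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "make_atlas",
    "simulate_edge_cohort",
    "simulate_timeseries_cohort",
    "simulate_structural_scene",
]

LOBE_LABELS = ("Sub", "Occ", "Par", "Temp", "Fro", "Cb")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class CovariateSpec:
    """One covariate: normal or binary, optionally confounded with group."""

    name: str
    kind: str = "normal"  # "normal" | "binary"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5  # binary success probability
    group_shift: float = 0.0  # added to mean (or to p) in group 1
    edge_effect: float = 0.0  # gamma: per-unit effect on every edge weight


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; the seed fixes every draw."""

    seed: int = 0
    n_clusters: int = 5
    regions_per_cluster: int = 6
    n0: int = 30
    n1: int = 30
    # functional time series
    T: int = 200
    rho_within: float = 0.6
    rho_between: float = 0.1
    # group effect
    effect_cluster_pair: str | None = None
    effect_edges: list | None = None  # explicit (i, j) region-position pairs
    effect_size: float = 0.0  # Fisher-z shift (time series) or
    #                           standardized mean shift (edge cohort)
    # direct edge cohort
    edge_kind: str = "DMC"
    edge_mu: float = 0.0
    edge_noise_sd: float = 1.0
    latent_loading: float = 0.0  # shared-factor loading -> correlated edges
    covariates: list = field(default_factory=list)
    # structural scene
    block_size: int = 2
    block_gap: int = 1
    slab_thickness: int = 4
    voxel_size: tuple = (1.0, 1.0, 1.0)
    fa_background: float = 0.25
    fa_ridge: float = 0.8
    ridge_radius: float = 1.2
    ridge_pairs: list | None = None  # region-position pairs; default: chain
    fa_scale_group1: float = 1.0
    fa_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.regions_per_cluster < 1:
            raise ConfigError("need at least one cluster and one region")
        if self.n0 < 2 or self.n1 < 2:
            raise ConfigError("need at least 2 subjects per group")
        if not (-1 < self.rho_between <= self.rho_within < 1):
            raise ConfigError(
                "require -1 < rho_between <= rho_within < 1 for a valid "
                "block covariance"
            )
        self.covariates = [
            c if isinstance(c, CovariateSpec) else CovariateSpec(**c)
            for c in self.covariates
        ]

    @property
    def r(self) -> int:
        return self.n_clusters * self.regions_per_cluster

    @property
    def n_subjects(self) -> int:
        return self.n0 + self.n1

    # ---- YAML round-trip -------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["voxel_size"] = list(d["voxel_size"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "voxel_size" in d:
            d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)


def make_atlas(cfg: SimulationConfig) -> RegionAtlas:
    """Synthetic atlas: g lobe clusters of k regions, hemispheres alternating."""
    ids, names, hemis, clusters = [], [], [], []
    for c in range(cfg.n_clusters):
        label = LOBE_LABELS[c % len(LOBE_LABELS)]
        for m in range(cfg.regions_per_cluster):
            hemi = "L" if m % 2 == 0 else "R"
            ids.append(f"{label}{m + 1}{hemi}")
            names.append(f"{label} region {m + 1} ({hemi})")
            hemis.append(hemi)
            clusters.append(label)
    return RegionAtlas(tuple(ids), tuple(names), tuple(hemis), tuple(clusters))


def _subject_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    group = np.r_[np.zeros(cfg.n0, dtype=int), np.ones(cfg.n1, dtype=int)]
    d = {
        "subject_id": [f"sub-{i:03d}" for i in range(cfg.n_subjects)],
        "group": group,
    }
    for cov in cfg.covariates:
        if cov.kind == "normal":
            vals = rng.normal(cov.mean, cov.sd, cfg.n_subjects)
            vals = vals + cov.group_shift * group
        elif cov.kind == "binary":
            pvec = np.clip(cov.p + cov.group_shift * group, 0.0, 1.0)
            vals = (rng.random(cfg.n_subjects) < pvec).astype(float)
        else:
            raise ConfigError(f"unknown covariate kind {cov.kind!r}")
        d[cov.name] = vals
    return pd.DataFrame(d)


def _resolve_effect_edges(cfg: SimulationConfig, atlas: RegionAtlas) -> np.ndarray:
    """Edge indices carrying the group effect."""
    idx = build_edge_index(atlas)
    if cfg.effect_cluster_pair is not None:
        labels = edge_cluster_pairs(atlas, idx)
        want = cluster_pair_label(*cfg.effect_cluster_pair.split("/"))
        edges = np.flatnonzero(labels == want)
        if edges.size == 0:
            raise ConfigError(
                f"no edges in cluster pair {cfg.effect_cluster_pair!r}"
            )
        return edges
    if cfg.effect_edges:
        return np.array(
            [idx.index_of(int(i), int(j)) for i, j in cfg.effect_edges],
            dtype=np.intp,
        )
    return np.array([], dtype=np.intp)


# --------------------------------------------------------------------------
# direct edge cohort
# --------------------------------------------------------------------------


def simulate_edge_cohort(cfg: SimulationConfig):
    """Draw a cohort of edge weights directly (no time series or images).

    Returns
    -------
    (stack, truth) : :class:`~conndiff.stats.CohortStack` and a dict with
        ``effect_edges`` (indices), ``beta`` (per-edge true group effect) and
        ``atlas``.
    """
    rng = np.random.default_rng(cfg.seed)
    atlas = make_atlas(cfg)
    idx = build_edge_index(atlas)
    subjects = _subject_table(cfg, rng)
    group = subjects["group"].to_numpy(dtype=float)

    M, n = idx.n_edges, cfg.n_subjects
    beta = np.zeros(M)
    effect_edges = _resolve_effect_edges(cfg, atlas)
    beta[effect_edges] = cfg.effect_size * cfg.edge_noise_sd

    X = cfg.edge_mu + rng.normal(0.0, cfg.edge_noise_sd, size=(M, n))
    X += beta[:, None] * group[None, :]
    if cfg.latent_loading:
        factor = rng.normal(0.0, 1.0, size=n)
        X += cfg.latent_loading * factor[None, :]
    for cov in cfg.covariates:
        if cov.edge_effect:
            X += cov.edge_effect * subjects[cov.name].to_numpy(dtype=float)[None, :]

    stack = CohortStack(cfg.edge_kind, X, subjects, idx, atlas=atlas)
    truth = {"effect_edges": effect_edges, "beta": beta, "atlas": atlas}
    return stack, truth


# --------------------------------------------------------------------------
# functional time series
# --------------------------------------------------------------------------


def _block_correlation(cfg: SimulationConfig, atlas: RegionAtlas) -> np.ndarray:
    r = atlas.r
    clusters = np.asarray(atlas.clusters, dtype=object)
    same = clusters[:, None] == clusters[None, :]
    C = np.where(same, cfg.rho_within, cfg.rho_between).astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def _shift_fisher_z(C: np.ndarray, pairs: np.ndarray, delta: float) -> np.ndarray:
    out = C.copy()
    z = np.arctanh(np.clip(out[pairs[:, 0], pairs[:, 1]], -0.999999, 0.999999))
    shifted = np.tanh(z + delta)
    out[pairs[:, 0], pairs[:, 1]] = shifted
    out[pairs[:, 1], pairs[:, 0]] = shifted
    return out


def _check_pd(C: np.ndarray, what: str) -> np.ndarray:
    lam_min = float(np.linalg.eigvalsh(C).min())
    if lam_min <= 1e-8:
        raise ConfigError(
            f"{what} target correlation is not positive definite "
            f"(min eigenvalue {lam_min:.3g}); reduce rho or the effect size"
        )
    return C


def simulate_timeseries_cohort(cfg: SimulationConfig):
    """Per-subject (T, r) region time series with block correlation.

    Group 0 subjects follow the base block-correlation matrix
    (``rho_within`` inside clusters, ``rho_between`` across); group 1's
    correlations on the effect edges are shifted by ``effect_size`` on the
    Fisher-z scale.

    Returns
    -------
    (series, subjects, truth) : list of DataFrames (columns = region ids,
        ``attrs['subject_id']`` set), the subject table, and a dict with
        ``atlas``, ``effect_edges`` and both target correlation matrices.
    """
    rng = np.random.default_rng(cfg.seed)
    atlas = make_atlas(cfg)
    idx = build_edge_index(atlas)
    subjects = _subject_table(cfg, rng)
    if cfg.T < atlas.r + 2:
        raise ConfigError(
            f"T={cfg.T} too short for r={atlas.r} regions (partial "
            "correlation needs T - 1 >= r)"
        )

    C0 = _check_pd(_block_correlation(cfg, atlas), "group-0")
    effect_edges = _resolve_effect_edges(cfg, atlas)
    if effect_edges.size and cfg.effect_size:
        pairs = idx.pairs[effect_edges]
        C1 = _check_pd(
            _shift_fisher_z(C0, pairs, cfg.effect_size), "group-1"
        )
    else:
        C1 = C0
    L0 = np.linalg.cholesky(C0)
    L1 = np.linalg.cholesky(C1)

    series = []
    for sid, g in zip(subjects["subject_id"], subjects["group"]):
        L = L1 if g == 1 else L0
        ts = rng.standard_normal((cfg.T, atlas.r)) @ L.T
        df = pd.DataFrame(ts, columns=list(atlas.region_ids))
        df.attrs["subject_id"] = sid
        series.append(df)
    truth = {
        "atlas": atlas,
        "effect_edges": effect_edges,
        "target_corr_group0": C0,
        "target_corr_group1": C1,
    }
    return series, subjects, truth


# --------------------------------------------------------------------------
# structural scene
# --------------------------------------------------------------------------


def _region_layout(cfg: SimulationConfig):
    """Region blocks on a 3D grid: clusters along y, members along x."""
    b, gap = cfg.block_size, cfg.block_gap
    pitch = b + gap
    nx = cfg.regions_per_cluster * pitch + gap
    ny = cfg.n_clusters * pitch + gap
    nz = cfg.slab_thickness
    shape = (nx, ny, nz)
    z0 = max((nz - b) // 2, 0)
    origins = {}
    for c in range(cfg.n_clusters):
        for m in range(cfg.regions_per_cluster):
            pos = c * cfg.regions_per_cluster + m
            origins[pos] = (gap + m * pitch, gap + c * pitch, z0)
    return shape, origins


def _default_ridges(cfg: SimulationConfig, atlas: RegionAtlas) -> list:
    """A chain of ridges linking consecutive regions (spans all clusters)."""
    return [(i, i + 1) for i in range(atlas.r - 1)]


def simulate_structural_scene(cfg: SimulationConfig):
    """Per-subject voxel grids: region blocks, FA ridges, group-1 FA scaling.

    Region blocks must not overlap (guaranteed by the layout); the FA field
    is ``fa_background`` plus smoothed noise, with ``fa_ridge`` painted on
    tubes of radius ``ridge_radius`` connecting ridge-pair region centres.
    Group-1 subjects' ridge FA is multiplied by ``fa_scale_group1`` — under
    the default cost 1 - FA, lowering ridge FA raises that pair's path cost
    (DMC) and lowers its DFA.

    Returns
    -------
    (grids, subjects, truth) : list of :class:`VoxelGrid`, subject table and
        a dict with ``atlas``, ``ridge_pairs``, ``centers`` and the noiseless
        per-group FA fields.
    """
    rng = np.random.default_rng(cfg.seed)
    atlas = make_atlas(cfg)
    subjects = _subject_table(cfg, rng)
    shape, origins = _region_layout(cfg)
    b = cfg.block_size

    labels = np.zeros(shape, dtype=np.int32)
    centers = {}
    for pos, (x0, y0, z0) in origins.items():
        sl = (slice(x0, x0 + b), slice(y0, y0 + b), slice(z0, z0 + b))
        if labels[sl].any():
            raise ConfigError(f"region {pos} overlaps an earlier region")
        labels[sl] = pos + 1
        centers[pos] = np.array([x0, y0, z0]) + (b - 1) / 2.0

    ridge_pairs = (
        [(int(i), int(j)) for i, j in cfg.ridge_pairs]
        if cfg.ridge_pairs
        else _default_ridges(cfg, atlas)
    )
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)

    ridge_mask = np.zeros(shape, dtype=bool)
    for i, j in ridge_pairs:
        a, c = centers[i], centers[j]
        d = c - a
        L2 = float(d @ d)
        tpar = np.clip(((coords - a) @ d) / L2, 0.0, 1.0) if L2 > 0 else 0.0
        closest = a + tpar[..., None] * d
        dist = np.linalg.norm(coords - closest, axis=-1)
        ridge_mask |= dist <= cfg.ridge_radius

    base = np.full(shape, cfg.fa_background)
    fa_group = {}
    for g in (0, 1):
        ridge_value = cfg.fa_ridge * (cfg.fa_scale_group1 if g == 1 else 1.0)
        fa_group[g] = np.where(ridge_mask, ridge_value, base)

    grids = []
    for g in subjects["group"]:
        noise = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=1.0
        )
        fa = np.clip(fa_group[int(g)] + cfg.fa_noise_sd * noise, 0.0, 0.999)
        grids.append(
            VoxelGrid(
                labels=labels.copy(),
                fa=fa,
                cost=cost_from_fa(fa),
                voxel_size=cfg.voxel_size,
            )
        )
    truth = {
        "atlas": atlas,
        "ridge_pairs": ridge_pairs,
        "centers": centers,
        "fa_noiseless_group0": fa_group[0],
        "fa_noiseless_group1": fa_group[1],
    }
    return grids, subjects, truth
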