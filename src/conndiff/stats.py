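"""Per-edge group statistics with an effective-number-of-tests correction.

The analysis unit is a :class:`CohortStack`: every subject's network of one
kind reduced to its edge vector, stacked into an edges-by-subjects matrix,
next to a subject table with a binary group column and covariates.

For each edge an ordinary least squares model

    weight ~ 1 + group + covariates

is fitted; the group coefficient's t statistic and two-sided p-value measure
the group difference at that edge (group coded 0/1, so positive t means
group 1 > group 0). Because the M = r(r-1)/2 edge tests are strongly
dependent, the Bonferroni denominator is replaced by an *effective number of
independent tests* M_eff — the Li & Ji eigenvalue rule applied to the
between-edge correlation matrix — giving the adjusted threshold
alpha_adj = alpha / M_eff and the worm-plot scale
s = log10(alpha) / log10(alpha_adj).

Coordinated sub-threshold shifts of whole lobe pairs are picked up by
one-sample t-tests of each cluster's edge t-statistics against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .atlas import EdgeIndex, RegionAtlas, build_edge_index, edge_cluster_pairs
from .network import ConnectivityNetwork

__all__ = [
    "CohortStack",
    "EdgeStatsResult",
    "CorrectionSpec",
    "MassUnivariateGroupRegression",
    "edge_regression",
    "group_mean_networks",
    "effective_number_of_tests",
    "li_ji_meff",
    "adjusted_threshold",
    "cluster_shift_tests",
    "handle_missing",
    "welch_from_summary",
    "chi2_2x2",
]


class StackError(ValueError):
    """Malformed cohort stack."""


@dataclass
class CohortStack:
    """Edge-by-subject weight matrix for one network kind, plus subjects.

    Parameters
    ----------
    kind : str
        Network kind tag (DMC/DFA/fMT/fPC).
    X : (M, n) float array
        Edge weights; NaN marks a missing edge for that subject.
    subjects : DataFrame
        One row per subject, columns ``subject_id``, ``group`` (0/1) and any
        covariates; row order matches the columns of ``X``.
    edge_index : EdgeIndex
    atlas : RegionAtlas, optional
    """

    kind: str
    X: np.ndarray
    subjects: pd.DataFrame
    edge_index: EdgeIndex
    atlas: RegionAtlas | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise StackError("X must be 2-D (edges x subjects)")
        if self.X.shape[1] != len(self.subjects):
            raise StackError(
                f"X has {self.X.shape[1]} subject columns but the subject "
                f"table has {len(self.subjects)} rows"
            )
        if self.X.shape[0] != self.edge_index.n_edges:
            raise StackError(
                f"X has {self.X.shape[0]} edges but edge index expects "
                f"{self.edge_index.n_edges}"
            )
        if "group" not in self.subjects.columns:
            raise StackError("subject table needs a 'group' column")
        g = np.asarray(self.subjects["group"])
        if not np.isin(g, (0, 1)).all():
            raise StackError("group must be coded 0/1")
        if len(self.subjects) < 4 or len(set(g)) < 2:
            raise StackError("need n >= 4 subjects and both groups non-empty")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[1]

    @property
    def n_edges(self) -> int:
        return self.X.shape[0]

    @property
    def group(self) -> np.ndarray:
        return np.asarray(self.subjects["group"], dtype=float)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.X)

    @classmethod
    def from_networks(
        cls,
        networks: list[ConnectivityNetwork],
        subjects: pd.DataFrame,
    ) -> "CohortStack":
        if not networks:
            raise StackError("no networks supplied")
        kinds = {n.kind for n in networks}
        if len(kinds) != 1:
            raise StackError(f"mixed network kinds: {sorted(kinds)}")
        rs = {n.r for n in networks}
        if len(rs) != 1:
            raise StackError("networks differ in region count")
        idx = build_edge_index(networks[0].r)
        X = np.column_stack([n.edge_vector() for n in networks])
        return cls(kinds.pop(), X, subjects.reset_index(drop=True), idx)


@dataclass
class EdgeStatsResult:
    """Per-edge regression outputs for one network kind."""

    kind: str
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    group_means: np.ndarray  # (2, M): row 0 = group 0, row 1 = group 1
    n_used: np.ndarray
    df: np.ndarray
    covariate_names: tuple[str, ...] = ()
    edge_index: EdgeIndex | None = field(default=None, repr=False)

    def to_frame(self, atlas: RegionAtlas | None = None) -> pd.DataFrame:
        d: dict = {}
        if atlas is not None and self.edge_index is not None:
            pairs = self.edge_index.pairs
            ids = np.asarray(atlas.region_ids, dtype=object)
            d["region_a"] = ids[pairs[:, 0]]
            d["region_b"] = ids[pairs[:, 1]]
            d["cluster_pair"] = edge_cluster_pairs(atlas, self.edge_index)
        d.update(
            beta=self.beta,
            t=self.t,
            p=self.p,
            group0_mean=self.group_means[0],
            group1_mean=self.group_means[1],
            n_used=self.n_used,
        )
        return pd.DataFrame(d)


@dataclass(frozen=True)
class CorrectionSpec:
    """Effective-number-of-tests Bonferroni record for one network.

    alpha_adj = alpha / m_eff;  s = log10(alpha) / log10(alpha_adj), the
    worm-plot scale that pins the adjusted threshold at -log10(alpha) for
    every network kind.
    """

    alpha: float
    m_g: int
    m_eff: float
    alpha_adj: float
    s: float

    def to_frame(self, kind: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": kind,
                    "alpha": self.alpha,
                    "M_G": self.m_g,
                    "M_eff": self.m_eff,
                    "alpha_adj": self.alpha_adj,
                    "s": self.s,
                }
            ]
        )


def _design_matrix(
    subjects: pd.DataFrame, covariate_names
) -> tuple[np.ndarray, int]:
    """Intercept + group + covariates; returns (A, group_column_index=1)."""
    cols = [np.ones(len(subjects)), np.asarray(subjects["group"], dtype=float)]
    for name in covariate_names:
        if name not in subjects.columns:
            raise StackError(f"unknown covariate {name!r}")
        cols.append(np.asarray(subjects[name], dtype=float))
    return np.column_stack(cols), 1


class MassUnivariateGroupRegression(BaseEstimator):
    """Per-edge OLS of edge weight on group membership plus covariates.

    sklearn-style estimator: ``fit(X, y)`` with X of shape
    (n_subjects, n_edges) (NaN = missing) and y the 0/1 group labels;
    covariates go in via the ``covariates`` keyword of :meth:`fit`.

    Fitted attributes (one entry per edge): ``beta_``, ``t_``, ``p_``,
    ``df_``, ``n_used_``, ``group_means_`` (shape (2, n_edges)).
    """

    def __init__(self, min_df: int = 1) -> None:
        self.min_df = min_df

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise StackError("X must be (n_subjects, n_edges)")
        y = np.asarray(y, dtype=float)
        n, M = X.shape
        if y.shape != (n,):
            raise StackError("y length must match X rows")
        C = (
            np.empty((n, 0))
            if covariates is None
            else np.atleast_2d(np.asarray(covariates, dtype=float).reshape(n, -1))
        )
        A = np.column_stack([np.ones(n), y, C])
        k = A.shape[1]

        beta = np.full(M, np.nan)
        t = np.full(M, np.nan)
        p = np.full(M, np.nan)
        df_out = np.full(M, np.nan)
        n_used = np.zeros(M, dtype=int)
        gmeans = np.full((2, M), np.nan)

        miss = np.isnan(X)
        # group means ignore the design; per group over non-missing values
        for gi in (0, 1):
            sel = y == gi
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                gmeans[gi] = np.nanmean(X[sel], axis=0)

        # fit edges sharing a missingness pattern together
        patterns: dict[bytes, list[int]] = {}
        for e in range(M):
            patterns.setdefault(miss[:, e].tobytes(), []).append(e)
        n_rank_deficient = 0
        for key, edges in patterns.items():
            keep = ~np.frombuffer(key, dtype=bool)
            Ak = A[keep]
            nk = int(keep.sum())
            df = nk - k
            n_used[edges] = nk
            if df < self.min_df or len(set(y[keep])) < 2:
                n_rank_deficient += len(edges)
                continue
            if np.linalg.matrix_rank(Ak) < k:
                n_rank_deficient += len(edges)
                continue
            Xe = X[np.ix_(keep, edges)]
            pinv = np.linalg.pinv(Ak)
            coef = pinv @ Xe  # (k, m)
            resid = Xe - Ak @ coef
            rss = np.einsum("ij,ij->j", resid, resid)
            sigma2 = rss / df
            xtx_inv_gg = (pinv @ pinv.T)[1, 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(sigma2 * xtx_inv_gg)
                tt = coef[1] / se
            # zero residual variance -> undefined t/p, leave masked
            # (relative to each edge's total sum of squares)
            ctr = Xe - Xe.mean(axis=0)
            tss = np.einsum("ij,ij->j", ctr, ctr)
            zero_var = rss <= 1e-12 * np.maximum(tss, np.finfo(float).tiny)
            tt = np.where(zero_var & (np.abs(coef[1]) < 1e-12), 0.0, tt)
            tt[zero_var & (np.abs(coef[1]) >= 1e-12)] = np.nan
            pp = 2.0 * sps.t.sf(np.abs(tt), df)
            beta[edges] = coef[1]
            t[edges] = tt
            p[edges] = pp
            df_out[edges] = df
        if n_rank_deficient:
            warnings.warn(
                f"{n_rank_deficient} edge(s) had a rank-deficient or "
                "under-determined design; their statistics are masked",
                RuntimeWarning,
                stacklevel=2,
            )
        self.n_features_in_ = M
        self.beta_ = beta
        self.t_ = t
        self.p_ = p
        self.df_ = df_out
        self.n_used_ = n_used
        self.group_means_ = gmeans
        return self


def edge_regression(stack: CohortStack, covariate_names=()) -> EdgeStatsResult:
    """Per-edge OLS group statistics for a cohort stack."""
    A, _ = _design_matrix(stack.subjects, covariate_names)  # validates names
    est = MassUnivariateGroupRegression().fit(
        stack.X.T, stack.group, covariates=A[:, 2:] if A.shape[1] > 2 else None
    )
    return EdgeStatsResult(
        kind=stack.kind,
        beta=est.beta_,
        t=est.t_,
        p=est.p_,
        group_means=est.group_means_,
        n_used=est.n_used_,
        df=est.df_,
        covariate_names=tuple(covariate_names),
        edge_index=stack.edge_index,
    )


def group_mean_networks(
    stack: CohortStack,
) -> tuple[ConnectivityNetwork, ConnectivityNetwork]:
    """Arithmetic mean network per group over non-missing values."""
    g = stack.group
    out = []
    for gi, kindtag in ((0, "group0"), (1, "group1")):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_vec = np.nanmean(stack.X[:, g == gi], axis=1)
        mat = stack.edge_index.matrix_from_vector(mean_vec)
        out.append(
            ConnectivityNetwork(stack.kind, mat, subject_id=f"mean_{kindtag}")
        )
    return out[0], out[1]


def li_ji_meff(eigenvalues: np.ndarray, snap_tol: float = 1e-9) -> float:
    """Effective number of independent tests from correlation eigenvalues.

    Applies f(lam) = 1[lam >= 1] + (lam - floor(lam)) to each eigenvalue and
    sums. Eigenvalues within ``snap_tol`` of an integer are snapped to it
    first: f has jumps at the integers and the eigensolver's last-digit noise
    must not land an exact multiplicity on the wrong side.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = np.where(lam < 0, 0.0, lam)
    near = np.round(lam)
    lam = np.where(np.abs(lam - near) <= snap_tol, near, lam)
    f = (lam >= 1.0).astype(float) + (lam - np.floor(lam))
    return float(f.sum())


def effective_number_of_tests(stack: CohortStack) -> float:
    """M_eff of a cohort stack via the between-edge correlation spectrum.

    The correlation matrix across edges is computed over pooled subjects
    (both groups). When the number of edges exceeds the number of subjects
    the spectrum is obtained from the n x n Gram matrix of the standardized
    edge rows, so only the <= n-1 structurally non-zero eigenvalues are ever
    materialized; zero eigenvalues contribute nothing to the sum.
    """
    if stack.n_subjects < 3:
        raise StackError("M_eff needs at least 3 subjects")
    X = stack.X
    complete = ~np.isnan(X).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"M_eff computed on the {int(complete.sum())} edges with complete "
            f"data (of {X.shape[0]})",
            RuntimeWarning,
            stacklevel=2,
        )
    Xc = X[complete]
    sd = Xc.std(axis=1)
    if (sd == 0).any():
        raise StackError(
            f"{int((sd == 0).sum())} edge(s) are constant across subjects; "
            "the edge correlation matrix is undefined"
        )
    Z = Xc - Xc.mean(axis=1, keepdims=True)
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    M, n = Z.shape
    if M <= n:
        lam = np.linalg.eigvalsh(Z @ Z.T)
    else:
        lam = np.linalg.eigvalsh(Z.T @ Z)  # Gram form: same non-zero spectrum
    return li_ji_meff(lam)


def adjusted_threshold(alpha: float, m_eff: float, m_g: int = 0) -> CorrectionSpec:
    """Bonferroni threshold with M_eff in place of the raw test count."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m_eff < 1:
        raise ValueError(f"M_eff must be >= 1, got {m_eff}")
    alpha_adj = alpha / m_eff
    s = np.log10(alpha) / np.log10(alpha_adj)
    return CorrectionSpec(
        alpha=float(alpha),
        m_g=int(m_g),
        m_eff=float(m_eff),
        alpha_adj=float(alpha_adj),
        s=float(s),
    )


def cluster_shift_tests(
    edge_t: np.ndarray, cluster_pairs: np.ndarray
) -> pd.DataFrame:
    """One-sample two-sided t-test of each lobe pair's edge t-values vs 0.

    Detects coordinated sub-threshold group differences: a whole worm shifted
    away from zero. Clusters with fewer than two finite t-values or zero
    variance come back with NaN statistics and a warning.
    """
    edge_t = np.asarray(edge_t, dtype=float)
    cluster_pairs = np.asarray(cluster_pairs, dtype=object)
    if edge_t.shape != cluster_pairs.shape:
        raise ValueError("edge_t and cluster_pairs must align")
    rows = []
    n_masked = 0
    for label in sorted(set(cluster_pairs)):
        tv = edge_t[cluster_pairs == label]
        tv = tv[np.isfinite(tv)]
        mean_t = float(tv.mean()) if tv.size else np.nan
        if tv.size < 2 or np.isclose(tv.std(ddof=1), 0.0):
            n_masked += 1
            rows.append(
                dict(
                    cluster_pair=label,
                    n_edges=int(tv.size),
                    mean_t=mean_t,
                    shift_t=np.nan,
                    shift_p=np.nan,
                )
            )
            continue
        res = sps.ttest_1samp(tv, 0.0)
        rows.append(
            dict(
                cluster_pair=label,
                n_edges=int(tv.size),
                mean_t=mean_t,
                shift_t=float(res.statistic),
                shift_p=float(res.pvalue),
            )
        )
    if n_masked:
        warnings.warn(
            f"{n_masked} cluster(s) had <2 usable edges or zero variance; "
            "their shift tests are masked",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def handle_missing(stack: CohortStack, policy: str = "exclude") -> CohortStack:
    """Apply the missing-edge policy.

    ``exclude`` keeps missing entries masked (the regression then does
    per-edge listwise deletion); ``impute_group_mean`` substitutes each
    missing entry with that edge's mean over the subject's group. An edge
    missing for an entire group stays masked under either policy.
    """
    if policy == "exclude":
        return stack
    if policy != "impute_group_mean":
        raise ValueError(f"unknown missing policy {policy!r}")
    X = stack.X.copy()
    g = stack.group
    for gi in (0, 1):
        sel = g == gi
        block = X[:, sel]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(block, axis=1)
        fill = np.isnan(block) & np.isfinite(means)[:, None]
        block[fill] = np.broadcast_to(means[:, None], block.shape)[fill]
        X[:, sel] = block
    return CohortStack(
        stack.kind, X, stack.subjects, stack.edge_index, atlas=stack.atlas
    )


def welch_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's two-sample t-test from printed group summaries.

    Returns (t, Welch-Satterthwaite df, two-sided p). Used for demographic
    comparisons where only mean +/- SD and n are reported.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    v1, v2 = s1**2 / n1, s2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi2_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 count table [[a, b], [c, d]].

    Continuity correction is off by default (switchable); identical rows give
    statistic 0 and p = 1.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("every margin of the 2x2 table must be positive")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
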