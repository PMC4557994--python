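"""Functional connectivity from region mean time series.

Two estimators, shaped like nilearn's connectivity transformers: full Pearson
correlation of each pair of region time series (kind ``fMT``), and partial
correlation with every other region's influence removed (kind ``fPC``).

Partial correlation is read off the precision matrix P (inverse of the sample
covariance of the region columns):

    r_ij = -P_ij / sqrt(P_ii * P_jj)

The sample covariance uses the unbiased (T-1) denominator; optional diagonal
loading (cov + lam*I) guards near-singular cases, which matter when the
number of timepoints is close to the number of regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import RegionAtlas
from .network import ConnectivityNetwork

__all__ = [
    "PearsonConnectivity",
    "PartialCorrelationConnectivity",
    "pearson_network",
    "partial_correlation_network",
    "precision_matrix",
]


class ConditioningError(np.linalg.LinAlgError):
    """Sample covariance is singular and shrinkage is disabled."""


def _as_timeseries(ts) -> tuple[np.ndarray, str]:
    """Coerce one subject's table to (T, r) float array + subject id."""
    sid = ""
    if isinstance(ts, pd.DataFrame):
        sid = str(ts.attrs.get("subject_id", ""))
        ts = ts.to_numpy(dtype=float)
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"time series must be 2-D (T x r), got shape {ts.shape}")
    if ts.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    return ts, sid


def _zero_variance_columns(ts: np.ndarray) -> np.ndarray:
    return np.isclose(ts.std(axis=0), 0.0)


class _FunctionalBase(TransformerMixin, BaseEstimator):
    kind: str

    def fit(self, X, y=None):
        """No fitting required; validates the input and records r."""
        first, _ = _as_timeseries(X[0] if isinstance(X, (list, tuple)) else X)
        self.n_regions_ = first.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Map a list of (T, r) series to an (n, r, r) connectivity stack."""
        if not isinstance(X, (list, tuple)):
            X = [X]
        return np.stack([self._connectivity(_as_timeseries(ts)[0]) for ts in X])

    def network(self, ts, subject_id: str = "") -> ConnectivityNetwork:
        arr, sid = _as_timeseries(ts)
        return ConnectivityNetwork(
            self.kind, self._connectivity(arr), subject_id=subject_id or sid
        )

    def _connectivity(self, ts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class PearsonConnectivity(_FunctionalBase):
    """Pairwise Pearson correlation of region mean time series (fMT)."""

    kind = "fMT"

    def _connectivity(self, ts: np.ndarray) -> np.ndarray:
        if ts.shape[0] < 3:
            raise ValueError("Pearson connectivity needs at least 3 timepoints")
        dead = _zero_variance_columns(ts)
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} zero-variance region(s); their edges are "
                "masked as missing",
                RuntimeWarning,
                stacklevel=2,
            )
            ts = ts.copy()
            ts[:, dead] = np.nan  # propagate to NaN correlations -> mask
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(ts, rowvar=False)
        c = np.clip(c, -1.0, 1.0)
        return c


class PartialCorrelationConnectivity(_FunctionalBase):
    """Partial correlation between region pairs, all other regions removed (fPC).

    Parameters
    ----------
    shrinkage : float, default 0.0
        Diagonal loading added to the sample covariance (cov + shrinkage*I).
        Zero means plain inversion, which requires T - 1 >= r and
        non-degenerate data.
    """

    kind = "fPC"

    def __init__(self, shrinkage: float = 0.0) -> None:
        self.shrinkage = shrinkage

    def _connectivity(self, ts: np.ndarray) -> np.ndarray:
        p = precision_matrix(ts, shrinkage=self.shrinkage)
        d = np.sqrt(np.diag(p))
        pc = -p / np.outer(d, d)
        np.fill_diagonal(pc, 1.0)
        pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)  # symmetrize roundoff
        return pc


def precision_matrix(ts: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Inverse sample covariance of the region columns (unbiased, T-1).

    Raises
    ------
    ConditioningError
        If the (possibly loaded) covariance is numerically singular; the
        message names the covariance rank so the caller can tell whether more
        timepoints or shrinkage is needed.
    """
    ts, _ = _as_timeseries(ts)
    T, r = ts.shape
    cov = np.cov(ts, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if shrinkage:
        cov = cov + shrinkage * np.eye(r)
    rank = np.linalg.matrix_rank(cov)
    if rank < r:
        raise ConditioningError(
            f"sample covariance is singular (rank {rank} < {r} regions; "
            f"T={T}); add timepoints or enable shrinkage"
        )
    try:
        prec = linalg.inv(cov)
    except linalg.LinAlgError as err:  # pragma: no cover - rank check above
        raise ConditioningError(str(err)) from err
    return (prec + prec.T) / 2.0


def pearson_network(ts, subject_id: str = "") -> ConnectivityNetwork:
    """Pearson-correlation (fMT) network for one subject's (T, r) series."""
    return PearsonConnectivity().network(ts, subject_id=subject_id)


def partial_correlation_network(
    ts, subject_id: str = "", shrinkage: float = 0.0
) -> ConnectivityNetwork:
    """Partial-correlation (fPC) network for one subject's (T, r) series."""
    return PartialCorrelationConnectivity(shrinkage=shrinkage).network(
        ts, subject_id=subject_id
    )
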