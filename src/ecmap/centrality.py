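"""Eigenvector centrality mapping (ECM) on shifted correlation adjacencies.

Eigenvector centrality scores each node by the corresponding entry of the
leading eigenvector of a nonnegative adjacency matrix: a node is central when
it is strongly connected to other central nodes. For correlation networks the
adjacency is the Pearson matrix shifted by +1, which maps r in [-1, 1] to
[0, 2] and guarantees (by Perron-Frobenius) a nonnegative leading eigenvector
with a real dominant eigenvalue. Because eigenvectors are invariant to adding
a constant to the diagonal and to global rescaling, the diagonal convention
(here r = 1, i.e. 2) cannot change the result.

Hubs are the ROIs whose group-mean centrality exceeds the 95th percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ROITimeSeries
from .connectivity import PermutationResult, permutation_group_test

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyMatrix:
    """N x N matrix of (Pearson r + 1) values in [0, 2]."""

    a: np.ndarray
    roi_ids: list[int]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = self.a.shape[0]
        if self.a.shape != (n, n) or n != len(self.roi_ids):
            raise ValueError("a must be square and match roi_ids")
        if np.max(np.abs(self.a - self.a.T)) > 1e-9:
            raise ValueError("adjacency must be symmetric")
        if np.any(self.a < -1e-12) or np.any(self.a > 2 + 1e-12):
            raise ValueError("adjacency entries must lie in [0, 2]")


@dataclass
class ECVector:
    """Unit-norm nonnegative leading eigenvector with its eigenvalue."""

    ec: np.ndarray
    eigenvalue: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.ec = np.asarray(self.ec, dtype=float)
        if abs(np.linalg.norm(self.ec) - 1.0) > 1e-10:
            raise ValueError("ec must have unit Euclidean norm")
        if np.any(self.ec < -1e-12):
            raise ValueError("ec entries must be nonnegative")


@dataclass
class HubSet:
    """ROIs whose group-mean centrality reaches the percentile threshold."""

    roi_ids: list[int]
    threshold: float
    percentile: float = 95.0


def adjacency_from_ts(ts: ROITimeSeries, diagonal: float = 2.0) -> AdjacencyMatrix:
    """Pearson correlation matrix + 1, with the diagonal set to ``diagonal``.

    The default diagonal 2 corresponds to r = 1 with itself; the choice is
    immaterial for centrality (diagonal-shift invariance).
    """
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("need T >= 3 for correlation")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        ids = ", ".join(str(ts.roi_ids[i]) for i in dead)
        raise ValueError(f"zero variance: {ids}")
    a = np.corrcoef(x, rowvar=False) + 1.0
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, diagonal)
    return AdjacencyMatrix(a=a, roi_ids=list(ts.roi_ids))


def eigenvector_centrality(
    adj: AdjacencyMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> ECVector:
    """Leading eigenvector by power iteration from the uniform positive vector.

    Iterates v <- A v / ||A v|| until successive iterates differ by < tol in
    max-norm; the eigenvalue is the Rayleigh quotient at the fixed point.
    Non-convergence returns the last iterate flagged ``converged=False``.
    """
    a = adj.a if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("adjacency must be square")
    if np.max(np.abs(a - a.T)) > 1e-9:
        raise ValueError("adjacency must be symmetric")
    v = np.full(n, 1.0 / np.sqrt(n))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break  # zero matrix: keep uniform vector
        w /= norm
        if np.max(np.abs(w - v)) < tol:
            v = w
            converged = True
            break
        v = w
    if not converged:
        logger.warning("power iteration did not converge in %d iterations", max_iter)
    v = np.abs(v)  # nonnegative orientation (Perron vector)
    v /= np.linalg.norm(v)
    eigenvalue = float(v @ a @ v)
    return ECVector(ec=v, eigenvalue=max(eigenvalue, 0.0), n_iter=it, converged=converged)


def ec_from_ts(ts: ROITimeSeries, **kwargs) -> ECVector:
    """Convenience: adjacency from the time series, then its centrality vector."""
    return eigenvector_centrality(adjacency_from_ts(ts), **kwargs)


def group_mean_ec(ec_table: pd.DataFrame) -> pd.Series:
    """Per-ROI mean over participants of per-participant centrality vectors."""
    return ec_table.mean(axis=0)


def identify_hubs(
    group_ec: pd.Series | np.ndarray,
    roi_ids: list[int] | None = None,
    percentile: float = 95.0,
) -> HubSet:
    """ROIs at or above the linear-interpolation percentile of group-mean EC.

    Ties at the threshold are all included, so a degenerate all-equal vector
    yields every ROI as a hub.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    if isinstance(group_ec, pd.Series):
        values = group_ec.to_numpy(float)
        ids = list(group_ec.index)
    else:
        values = np.asarray(group_ec, dtype=float)
        ids = list(roi_ids) if roi_ids is not None else list(range(len(values)))
    if values.size < 2:
        raise ValueError("need at least 2 ROIs")
    if not np.all(np.isfinite(values)):
        raise ValueError("group EC must be finite")
    threshold = float(np.percentile(values, percentile))  # linear interpolation
    members = [i for i, v in zip(ids, values) if v >= threshold]
    return HubSet(roi_ids=members, threshold=threshold, percentile=percentile)


def compare_hub_ec(
    ec_a: pd.DataFrame,
    ec_b: pd.DataFrame,
    hubs: HubSet,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Per-hub group comparison of centrality with max-statistic FWE correction.

    ``ec_a``/``ec_b`` are participants x ROIs tables (columns indexed by ROI
    id); the test family is exactly the hub set, per-hub statistic is the
    difference of group means.
    """
    for rid in hubs.roi_ids:
        if rid not in ec_a.columns or rid not in ec_b.columns:
            raise ValueError(f"unknown hub id: {rid}")
    a = ec_a[hubs.roi_ids].to_numpy(float)
    b = ec_b[hubs.roi_ids].to_numpy(float)
    result = permutation_group_test(
        a, b, statistic="diff_of_means", n_perm=n_perm, seed=seed
    )
    result.labels = list(hubs.roi_ids)
    return result
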