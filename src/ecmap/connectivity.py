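"""Functional connectivity matrices and group-label permutation tests.

Functional connectivity (FC) between two ROIs is the Pearson correlation of
their time series, Fisher z-transformed (z = atanh r) so that values are
approximately variance-stabilized. Group comparisons use label-permutation
tests with family-wise error (FWE) control by the max-statistic method: the
null distribution of the maximum |statistic| across the declared family of
tests bounds every member's corrected p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .atlas import ROITimeSeries

_R_CLIP = 1.0 - 1e-15


@dataclass
class FCMatrix:
    """Symmetric N x N matrix of Fisher-z connectivity values (diagonal NaN)."""

    z: np.ndarray
    roi_ids: list[int]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n) or n != len(self.roi_ids):
            raise ValueError("z must be square and match roi_ids")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.z[off])):
            raise ValueError("off-diagonal z values must be finite")
        if np.max(np.abs(self.z - self.z.T)[off]) > 1e-12:
            raise ValueError("z must be symmetric")


@dataclass
class PermutationResult:
    """Observed statistic(s) with raw and FWE-corrected permutation p-values."""

    observed: np.ndarray
    p_raw: np.ndarray
    p_fwe: np.ndarray
    n_perm: int
    seed: int | None = None
    statistic: str = "diff_of_means"
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observed = np.atleast_1d(np.asarray(self.observed, dtype=float))
        self.p_raw = np.atleast_1d(np.asarray(self.p_raw, dtype=float))
        self.p_fwe = np.atleast_1d(np.asarray(self.p_fwe, dtype=float))
        if np.any(self.p_raw <= 0) or np.any(self.p_raw > 1):
            raise ValueError("p_raw must lie in (0, 1]")
        if np.any(self.p_fwe + 1e-15 < self.p_raw):
            raise ValueError("p_fwe must be >= p_raw")

    @property
    def scalar(self) -> bool:
        return self.observed.size == 1


def fc_matrix(ts: ROITimeSeries) -> FCMatrix:
    """Pairwise Pearson correlation between ROI series, Fisher z-transformed."""
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("need T >= 3 for correlation")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        ids = ", ".join(str(ts.roi_ids[i]) for i in dead)
        raise ValueError(f"zero variance: {ids}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetry
    return FCMatrix(z=z, roi_ids=list(ts.roi_ids), participant_id=ts.participant_id)


def participant_fc_summary(fc: FCMatrix) -> float:
    """Whole-brain FC for one participant: mean of the upper-triangle z values."""
    iu = np.triu_indices_from(fc.z, k=1)
    return float(np.mean(fc.z[iu]))


def _group_stat(x: np.ndarray, axis: int, statistic: str) -> np.ndarray:
    if statistic == "diff_of_means":
        return np.mean(x, axis=axis)
    if statistic == "diff_of_medians":
        return np.median(x, axis=axis)
    raise ValueError(f"unknown statistic: {statistic}")


def permutation_group_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    statistic: str = "diff_of_means",
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
    fwe: str = "max_stat",
    chunk: int = 2_000,
) -> PermutationResult:
    """Two-sided group-label permutation test with max-statistic FWE control.

    Parameters
    ----------
    values_a, values_b : arrays, shape (n_a,) or (n_a, K)
        Per-participant statistic(s) in each group; for 2-D input each of the
        K columns is one member of the test family.
    statistic : {"diff_of_means", "diff_of_medians"}
        observed = statistic(a) - statistic(b).
    exact : bool
        Enumerate all C(n_a+n_b, n_a) group assignments instead of sampling;
        p is then the exact tail probability (identity assignment included).
    fwe : {"max_stat", "bonferroni"}
        Family-wise correction across the K tests.

    The sampled-permutation p-value uses the add-one rule,
    p = (1 + #{|null| >= |obs|}) / (n_perm + 1), so it never equals 0.
    """
    a = np.atleast_1d(np.asarray(values_a, dtype=float))
    b = np.atleast_1d(np.asarray(values_b, dtype=float))
    scalar_family = a.ndim == 1
    a2 = a[:, None] if scalar_family else a
    b2 = b[:, None] if scalar_family else b
    n_a, k = a2.shape
    n_b = b2.shape[0]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    if b2.shape[1] != k:
        raise ValueError("groups must have the same number of tests")
    if fwe not in ("max_stat", "bonferroni"):
        raise ValueError(f"unknown fwe method: {fwe}")

    pooled = np.vstack([a2, b2])
    n = n_a + n_b
    observed = _group_stat(a2, 0, statistic) - _group_stat(b2, 0, statistic)
    abs_obs = np.abs(observed)
    tol = 1e-12  # ties at |obs| count as extreme

    if exact:
        combos = list(itertools.combinations(range(n), n_a))
        count = np.zeros(k)
        count_max = np.zeros(k)
        for idx_a in combos:
            sel = np.zeros(n, dtype=bool)
            sel[list(idx_a)] = True
            null = _group_stat(pooled[sel], 0, statistic) - _group_stat(
                pooled[~sel], 0, statistic
            )
            abs_null = np.abs(null)
            count += abs_null >= abs_obs - tol
            count_max += np.max(abs_null) >= abs_obs - tol
        total = len(combos)
        p_raw = count / total
        p_fwe = count_max / total if fwe == "max_stat" else np.minimum(1.0, p_raw * k)
        p_fwe = np.maximum(p_fwe, p_raw)
        return PermutationResult(
            observed=observed if not scalar_family else observed[:1],
            p_raw=p_raw, p_fwe=p_fwe, n_perm=total, seed=seed, statistic=statistic,
        )

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = np.zeros(k)
    count_max = np.zeros(k)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        ga = pooled[perm[:, :n_a]]  # (m, n_a, K)
        gb = pooled[perm[:, n_a:]]
        null = _group_stat(ga, 1, statistic) - _group_stat(gb, 1, statistic)
        abs_null = np.abs(null)  # (m, K)
        count += np.sum(abs_null >= abs_obs[None, :] - tol, axis=0)
        count_max += np.sum(abs_null.max(axis=1)[:, None] >= abs_obs[None, :] - tol, axis=0)
        done += m
    p_raw = (1.0 + count) / (n_perm + 1.0)
    if fwe == "max_stat":
        p_fwe = (1.0 + count_max) / (n_perm + 1.0)
    else:
        p_fwe = np.minimum(1.0, p_raw * k)
    p_fwe = np.maximum(p_fwe, p_raw)
    return PermutationResult(
        observed=observed, p_raw=p_raw, p_fwe=p_fwe, n_perm=n_perm, seed=seed,
        statistic=statistic,
    )


def whole_brain_fc_test(
    summaries_a: np.ndarray,
    summaries_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic: str = "diff_of_medians",
) -> PermutationResult:
    """Group comparison of per-participant whole-brain FC values.

    The group-level statistic defaults to the difference of group medians.
    """
    return permutation_group_test(
        np.asarray(summaries_a, float),
        np.asarray(summaries_b, float),
        statistic=statistic,
        n_perm=n_perm,
        seed=seed,
    )
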