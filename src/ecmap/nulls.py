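"""Surrogate and bootstrap distributions of eigenvector centrality.

Two complementary resampling constructions frame each centrality estimate:

* **iAAFT surrogates** (iterative amplitude-adjusted Fourier transform)
  randomize each ROI series' Fourier phases while retaining its exact value
  distribution and, approximately, its power spectrum. Applied independently
  per ROI they destroy all cross-ROI correlation, so the centrality of the
  surrogate cohorts is a null for "no functional communication". Note this
  null is not centered at zero: with all correlations near zero the shifted
  adjacency approaches the all-ones matrix, whose unit-norm leading
  eigenvector is uniform at 1/sqrt(N).

* **Time-point bootstrap**: one resampled time-index vector per participant
  applied jointly to all ROI columns, preserving cross-ROI structure; the
  spread of recomputed centralities is a confidence distribution for the
  point estimate.

Gaussian fits (sample mean/SD) summarize both distributions for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ROITimeSeries
from .centrality import ec_from_ts

logger = logging.getLogger(__name__)


@dataclass
class SurrogateConfig:
    n_surrogates: int = 1000
    max_iter: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class NullDistribution:
    """Replicate x ROI samples of group-mean EC with per-ROI Gaussian fits."""

    samples: np.ndarray  # (n_replicates, N)
    roi_ids: list[int]
    kind: str  # "surrogate" | "bootstrap"
    gauss_mu: np.ndarray = field(init=False)
    gauss_sigma: np.ndarray = field(init=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.kind not in ("surrogate", "bootstrap"):
            raise ValueError(f"kind must be surrogate|bootstrap, got {self.kind!r}")
        mu = np.empty(self.samples.shape[1])
        sigma = np.empty(self.samples.shape[1])
        for j in range(self.samples.shape[1]):
            mu[j], sigma[j] = fit_gaussian(self.samples[:, j])
        self.gauss_mu = mu
        self.gauss_sigma = sigma

    def for_roi(self, roi_id: int) -> np.ndarray:
        return self.samples[:, self.roi_ids.index(roi_id)]


def fit_gaussian(samples: np.ndarray) -> tuple[float, float]:
    """Sample mean and SD (ddof=1); sigma = 0 with a warning for < 2 samples."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("need at least one sample")
    if x.size < 2:
        logger.warning("fewer than 2 samples; sigma set to 0")
        return float(x[0]), 0.0
    return float(x.mean()), float(x.std(ddof=1))


def _iaaft_block(
    x: np.ndarray, max_iter: int, rng: np.random.Generator, alpha: float = 0.5
) -> np.ndarray:
    """iAAFT surrogates for every column of a (T, N) block, vectorized.

    Each iteration (i) imposes a working amplitude spectrum while keeping the
    current phases, then (ii) rank-remaps onto the column's sorted original
    values. Plain alternation leaves a spectral bias because the value remap
    perturbs the just-imposed spectrum; the working amplitudes are therefore
    nudged by the damped correction ``A_imp *= (A_target / A_achieved)**alpha``
    so the *post-remap* spectrum converges to the target. The returned series
    is the post-remap iterate with the smallest mean relative periodogram
    error, so the value multiset is always exactly the original's.

    Constant columns are returned unchanged (with a warning).
    """
    t, n = x.shape
    const = np.ptp(x, axis=0) == 0
    if np.any(const):
        logger.warning("constant column(s) %s; surrogate returned unchanged",
                       np.flatnonzero(const).tolist())
    sorted_vals = np.sort(x, axis=0)
    target_amp = np.abs(np.fft.rfft(x, axis=0))
    target_pow = target_amp**2
    # guard against zero ordinates in the relative-error weights
    safe_pow = np.where(target_pow[1:] > 0, target_pow[1:], 1.0)

    a_imp = target_amp.copy()
    # random starting shuffle per column: exact value distribution from step 0
    s = np.take_along_axis(x, rng.permuted(np.tile(np.arange(t)[:, None], (1, n)), axis=0), axis=0)
    best = s.copy()
    best_err = np.full(n, np.inf)
    prev_ranks = None
    for _ in range(max_iter):
        spec = np.fft.rfft(s, axis=0)
        mag = np.abs(spec)
        phase = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 1.0)
        s = np.fft.irfft(a_imp * phase, n=t, axis=0)
        ranks = np.argsort(np.argsort(s, axis=0), axis=0)
        s = np.take_along_axis(sorted_vals, ranks, axis=0)
        achieved = np.abs(np.fft.rfft(s, axis=0))
        err = np.mean(np.abs(achieved[1:] ** 2 - target_pow[1:]) / safe_pow, axis=0)
        better = err < best_err
        best_err = np.where(better, err, best_err)
        best[:, better] = s[:, better]
        ratio = np.where(achieved > 0, target_amp / np.where(achieved > 0, achieved, 1.0), 1.0)
        a_imp = a_imp * ratio**alpha
        if prev_ranks is not None and np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks
    best[:, const] = x[:, const]
    return best


def iaaft_surrogate(
    x: np.ndarray,
    max_iter: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One iAAFT surrogate of a univariate series.

    Preserves the input's value distribution exactly (the output's sorted
    values equal the input's) and its power spectrum approximately, while
    randomizing phases; see :func:`_iaaft_block` for the iteration.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need T >= 4 for a surrogate")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _iaaft_block(x[:, None], max_iter=max_iter, rng=rng)[:, 0]


def _cohort_group_mean_ec(cohort_ts: list[ROITimeSeries]) -> np.ndarray:
    ecs = np.vstack([ec_from_ts(ts).ec for ts in cohort_ts])
    return ecs.mean(axis=0)


def surrogate_ec_distribution(
    cohort_ts: list[ROITimeSeries], cfg: SurrogateConfig
) -> NullDistribution:
    """Null distribution of group-mean EC under independent iAAFT surrogates.

    Each replicate replaces every ROI series of every participant by an
    independent surrogate (fresh random phases per ROI and participant),
    removing all cross-ROI correlation, then recomputes per-participant EC
    and records the group mean per ROI.
    """
    if not cohort_ts:
        raise ValueError("cohort must be nonempty")
    roi_ids = list(cohort_ts[0].roi_ids)
    rng = cfg.seed if isinstance(cfg.seed, np.random.Generator) else np.random.default_rng(cfg.seed)
    reps = np.empty((cfg.n_surrogates, len(roi_ids)))
    for r in range(cfg.n_surrogates):
        surro_cohort = [
            ROITimeSeries(
                data=_iaaft_block(ts.data, max_iter=cfg.max_iter, rng=rng),
                roi_ids=roi_ids, tr=ts.tr, participant_id=ts.participant_id,
            )
            for ts in cohort_ts
        ]
        reps[r] = _cohort_group_mean_ec(surro_cohort)
    return NullDistribution(samples=reps, roi_ids=roi_ids, kind="surrogate", seed=cfg.seed)


def bootstrap_ec_distribution(
    cohort_ts: list[ROITimeSeries],
    n_boot: int = 1000,
    seed: int | None = None,
    block: bool = False,
) -> NullDistribution:
    """Confidence distribution of group-mean EC under time-point resampling.

    Per replicate, one index vector (sampled with replacement, length T) is
    drawn per participant and applied to all ROI columns jointly, preserving
    the cross-ROI correlation structure. ``block=True`` uses moving-block
    resampling with block length ceil(sqrt(T)), which additionally preserves
    short-range autocorrelation.
    """
    if not cohort_ts:
        raise ValueError("cohort must be nonempty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    roi_ids = list(cohort_ts[0].roi_ids)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = np.empty((n_boot, len(roi_ids)))
    for r in range(n_boot):
        boot_cohort = []
        for ts in cohort_ts:
            t = ts.n_timepoints
            if block:
                blen = int(np.ceil(np.sqrt(t)))
                n_blocks = int(np.ceil(t / blen))
                starts = rng.integers(0, t - blen + 1, size=n_blocks)
                idx = np.concatenate([np.arange(s, s + blen) for s in starts])[:t]
            else:
                idx = rng.integers(0, t, size=t)
            boot_cohort.append(
                ROITimeSeries(data=ts.data[idx], roi_ids=roi_ids, tr=ts.tr,
                              participant_id=ts.participant_id)
            )
        reps[r] = _cohort_group_mean_ec(boot_cohort)
    return NullDistribution(samples=reps, roi_ids=roi_ids, kind="bootstrap", seed=seed)
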