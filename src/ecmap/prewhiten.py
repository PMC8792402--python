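"""Two-step GLM prewhitening of ROI time series.

BOLD noise is temporally autocorrelated, which biases correlation-based
statistics. The procedure: (1) regress the raw series on the six rigid-body
motion parameters, estimate a lag-1 autoregressive coefficient per ROI on the
residuals, and apply the AR(1) whitening filter to the *raw* data; (2) regress
the motion parameters plus white-matter and CSF mean signals out of the
whitened data. The output is one sample shorter than the input (the filter
consumes the first time point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .atlas import ROITimeSeries

logger = logging.getLogger(__name__)


@dataclass
class ConfoundSet:
    """Nuisance regressors paired with one participant's scan.

    motion : T x 6 (3 translations in mm, 3 rotations in rad)
    wm, csf : length-T mean tissue signals
    """

    motion: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion must be T x 6")
        t = self.motion.shape[0]
        if self.wm.shape[0] != t or self.csf.shape[0] != t:
            raise ValueError("wm/csf length must match motion row count")
        for name, arr in (("motion", self.motion), ("wm", self.wm), ("csf", self.csf)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]


@dataclass
class AR1Estimate:
    """Per-ROI lag-1 autoregressive coefficients, each in (-1, 1)."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float).ravel()
        if np.any(np.abs(self.phi) >= 1):
            raise ValueError("|phi| must be < 1")


def _with_intercept(design: np.ndarray) -> np.ndarray:
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] == 1 and design.shape[1] > 1:
        design = design.T
    # a column with zero variance acts as the intercept
    has_const = np.any(np.ptp(design, axis=0) == 0) if design.size else False
    if not has_const:
        design = np.column_stack([np.ones(design.shape[0]), design])
    return design


def regress_out(ts: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of `ts` against the design (intercept added).

    Rank-deficient designs are handled by the minimum-norm least-squares
    solution (equivalent to dropping dependent columns); a warning is logged.
    """
    y = np.asarray(ts, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y.T).T if squeeze else y
    x = _with_intercept(regressors)
    t, m = x.shape
    if y.shape[0] != t:
        raise ValueError("ts and regressors must have the same number of rows")
    if t <= m:
        raise ValueError(f"need more time points than regressors (T={t}, M={m})")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < m:
        logger.warning("rank-deficient design (rank %d < %d columns); dependent columns ignored", rank, m)
    resid = y - x @ beta
    return resid.ravel() if squeeze else resid


def estimate_ar1(residuals: np.ndarray) -> AR1Estimate:
    """Lag-1 autocorrelation per column (Yule-Walker order 1), clipped to +/-0.99.

    Columns are mean-centered internally; a zero-variance column gets phi = 0
    with a logged warning.
    """
    x = np.atleast_2d(np.asarray(residuals, dtype=float).T).T
    if x.shape[0] < 3:
        raise ValueError("need T >= 3 to estimate AR(1)")
    x = x - x.mean(axis=0)
    denom = np.sum(x**2, axis=0)
    num = np.sum(x[1:] * x[:-1], axis=0)
    phi = np.zeros_like(denom)
    zero = denom <= 0
    if np.any(zero):
        logger.warning("zero-variance column(s) at %s; phi set to 0", np.flatnonzero(zero).tolist())
    np.divide(num, denom, out=phi, where=~zero)
    return AR1Estimate(phi=np.clip(phi, -0.99, 0.99))


def ar1_whiten(
    ts: np.ndarray, ar: AR1Estimate, scaled_first_row: bool = False
) -> np.ndarray:
    """Apply the AR(1) whitening filter x_{t+1} - phi * x_t per column.

    By default the first time point is dropped (output has T-1 rows). With
    ``scaled_first_row`` the stationarity-scaled first row sqrt(1-phi^2)*x_1
    is prepended instead, keeping T rows.
    """
    x = np.asarray(ts, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x.T).T if squeeze else x
    phi = ar.phi
    if phi.shape[0] != x.shape[1]:
        raise ValueError(f"phi length {phi.shape[0]} != column count {x.shape[1]}")
    out = x[1:] - phi[None, :] * x[:-1]
    if scaled_first_row:
        first = np.sqrt(1.0 - phi**2)[None, :] * x[:1]
        out = np.vstack([first, out])
    return out.ravel() if squeeze else out


def prewhiten_pipeline(
    ts: ROITimeSeries,
    confounds: ConfoundSet,
    pooled_phi: bool = False,
    scaled_first_row: bool = False,
) -> ROITimeSeries:
    """Run the full two-step prewhitening on one participant's scan.

    Step 1: residualize against motion, estimate AR(1) on the residuals, and
    whiten the raw series with those coefficients. Step 2: regress motion
    (trimmed to the whitened length, not re-whitened), WM and CSF out of the
    whitened data. With ``pooled_phi`` a single phi (the mean across ROIs) is
    used for every column.
    """
    if ts.participant_id != confounds.participant_id:
        raise ValueError(
            f"participant mismatch: ts {ts.participant_id!r} vs confounds "
            f"{confounds.participant_id!r}"
        )
    if ts.n_timepoints != confounds.n_timepoints:
        raise ValueError("time series and confounds differ in length")

    resid = regress_out(ts.data, confounds.motion)
    ar = estimate_ar1(resid)
    if pooled_phi:
        ar = AR1Estimate(phi=np.full(ts.n_rois, float(ar.phi.mean())))
    white = ar1_whiten(ts.data, ar, scaled_first_row=scaled_first_row)

    offset = 0 if scaled_first_row else 1
    design = np.column_stack(
        [confounds.motion[offset:], confounds.wm[offset:], confounds.csf[offset:]]
    )
    clean = regress_out(white, design)
    return ROITimeSeries(
        data=clean, roi_ids=list(ts.roi_ids), tr=ts.tr, participant_id=ts.participant_id
    )
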