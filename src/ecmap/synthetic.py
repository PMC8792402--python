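"""Synthetic resting-state cohorts with planted hubs and coupled perimetry.

The generator emulates the statistical structure the analysis assumes, so
every stage can be verified against ground truth:

* ROI series follow a low-rank latent-factor model,
  ``x_j(t) = lambda_j * s(t) + gamma_j * c_net(j)(t) + confounds + noise``,
  where ``s`` is a cohort-shared latent signal, ``c_k`` are per-network
  latents, and all latents/noise are unit-variance AR(1) processes. Planted
  hub ROIs load on ``s`` with ``hub_strength``; the rest with
  ``base_strength``. High loading on the shared signal is what makes a node
  central, so hubs are well-defined by construction.
* Disease severity (a nonnegative latent, dB-like scale) attenuates the hub
  loading multiplicatively (``hub_strength * (1 - coupling * severity)``)
  and simultaneously drives visual-field loss, so reduced centrality
  accompanies worse fields.
* Per-eye total-deviation maps are ``-softplus(severity + asymmetry *
  eye_sign + field)`` with a spatially correlated Gaussian field, clipped to
  [-32, 2] dB; md = mean(td).
* Each participant gets two scans ("RS1"/"RS2") with shared loadings but
  independent latents and noise, so test-retest reproducibility is a
  testable property.

Default sizes mirror the study design: 131 ROIs over 7 networks, 260 time
points at TR 1.35 s, 24 controls and 20 patients, of whom 17 and 19
respectively completed perimetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .atlas import ROITimeSeries
from .behavioral import VFMap
from .prewhiten import ConfoundSet
from .vfgrids import grid_locations

_BURN_IN = 50


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_rois: int = 131
    n_timepoints: int = 260
    tr: float = 1.35
    n_controls: int = 24
    n_patients: int = 20
    n_networks: int = 7
    planted_hubs: tuple[int, ...] = (5, 23, 47, 68, 90, 112)
    hub_strength: float = 1.5
    base_strength: float = 0.5
    network_strength: float = 0.8
    ar_phi: float = 0.3
    noise_sd: float = 1.0
    confound_sd: float = 0.5
    coupling: float = 0.1
    severity_mean: float = 3.0
    severity_sd: float = 1.5
    asymmetry_sd: float = 1.0
    grid: str = "24-2"
    field_sd: float = 0.8
    field_scale_deg: float = 10.0
    n_controls_missing_vf: int = 7
    n_patients_missing_vf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar_phi < 1:
            raise ValueError("need 0 <= ar_phi < 1")
        # equality makes all ROIs exchangeable (a valid null construction)
        if not self.hub_strength >= self.base_strength >= 0:
            raise ValueError("need hub_strength >= base_strength >= 0")
        for name in ("n_rois", "n_timepoints", "n_controls", "n_networks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if any(not 0 <= h < self.n_rois for h in self.planted_hubs):
            raise ValueError("planted hub indices must lie in [0, n_rois)")
        if self.grid not in ("24-2", "30-2"):
            raise ValueError("grid must be 24-2|30-2")

    def network_of(self, roi: int) -> int:
        return roi % self.n_networks

    def loadings(self, severity: float) -> np.ndarray:
        """Shared-signal loading per ROI given a participant's severity."""
        lam = np.full(self.n_rois, self.base_strength, dtype=float)
        hub_lam = self.hub_strength * max(0.0, 1.0 - self.coupling * severity)
        lam[list(self.planted_hubs)] = hub_lam
        return lam


@dataclass
class GroundTruth:
    """Everything needed to recompute the generator's expectations."""

    planted_hubs: list[int]
    groups: dict[str, str]
    severity: dict[str, float]
    asymmetry: dict[str, float]
    hub_loading: dict[str, float]
    seed: int


@dataclass
class ParticipantBundle:
    participant_id: str
    group: str  # "control" | "patient"
    severity: float
    asymmetry: float
    scans: dict  # scan name -> (ROITimeSeries, ConfoundSet)
    vf_left: Optional[VFMap] = None
    vf_right: Optional[VFMap] = None

    @property
    def has_vf(self) -> bool:
        return self.vf_left is not None and self.vf_right is not None


def _ar1(rng: np.random.Generator, t: int, phi: float, n_series: int) -> np.ndarray:
    """(t, n_series) unit-variance AR(1) columns."""
    w = rng.standard_normal((t + _BURN_IN, n_series))
    x = lfilter([1.0], [1.0, -phi], w, axis=0)[_BURN_IN:]
    return x * np.sqrt(1.0 - phi**2)


def _confounds(rng: np.random.Generator, t: int, participant_id: str) -> tuple[ConfoundSet, np.ndarray]:
    """Motion as smoothed random walks; WM/CSF as low-frequency sinusoid mixes."""
    steps = rng.normal(0.0, 0.02, size=(t, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    motion = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(6)]
    )
    tt = np.arange(t)
    def sin_mix() -> np.ndarray:
        freqs = rng.uniform(0.5, 3.0, size=3) / t
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.uniform(0.5, 1.0, size=3)
        return (amps[None, :] * np.sin(2 * np.pi * freqs[None, :] * tt[:, None]
                                       + phases[None, :])).sum(axis=1) \
            + rng.normal(0, 0.1, size=t)
    conf = ConfoundSet(motion=motion, wm=sin_mix(), csf=sin_mix(),
                       participant_id=participant_id)
    stacked = np.column_stack([motion, conf.wm, conf.csf])
    std = stacked.std(axis=0)
    std[std == 0] = 1.0
    return conf, (stacked - stacked.mean(axis=0)) / std


def _scan(
    cfg: SimConfig,
    lam: np.ndarray,
    conf_w: np.ndarray,
    rng: np.random.Generator,
    participant_id: str,
) -> tuple[ROITimeSeries, ConfoundSet]:
    t, n = cfg.n_timepoints, cfg.n_rois
    s = _ar1(rng, t, cfg.ar_phi, 1)[:, 0]
    c_net = _ar1(rng, t, cfg.ar_phi, cfg.n_networks)
    noise = _ar1(rng, t, cfg.ar_phi, n) * cfg.noise_sd
    net_idx = np.array([cfg.network_of(j) for j in range(n)])
    data = lam[None, :] * s[:, None] + cfg.network_strength * c_net[:, net_idx] + noise
    conf, conf_std = _confounds(rng, t, participant_id)
    data = data + conf_std @ conf_w
    ts = ROITimeSeries(data=data, roi_ids=list(range(n)), tr=cfg.tr,
                       participant_id=participant_id)
    return ts, conf


def simulate_participant_ts(
    cfg: SimConfig, severity: float, seed: int | np.random.Generator | None = None,
    participant_id: str = "sim",
) -> tuple[ROITimeSeries, ConfoundSet]:
    """One scan for one participant at the given severity."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = cfg.loadings(severity)
    conf_w = rng.normal(0.0, cfg.confound_sd / np.sqrt(8), size=(8, cfg.n_rois))
    return _scan(cfg, lam, conf_w, rng, participant_id)


def simulate_vf_pair(
    severity: float,
    asymmetry: float,
    grid: str = "24-2",
    seed: int | np.random.Generator | None = None,
    participant_id: str = "sim",
    field_sd: float = 0.8,
    field_scale_deg: float = 10.0,
) -> tuple[VFMap, VFMap]:
    """Paired-eye total-deviation maps whose loss tracks severity.

    td = -softplus(severity + asymmetry * eye_sign + field), clipped to
    [-32, 2] dB, with a squared-exponential spatially correlated field;
    md = mean(td). BIVF decreases and AbsDiffMD grows with |asymmetry| in
    expectation by construction.
    """
    if grid not in ("24-2", "30-2"):
        raise ValueError(f"grid must be 24-2|30-2, got {grid!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maps = {}
    for eye, eye_sign in (("left", -1.0), ("right", 1.0)):
        locs = grid_locations(grid, eye)
        d2 = np.sum((locs[:, None, :] - locs[None, :, :]) ** 2, axis=2)
        cov = field_sd**2 * np.exp(-d2 / (2 * field_scale_deg**2))
        cov[np.diag_indices_from(cov)] += 1e-8
        fieldn = np.linalg.cholesky(cov) @ rng.standard_normal(locs.shape[0])
        drive = severity + asymmetry * eye_sign + fieldn
        td = np.clip(-np.logaddexp(0.0, drive), -32.0, 2.0)  # -softplus
        maps[eye] = VFMap(eye=eye, grid=grid, td=td, locations=locs,
                          md=float(td.mean()), participant_id=participant_id)
    return maps["left"], maps["right"]


def simulate_cohort(cfg: SimConfig) -> tuple[list[ParticipantBundle], GroundTruth]:
    """Full two-scan cohort with perimetry, group labels and ground truth.

    Controls have severity 0; patients draw a nonnegative severity with mean
    ``severity_mean`` and SD ``severity_sd``. Loadings (and hence the hub
    structure) are shared between the two scans of a participant; latents and
    noise are independent. A fixed number of participants per group is marked
    as missing perimetry, mirroring study attrition.
    """
    root = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_controls + cfg.n_patients
    child_seeds = root.spawn(n_total + 1)
    master = np.random.default_rng(child_seeds[0])

    ids = [f"C{i+1:02d}" for i in range(cfg.n_controls)] + [
        f"P{i+1:02d}" for i in range(cfg.n_patients)
    ]
    groups = {pid: ("control" if pid.startswith("C") else "patient") for pid in ids}

    miss_c = master.choice(cfg.n_controls,
                           size=min(cfg.n_controls_missing_vf, cfg.n_controls),
                           replace=False)
    miss_p = (cfg.n_controls + master.choice(
        cfg.n_patients, size=min(cfg.n_patients_missing_vf, cfg.n_patients),
        replace=False)) if cfg.n_patients else np.array([], dtype=int)
    missing = {ids[i] for i in np.concatenate([miss_c, np.atleast_1d(miss_p)]).astype(int)}

    bundles: list[ParticipantBundle] = []
    severity_map: dict[str, float] = {}
    asym_map: dict[str, float] = {}
    loading_map: dict[str, float] = {}
    for i, pid in enumerate(ids):
        rng = np.random.default_rng(child_seeds[i + 1])
        if groups[pid] == "control":
            severity, asym = 0.0, 0.0
        else:
            severity = float(np.clip(rng.normal(cfg.severity_mean, cfg.severity_sd),
                                     0.0, None))
            asym = float(rng.normal(0.0, cfg.asymmetry_sd))
        lam = cfg.loadings(severity)
        conf_w = rng.normal(0.0, cfg.confound_sd / np.sqrt(8), size=(8, cfg.n_rois))
        scans = {name: _scan(cfg, lam, conf_w, rng, pid) for name in ("RS1", "RS2")}
        vf_l = vf_r = None
        if pid not in missing:
            vf_l, vf_r = simulate_vf_pair(
                severity, asym, grid=cfg.grid, seed=rng, participant_id=pid,
                field_sd=cfg.field_sd, field_scale_deg=cfg.field_scale_deg,
            )
        bundles.append(ParticipantBundle(
            participant_id=pid, group=groups[pid], severity=severity,
            asymmetry=asym, scans=scans, vf_left=vf_l, vf_right=vf_r,
        ))
        severity_map[pid] = severity
        asym_map[pid] = asym
        loading_map[pid] = float(lam[cfg.planted_hubs[0]]) if cfg.planted_hubs else float("nan")

    truth = GroundTruth(
        planted_hubs=list(cfg.planted_hubs), groups=groups, severity=severity_map,
        asymmetry=asym_map, hub_loading=loading_map, seed=cfg.seed,
    )
    return bundles, truth
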