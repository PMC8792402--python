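"""Visual-field scores and their correlation with hub centrality.

Three scores summarize a participant's binocular field loss from per-eye
Humphrey total-deviation (TD) grids and mean deviations (MD, in dB; more
negative = worse):

* **WorseMD** — the MD of the worse (more negative) eye.
* **BIVF** (binocular integrated visual field) — at each visual-field
  location seen by both eyes, take the better (higher) TD of the two, then
  average; this models binocular compensation, where one eye's intact region
  can cover the other's defect.
* **AbsDiffMD** — the absolute between-eye MD difference, an asymmetry index.

Scores are correlated with per-participant hub centrality by Spearman rank
correlation (average ranks for ties; exact permutation p for n <= 9, the
t-approximation otherwise), dropping participants pairwise where a score is
missing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import HubSet
from .vfgrids import expected_point_count, grid_locations

SCORE_NAMES = ("worse_md", "bivf", "abs_diff_md")


@dataclass
class VFMap:
    """One eye's total-deviation map on a standard perimetry grid.

    ``locations`` are visual-field coordinates in degrees (same frame for
    both eyes); ``td`` the per-location total deviation in dB; ``md`` the
    instrument's mean deviation.
    """

    eye: str
    grid: str
    td: np.ndarray
    locations: np.ndarray
    md: float
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be left|right, got {self.eye!r}")
        if self.grid not in ("24-2", "30-2"):
            raise ValueError(f"grid must be 24-2|30-2, got {self.grid!r}")
        self.td = np.asarray(self.td, dtype=float).ravel()
        self.locations = np.asarray(self.locations, dtype=float).reshape(-1, 2)
        if self.td.shape[0] != self.locations.shape[0]:
            raise ValueError("td and locations length mismatch")
        if not np.all(np.isfinite(self.td)):
            raise ValueError("td must be finite")
        uniq = {tuple(p) for p in self.locations.tolist()}
        if len(uniq) != self.locations.shape[0]:
            raise ValueError("locations must be unique")

    @classmethod
    def on_standard_grid(
        cls, eye: str, grid: str, td: np.ndarray, md: float | None = None,
        participant_id: str = "",
    ) -> "VFMap":
        """Build a map on the full standard grid (blind spot excluded).

        With ``md=None`` the fallback md = mean(td) is used (flagged for
        synthetic data; instrument MD is age-adjusted and not recomputable
        from td alone).
        """
        locs = grid_locations(grid, eye)
        td = np.asarray(td, dtype=float).ravel()
        if td.shape[0] != expected_point_count(grid):
            raise ValueError(
                f"expected {expected_point_count(grid)} points for {grid}, got {td.shape[0]}"
            )
        if md is None:
            md = float(td.mean())
        return cls(eye=eye, grid=grid, td=td, locations=locs, md=md,
                   participant_id=participant_id)


@dataclass
class BehavioralScores:
    """WorseMD, BIVF and AbsDiffMD (dB) for one participant; NaN = missing."""

    worse_md: float
    bivf: float
    abs_diff_md: float
    participant_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {"worse_md": self.worse_md, "bivf": self.bivf,
                "abs_diff_md": self.abs_diff_md}


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def worse_md(md_left: float, md_right: float) -> float:
    """MD of the worse eye: min of the two (more negative = worse)."""
    if _missing(md_left) or _missing(md_right):
        return float("nan")
    return float(min(md_left, md_right))


def abs_diff_md(md_left: float, md_right: float) -> float:
    """Absolute between-eye MD difference."""
    if _missing(md_left) or _missing(md_right):
        return float("nan")
    return float(abs(md_right - md_left))


def bivf(left: VFMap, right: VFMap) -> float:
    """Binocular integrated visual field: mean of pointwise-best TD.

    For each location present in both eyes' grids (same point in visual
    space), the higher TD is selected; the score is the mean of these maxima.
    A 30-2 vs 24-2 pairing overlaps on the 24-2 point set (minus per-eye
    asymmetric points).
    """
    if left.eye == right.eye:
        raise ValueError("bivf needs one map per eye")
    if left.participant_id != right.participant_id:
        raise ValueError("eye maps belong to different participants")
    lmap = {tuple(p): v for p, v in zip(left.locations.tolist(), left.td)}
    rmap = {tuple(p): v for p, v in zip(right.locations.tolist(), right.td)}
    common = sorted(set(lmap) & set(rmap))
    if not common:
        raise ValueError("no overlapping visual-field locations")
    best = [max(lmap[p], rmap[p]) for p in common]
    return float(np.mean(best))


def behavioral_scores(
    left: VFMap | None, right: VFMap | None, participant_id: str = ""
) -> BehavioralScores:
    """All three scores for one participant; missing eyes give NaN scores."""
    if left is None or right is None:
        return BehavioralScores(float("nan"), float("nan"), float("nan"),
                                participant_id)
    return BehavioralScores(
        worse_md=worse_md(left.md, right.md),
        bivf=bivf(left, right),
        abs_diff_md=abs_diff_md(left.md, right.md),
        participant_id=participant_id or left.participant_id,
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with exact permutation p for n <= 9, else t-approximation."""
    n = x.size
    rho = float(stats.spearmanr(x, y).statistic)
    if not np.isfinite(rho):
        return rho, float("nan")
    if n <= 9:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        perms = np.array(list(itertools.permutations(range(n))))
        null = (rx[perms] * ((ry - ry.mean()) / ry.std())).mean(axis=1)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def correlate_scores_with_ec(
    scores: pd.DataFrame, ec_table: pd.DataFrame, hubs: HubSet
) -> pd.DataFrame:
    """Spearman correlation of each behavioral score with each hub's EC.

    ``scores`` is indexed by participant with columns worse_md, bivf,
    abs_diff_md; ``ec_table`` is participants x ROIs. Participants missing a
    score or an EC value are dropped pairwise; a pairing with fewer than 4
    complete pairs is marked not-computable (NaN rho/p).

    Returns a tidy frame with columns hub, score, rho, p, n.
    """
    for c in SCORE_NAMES:
        if c not in scores.columns:
            raise ValueError(f"scores missing column {c!r}")
    rows = []
    common = scores.index.intersection(ec_table.index)
    for rid in hubs.roi_ids:
        if rid not in ec_table.columns:
            raise ValueError(f"unknown hub id: {rid}")
        ec = ec_table.loc[common, rid]
        for score in SCORE_NAMES:
            sc = scores.loc[common, score]
            ok = sc.notna() & ec.notna()
            n = int(ok.sum())
            if n < 4:
                rows.append({"hub": rid, "score": score, "rho": float("nan"),
                             "p": float("nan"), "n": n})
                continue
            rho, p = _spearman(ec[ok].to_numpy(float), sc[ok].to_numpy(float))
            rows.append({"hub": rid, "score": score, "rho": rho, "p": p, "n": n})
    return pd.DataFrame(rows, columns=["hub", "score", "rho", "p", "n"])


def read_vf_csv(path: str | Path) -> VFMap:
    """Read a per-participant-eye CSV: header lines ``# key=value`` for
    participant_id, eye, grid, md_db, then columns x_deg, y_deg, td_db."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition("=")
            meta[k.strip()] = v.strip()
        else:
            body.append(line)
    import io

    df = pd.read_csv(io.StringIO("\n".join(body)))
    for c in ("x_deg", "y_deg", "td_db"):
        if c not in df.columns:
            raise ValueError(f"VF file missing column {c!r}")
    md = float(meta["md_db"]) if "md_db" in meta else float(df["td_db"].mean())
    return VFMap(
        eye=meta.get("eye", "right"),
        grid=meta.get("grid", "24-2"),
        td=df["td_db"].to_numpy(float),
        locations=df[["x_deg", "y_deg"]].to_numpy(float),
        md=md,
        participant_id=meta.get("participant_id", ""),
    )


def write_vf_csv(vf: VFMap, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# participant_id={vf.participant_id}",
        f"# eye={vf.eye}",
        f"# grid={vf.grid}",
        f"# md_db={vf.md}",
        "x_deg,y_deg,td_db",
    ]
    for (x, y), v in zip(vf.locations.tolist(), vf.td):
        lines.append(f"{x},{y},{v}")
    path.write_text("\n".join(lines) + "\n")
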