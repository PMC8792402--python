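"""Spherical ROI atlases and voxel-averaged time-series extraction.

An atlas is an ordered list of spherical regions of interest (ROIs), each a
5 mm-radius sphere around an MNI coordinate with a functional-network label.
The ROI order is stable and defines the column order of every downstream
matrix (time series, connectivity, centrality).

A synthetic 232-ROI fixture in the style of the Power parcellation ships with
the package (``data/atlas232_synthetic.tsv``); its coordinates and labels are
generated, not the published node set, and it is laid out so that merging the
two somatomotor sub-networks and dropping the cerebellar, uncertain and
subcortical networks leaves 131 ROIs over 7 networks.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ATLAS_COLUMNS = ("roi_id", "x", "y", "z", "network", "hemisphere", "name")

#: default network surgery mirroring the study design: combine the two
#: somatomotor sub-networks, keep only cortical networks of interpretable
#: function.
DEFAULT_MERGE_PAIRS = [("somatomotor_hand", "somatomotor_mouth", "somatomotor")]
DEFAULT_DROP_LABELS = ["cerebellar", "uncertain", "subcortical"]


@dataclass(frozen=True)
class AtlasROI:
    """A spherical ROI: MNI center (mm), radius (mm), network and name."""

    roi_id: int
    center: tuple[float, float, float]
    network: str
    hemisphere: str
    name: str
    radius: float = 5.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left|right, got {self.hemisphere!r}")
        x = self.center[0]
        if (x > 0 and self.hemisphere != "right") or (x < 0 and self.hemisphere != "left"):
            raise ValueError(
                f"ROI {self.roi_id}: hemisphere {self.hemisphere!r} inconsistent with x={x}"
            )


@dataclass(frozen=True)
class Atlas:
    """Ordered collection of :class:`AtlasROI`; order fixes column order downstream."""

    rois: tuple[AtlasROI, ...]

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.rois]
        seen: set[int] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate roi_id: {i}")
            seen.add(i)

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def roi_ids(self) -> list[int]:
        return [r.roi_id for r in self.rois]

    @property
    def networks(self) -> set[str]:
        return {r.network for r in self.rois}

    @property
    def centers(self) -> np.ndarray:
        return np.array([r.center for r in self.rois], dtype=float)


@dataclass
class ROITimeSeries:
    """T x N matrix of BOLD samples with ROI identities and the repetition time.

    Rows are time points, columns are ROIs in atlas order.
    """

    data: np.ndarray
    roi_ids: list[int]
    tr: float
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x ROI)")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise ValueError(f"need T >= 2 and N >= 2, got shape {self.data.shape}")
        if n != len(self.roi_ids):
            raise ValueError("column count does not match roi_ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def load_atlas(path: str | Path) -> Atlas:
    """Load an atlas from a TSV table with columns roi_id, x, y, z, network, hemisphere, name."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"atlas table missing column(s): {', '.join(missing)}")
    dup = df["roi_id"][df["roi_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate roi_id: {int(dup.iloc[0])}")
    rois = tuple(
        AtlasROI(
            roi_id=int(row.roi_id),
            center=(float(row.x), float(row.y), float(row.z)),
            network=str(row.network),
            hemisphere=str(row.hemisphere),
            name=str(row.name),
        )
        for row in df.itertuples(index=False)
    )
    return Atlas(rois=rois)


def bundled_atlas() -> Atlas:
    """The packaged synthetic 232-ROI atlas fixture."""
    ref = importlib.resources.files("ecmap.data") / "atlas232_synthetic.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_atlas(p)


def filter_atlas(
    atlas: Atlas,
    merge_pairs: Iterable[tuple[str, str, str]] = (),
    drop_labels: Iterable[str] = (),
    strict: bool = True,
) -> Atlas:
    """Merge networks pairwise into new labels and drop whole networks.

    ROI order of survivors is preserved. In strict mode every referenced label
    must exist in the atlas.
    """
    merge_pairs = list(merge_pairs)
    drop_labels = list(drop_labels)
    known = atlas.networks
    if strict:
        referenced = [l for a, b, _ in merge_pairs for l in (a, b)] + drop_labels
        for label in referenced:
            if label not in known:
                raise ValueError(f"unknown network label: {label}")
    relabel: dict[str, str] = {}
    for a, b, new in merge_pairs:
        relabel[a] = new
        relabel[b] = new
    drops = set(drop_labels)
    survivors = []
    for roi in atlas.rois:
        if roi.network in drops:
            continue
        net = relabel.get(roi.network, roi.network)
        survivors.append(replace(roi, network=net) if net != roi.network else roi)
    return Atlas(rois=tuple(survivors))


def extract_roi_timeseries(
    volume, atlas: Atlas, mask=None, participant_id: str = ""
) -> ROITimeSeries:
    """Average the 4-D image over each ROI's voxels per time point.

    A voxel belongs to a sphere iff its center (in mm, via the image affine)
    lies within the ROI radius (closed ball); overlapping spheres share
    voxels. TR is read from the image header.

    Parameters
    ----------
    volume : nibabel image or path
        4-D NIfTI with a valid affine.
    mask : nibabel image or path, optional
        3-D mask on the same grid; voxels where the mask is 0 are excluded.
    """
    import nibabel as nib

    if isinstance(volume, (str, Path)):
        volume = nib.load(str(volume))
    if isinstance(mask, (str, Path)):
        mask = nib.load(str(mask))

    affine = np.asarray(volume.affine, dtype=float)
    if not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("volume affine is missing or singular")
    data = np.asarray(volume.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume")
    nx, ny, nz, nt = data.shape

    zooms = volume.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    mm = vox @ affine[:3, :3].T + affine[:3, 3]  # voxel centers in world mm

    in_mask = np.ones(mm.shape[0], dtype=bool)
    if mask is not None:
        mvals = np.asarray(mask.dataobj).astype(bool).ravel()
        if mvals.shape[0] != mm.shape[0]:
            raise ValueError("mask grid does not match volume grid")
        in_mask = mvals

    flat = data.reshape(-1, nt)
    series = np.empty((nt, len(atlas)), dtype=float)
    empty: list[int] = []
    for col, roi in enumerate(atlas.rois):
        d2 = np.sum((mm - np.asarray(roi.center)) ** 2, axis=1)
        sel = (d2 <= roi.radius**2) & in_mask
        if not np.any(sel):
            empty.append(roi.roi_id)
            continue
        series[:, col] = flat[sel].mean(axis=0)
    if empty:
        raise ValueError(f"empty ROI: {', '.join(map(str, empty))}")

    return ROITimeSeries(
        data=series, roi_ids=atlas.roi_ids, tr=tr, participant_id=participant_id
    )


def write_roi_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    """Write a time-series TSV (first column ``t``) plus a JSON sidecar with TR."""
    path = Path(path)
    df = pd.DataFrame(ts.data, columns=[str(r) for r in ts.roi_ids])
    df.insert(0, "t", np.arange(ts.n_timepoints))
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"tr": ts.tr, "participant_id": ts.participant_id}
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=2))


def read_roi_timeseries(path: str | Path) -> ROITimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "t" not in df.columns:
        raise ValueError("time-series TSV must have a 't' column")
    sidecar_path = path.with_suffix(".json")
    tr, pid = 1.0, ""
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        tr = float(sidecar.get("tr", 1.0))
        pid = str(sidecar.get("participant_id", ""))
    cols = [c for c in df.columns if c != "t"]
    return ROITimeSeries(
        data=df[cols].to_numpy(float),
        roi_ids=[int(c) for c in cols],
        tr=tr,
        participant_id=pid,
    )
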