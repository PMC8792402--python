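"""Humphrey-style perimetry grid geometry (24-2 and 30-2 patterns).

Locations are visual-field coordinates in degrees: x positive to the
subject's right, y positive upward, for both eyes (the standard chart
convention, so "the same location" means the same point in visual space).
The physiological blind spot sits temporally at (15, +/-3) for the right eye
and (-15, +/-3) for the left; those points are excluded by default, leaving
52 test points for 24-2 and 74 for 30-2.
"""

from __future__ import annotations

import numpy as np

# 24-2 (right-eye template): rows y = +/-21, +/-15, +/-9, +/-3; the two rows at
# y = +/-3 extend one extra step nasally (x = -27 for the right eye).
_ROWS_24_2 = {
    21: (-9, 9), 15: (-15, 15), 9: (-21, 21), 3: (-27, 21),
    -3: (-27, 21), -9: (-21, 21), -15: (-15, 15), -21: (-9, 9),
}


def _grid_24_2_right() -> np.ndarray:
    pts = []
    for y, (lo, hi) in _ROWS_24_2.items():
        for x in range(lo, hi + 1, 6):
            pts.append((x, y))
    return np.array(pts, dtype=float)


def _grid_30_2_right() -> np.ndarray:
    vals = [-27, -21, -15, -9, -3, 3, 9, 15, 21, 27]
    pts = [
        (x, y)
        for x in vals
        for y in vals
        if np.hypot(x, y) <= 30 and not (abs(x) == 21 and abs(y) == 21)
    ]
    return np.array(pts, dtype=float)


def blind_spot(eye: str) -> np.ndarray:
    """The two blind-spot test locations for the given eye."""
    sign = 1.0 if eye == "right" else -1.0
    return np.array([[15.0 * sign, 3.0], [15.0 * sign, -3.0]])


def grid_locations(
    grid: str, eye: str, include_blind_spot: bool = False
) -> np.ndarray:
    """(n, 2) array of test locations in visual-field degrees for one eye."""
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be left|right, got {eye!r}")
    if grid == "24-2":
        pts = _grid_24_2_right()
    elif grid == "30-2":
        pts = _grid_30_2_right()
    else:
        raise ValueError(f"grid must be 24-2|30-2, got {grid!r}")
    if eye == "left":
        pts = pts * np.array([-1.0, 1.0])  # mirror the nasal extension
    if not include_blind_spot:
        bs = blind_spot(eye)
        keep = ~np.any(np.all(np.isclose(pts[:, None, :], bs[None, :, :]), axis=2), axis=1)
        pts = pts[keep]
    order = np.lexsort((pts[:, 0], -pts[:, 1]))  # chart order: top row first
    return pts[order]


def expected_point_count(grid: str, include_blind_spot: bool = False) -> int:
    n = {"24-2": 54, "30-2": 76}[grid]
    return n if include_blind_spot else n - 2
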