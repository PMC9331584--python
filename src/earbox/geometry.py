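"""Roller acquisition geometry: rolling-contact ear rotation and circumference coverage.

Ears rest on a pair of motorized rollers and rotate by rolling contact each
time the rollers step.  Because contact arc lengths are equal on roller and
ear, the ear rotation per roller step is the roller step angle scaled by the
ratio of roller to ear diameter.  Each image captures a fixed arc of the ear
circumference; the cumulative fraction of the circumference seen over all
views is the union of the per-view arcs on the circle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionPlan",
    "ear_rotation_step",
    "circumference_coverage",
    "coverage_map",
]


@dataclass(frozen=True)
class AcquisitionPlan:
    """Acquisition parameters of the imaging box.

    Parameters
    ----------
    roller_diameter : float
        Diameter of the drive rollers in cm.
    roller_step_angle : float
        Rotation of the rollers between consecutive images, degrees.
    n_views : int
        Number of images taken per ear.
    view_arc : float
        Arc of ear circumference captured per image, degrees.
    """

    roller_diameter: float = 5.2
    roller_step_angle: float = 58.0
    n_views: int = 6
    view_arc: float = 120.0

    def __post_init__(self) -> None:
        if self.roller_diameter <= 0:
            raise ValueError("roller_diameter must be > 0")
        if not (0 < self.view_arc <= 360):
            raise ValueError("view_arc must lie in (0, 360]")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")

    def replace(self, **changes) -> "AcquisitionPlan":
        return dataclasses.replace(self, **changes)


def ear_rotation_step(plan: AcquisitionPlan, ear_diameter: float) -> float:
    """Ear rotation (degrees) per roller step, from no-slip rolling contact.

    Equal contact arc lengths on roller and ear give
    ``step * roller_diameter / ear_diameter``.
    """
    if ear_diameter <= 0:
        raise ValueError("ear_diameter must be > 0")
    return plan.roller_step_angle * plan.roller_diameter / ear_diameter


def _union_of_arcs(centres_deg: np.ndarray, width_deg: float) -> float:
    """Measure (degrees) of the union of closed arcs on the circle.

    Arcs are ``[c - w/2, c + w/2]`` reduced modulo 360 and merged
    analytically by interval sweeping, so the result carries no raster
    resolution artefact.
    """
    if width_deg >= 360:
        return 360.0
    starts = np.mod(np.asarray(centres_deg, dtype=float) - width_deg / 2.0, 360.0)
    intervals = []
    for s in starts:
        e = s + width_deg
        if e <= 360.0:
            intervals.append((s, e))
        else:  # wraps past 0
            intervals.append((s, 360.0))
            intervals.append((0.0, e - 360.0))
    intervals.sort()
    total = 0.0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return min(total, 360.0)


def view_centres(plan: AcquisitionPlan, ear_diameter: float, offset_deg: float = 0.0) -> np.ndarray:
    """Angular centre of each view: cumulative ear rotation k*step (first image
    before any rotation), plus an optional global offset."""
    step = ear_rotation_step(plan, ear_diameter)
    return offset_deg + step * np.arange(plan.n_views)


def circumference_coverage(
    plan: AcquisitionPlan, ear_diameter: float, offset_deg: float = 0.0
) -> float:
    """Cumulative percentage of the ear circumference seen over all views."""
    centres = view_centres(plan, ear_diameter, offset_deg)
    return 100.0 * _union_of_arcs(centres, plan.view_arc) / 360.0


def coverage_map(
    plan: AcquisitionPlan,
    diameter_grid: np.ndarray,
    angle_grid: np.ndarray,
) -> np.ndarray:
    """Coverage (percent) for every (roller step angle, ear diameter) pair.

    Returns an array of shape ``(len(angle_grid), len(diameter_grid))``;
    row/column order follows the input grids.
    """
    diameters = np.atleast_1d(np.asarray(diameter_grid, dtype=float))
    angles = np.atleast_1d(np.asarray(angle_grid, dtype=float))
    if diameters.size == 0 or angles.size == 0:
        raise ValueError("diameter_grid and angle_grid must be non-empty")
    if np.any(diameters <= 0):
        raise ValueError("diameters must be > 0")
    out = np.empty((angles.size, diameters.size), dtype=float)
    for i, a in enumerate(angles):
        p = plan.replace(roller_step_angle=float(a))
        for j, d in enumerate(diameters):
            out[i, j] = circumference_coverage(p, float(d))
    return out
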