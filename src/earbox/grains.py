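"""Per-grain measurements: barycentres, fitted rectangles, arc correction.

A grain width read off the image is a chord of the ear's roughly circular
cross-section, so grains near the limb look narrower than they are.  The
arc correction projects the chord endpoints back onto a circle of radius
``Diameter_i / 2`` (the ear radius at the grain's row) and measures the
arc between them: ``R * |asin(x2/R) - asin(x1/R)|`` with signed offsets
measured from the ear centreline.  Applied to the fitted rectangle's
horizontal extremes, it makes grain width independent of the grain's
angular position around the ear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .morphometry import CentralAxis, DiameterProfile

__all__ = ["Grain", "extract_grains", "arc_correct", "grain_dimensions"]


@dataclass
class Grain:
    """One segmented grain in one view."""

    label: int
    barycentre_row: float
    barycentre_col: float
    min_row: int            # bounding rectangle, half-open [min, max)
    min_col: int
    max_row: int
    max_col: int
    height_cm: float | None = None
    width_cm: float | None = None
    cohort: int | None = None
    view_index: int | None = None
    flags: set = field(default_factory=set)

    @property
    def height_px(self) -> int:
        return self.max_row - self.min_row

    @property
    def width_px(self) -> int:
        return self.max_col - self.min_col


def extract_grains(label_mask: np.ndarray, view_index: int | None = None) -> list[Grain]:
    """One :class:`Grain` per distinct positive label in the instance mask.

    Barycentre = mean pixel coordinate of the region; rectangle =
    axis-aligned bounding box (image axes are the reference, since the ear
    is vertically oriented).
    """
    mask = np.asarray(label_mask)
    if mask.size == 0 or mask.max() == 0:
        return []
    grains = []
    for rp in measure.regionprops(mask.astype(np.int64)):
        r, c = rp.centroid
        grains.append(
            Grain(
                label=int(rp.label),
                barycentre_row=float(r),
                barycentre_col=float(c),
                min_row=int(rp.bbox[0]),
                min_col=int(rp.bbox[1]),
                max_row=int(rp.bbox[2]),
                max_col=int(rp.bbox[3]),
                view_index=view_index,
            )
        )
    return grains


def arc_correct(x1_offset: float, x2_offset: float, radius: float,
                warn_on_clamp: bool = True) -> float:
    """Arc length (cm) on a circle of ``radius`` between two chord offsets.

    ``x1_offset`` and ``x2_offset`` are signed horizontal distances (cm)
    from the ear centreline.  Offsets beyond the limb (|x| > radius) are
    clamped to it.  The result is always >= the chord ``|x2 - x1|``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    u1, u2 = x1_offset / radius, x2_offset / radius
    if warn_on_clamp and (abs(u1) > 1.0 or abs(u2) > 1.0):
        warnings.warn("offset beyond ear limb; clamped to the limb", stacklevel=2)
    u1, u2 = np.clip(u1, -1.0, 1.0), np.clip(u2, -1.0, 1.0)
    return float(radius * abs(np.arcsin(u2) - np.arcsin(u1)))


def grain_dimensions(
    grain: Grain,
    axis: CentralAxis,
    diameter: DiameterProfile,
    pixel_scale: float,
) -> tuple[float, float]:
    """(height cm, width cm) of a grain; also stored on the grain.

    Height is the fitted-rectangle extent along the ear axis.  Width is the
    arc correction of the rectangle's left/right extremes, with offsets
    taken from the central-axis abscissa at the barycentre row (so bowed
    ears are handled) and radius = half the ear diameter at that row.
    """
    row = int(round(grain.barycentre_row))
    d_cm = diameter.diameter_at(row)
    if d_cm <= 0:
        grain.flags.add("invalid_measurement")
        grain.height_cm = grain.height_px / pixel_scale
        grain.width_cm = None
        return grain.height_cm, float("nan")
    radius = d_cm / 2.0
    centre = axis.centre_at(row)
    # outer pixel edges of the half-open bbox, matching the contour-based
    # diameter convention (right - left + 1)
    x1 = (grain.min_col - 0.5 - centre) / pixel_scale
    x2 = (grain.max_col - 0.5 - centre) / pixel_scale
    if abs(x1) > radius or abs(x2) > radius:
        grain.flags.add("near_limb")
    width = arc_correct(x1, x2, radius, warn_on_clamp=False)
    grain.height_cm = grain.height_px / pixel_scale
    grain.width_cm = width
    return grain.height_cm, width
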