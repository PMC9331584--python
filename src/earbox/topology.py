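"""Spatial organization of grains: cohorts, crossing profiles, grain counts.

Grains on a maize ear form rings (cohorts, synchronous development) and
vertical files (rows).  Cohorts are recovered bottom-up by grouping grain
barycentres within a vertical window of half the mean grain width.  Two
reduced representations of each grain drive the counting statistics:

* a 1-px *horizontal* segment (its bbox horizontal extent at the
  barycentre row): scanning each image column bottom to top and counting
  crossings gives a per-column cohort count whose maximum is the number of
  cohorts visible in the view;
* a 1-px *vertical* segment (its bbox vertical extent at the barycentre
  column): per row, the mean arc-corrected gap ``Dist_i`` between
  consecutive crossing columns extrapolates around the circumference as
  ``pi * Diameter_i / Dist_i`` grains per cohort.

The per-ear grain number averages an over-estimator (median-zone grains
per cohort x maximum cohort count) and an under-estimator combining both
statistics per ear third.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grains import Grain, arc_correct
from .morphometry import CentralAxis, DiameterProfile

__all__ = [
    "CohortCountProfile",
    "GrainsPerCohortProfile",
    "ViewGrainEstimate",
    "assign_cohorts",
    "cohort_count_profile",
    "grains_per_cohort_profile",
    "view_grain_estimate",
    "grain_number_per_ear",
]


@dataclass
class CohortCountProfile:
    """Per-column horizontal-segment crossing counts (bottom -> top scan)."""

    per_column: np.ndarray   # int, one entry per image column
    max_count: int


@dataclass
class GrainsPerCohortProfile:
    """Per-row grains-per-cohort estimate ``pi * Diameter_i / Dist_i``.

    ``estimate`` is NaN where fewer than two vertical grain lines cross the
    row.  Rows are ordered bottom -> top, aligned with ``rows``.
    """

    rows: np.ndarray         # raster row indices, bottom first
    estimate: np.ndarray     # grains per cohort, NaN where undefined
    dist_cm: np.ndarray      # mean arc-corrected neighbour distance, NaN where undefined
    diameter_cm: np.ndarray  # ear diameter at each row

    def zone_slices(self) -> tuple[slice, slice, slice]:
        """Equal thirds of the ear-row range: (basal, median, apical)."""
        n = len(self.rows)
        a, b = n // 3, 2 * n // 3
        return slice(0, a), slice(a, b), slice(b, n)


def assign_cohorts(grains: list[Grain], window_factor: float = 0.5) -> list[Grain]:
    """Assign cohort ranks (1..n, bottom to top) by iterative grouping.

    The grouping window is ``window_factor`` x the mean grain bbox width
    (px) over all grains in the view.  Starting from the lowest unassigned
    barycentre, every unassigned grain whose barycentre row lies within the
    window above the seed joins the cohort (window boundary inclusive);
    assigned grains are removed and the scan repeats.
    """
    if not grains:
        return grains
    window = window_factor * float(np.mean([g.width_px for g in grains]))
    # raster row 0 is the image top: "lowest grain" has the largest row
    remaining = sorted(grains, key=lambda g: -g.barycentre_row)
    rank = 0
    while remaining:
        rank += 1
        seed_row = remaining[0].barycentre_row
        members = [g for g in remaining if g.barycentre_row >= seed_row - window]
        for g in members:
            g.cohort = rank
        remaining = [g for g in remaining if g.cohort is None]
    return grains


def cohort_count_profile(
    grains: list[Grain],
    mask_width: int,
    row_range: tuple[int, int] | None = None,
) -> CohortCountProfile:
    """Count, per column, the horizontal grain segments crossed bottom to top.

    Each grain contributes a 1-px-high horizontal segment spanning its bbox
    horizontal extent at its barycentre row.  ``row_range`` (min_row,
    max_row, inclusive, raster coordinates) optionally restricts the count
    to segments within an ear zone.
    """
    counts = np.zeros(int(mask_width), dtype=int)
    for g in grains:
        if row_range is not None:
            r = g.barycentre_row
            if not (row_range[0] <= r <= row_range[1]):
                continue
        counts[max(g.min_col, 0): min(g.max_col, len(counts))] += 1
    return CohortCountProfile(per_column=counts, max_count=int(counts.max(initial=0)))


def grains_per_cohort_profile(
    grains: list[Grain],
    axis: CentralAxis,
    diameter: DiameterProfile,
    capture_arc: float = 120.0,
) -> GrainsPerCohortProfile:
    """Estimate grains per cohort at every ear row.

    Each grain is shrunk to a 1-px-wide vertical segment at its barycentre
    column spanning its bbox vertical extent.  Per row, consecutive
    crossing columns are arc-corrected onto the ear's circular section
    (radius ``Diameter_i / 2``, offsets from the central axis) and their
    mean gap ``Dist_i`` gives the estimate ``pi * Diameter_i / Dist_i``.
    The wrap-around gap is excluded: only the visible side of the ear
    carries grains, and the ratio itself extrapolates to the full circle.

    Crossings whose offset from the centreline exceeds
    ``sin(capture_arc / 2)`` of the ear radius are discarded: beyond the
    reliably captured arc of the acquisition design, foreshortening makes
    chord midpoints (hence arc-corrected gaps) unreliable.

    A grain's barycentre is the midpoint of its projected chord, which
    sits at ``R * sin(theta) * cos(w / 2R)`` for a grain of width ``w``
    centred at angle ``theta`` — compressed towards the centreline by the
    known factor ``cos(w / 2R)``.  Offsets are divided by that factor
    (from the mean measured grain width) before arc correction, so the
    recovered angular gaps are unbiased.
    """
    rows = diameter.rows
    n = len(rows)
    est = np.full(n, np.nan)
    dist = np.full(n, np.nan)
    if n == 0:
        return GrainsPerCohortProfile(rows=rows, estimate=est, dist_cm=dist,
                                      diameter_cm=np.empty(0))
    row_index = {int(r): i for i, r in enumerate(rows)}
    crossings: list[list[float]] = [[] for _ in range(n)]
    for g in grains:
        for r in range(g.min_row, g.max_row):
            i = row_index.get(r)
            if i is not None:
                crossings[i].append(g.barycentre_col)
    scale = diameter.pixel_scale
    max_offset = np.sin(np.radians(capture_arc / 2.0))
    widths = [g.width_cm for g in grains if g.width_cm is not None]
    mean_width = float(np.mean(widths)) if widths else 0.0
    for i, cols in enumerate(crossings):
        if len(cols) < 2:
            continue
        cols = np.sort(np.asarray(cols))
        radius = diameter.diameter_cm[i] / 2.0
        if radius <= 0:
            continue
        centre = axis.centre_at(int(rows[i]))
        offsets = (cols - centre) / scale
        offsets = offsets[np.abs(offsets) <= max_offset * radius]
        if len(offsets) < 2:
            continue
        compression = np.cos(min(mean_width / (2.0 * radius), 1.0))
        offsets = np.clip(offsets / compression, -radius, radius)
        gaps = [
            arc_correct(a, b, radius, warn_on_clamp=False)
            for a, b in zip(offsets[:-1], offsets[1:])
        ]
        d = float(np.mean(gaps))
        if d > 0:
            dist[i] = d
            est[i] = np.pi * diameter.diameter_cm[i] / d
    return GrainsPerCohortProfile(rows=rows, estimate=est, dist_cm=dist,
                                  diameter_cm=diameter.diameter_cm.copy())


@dataclass
class ViewGrainEstimate:
    """Composite per-view grain-number estimate."""

    over: float
    under: float

    @property
    def value(self) -> float:
        return (self.over + self.under) / 2.0


def _zone_mean_crossings(grains: list[Grain], mask_width: int,
                         row_range: tuple[int, int]) -> float:
    """Mean per-column crossing count restricted to a zone, over columns
    crossed at least once (0 when the zone is barren)."""
    counts = cohort_count_profile(grains, mask_width, row_range=row_range).per_column
    hit = counts > 0
    return float(counts[hit].mean()) if np.any(hit) else 0.0


def view_grain_estimate(
    grains: list[Grain],
    gpc: GrainsPerCohortProfile,
    mask_width: int,
    under_strategy: str = "zonal",
) -> ViewGrainEstimate:
    """Over/under grain-number estimators for one view.

    over  = mean grains-per-cohort over the median third x the maximum
            cohort count of the whole view.
    under ("zonal", default) = sum over ear thirds of (mean grains per
            cohort in the third) x (mean per-column crossing count in the
            third); a barren zone contributes 0.
    under ("global") = mean grains per cohort over all defined rows x mean
            per-column crossing count of the whole view.
    """
    if under_strategy not in ("zonal", "global"):
        raise ValueError("under_strategy must be 'zonal' or 'global'")
    if not grains or len(gpc.rows) == 0:
        return ViewGrainEstimate(over=0.0, under=0.0)
    basal, median, apical = gpc.zone_slices()
    total = cohort_count_profile(grains, mask_width)

    med_est = gpc.estimate[median]
    med_mean = float(np.nanmean(med_est)) if np.any(np.isfinite(med_est)) else 0.0
    over = med_mean * total.max_count

    if under_strategy == "global":
        all_est = gpc.estimate
        g_mean = float(np.nanmean(all_est)) if np.any(np.isfinite(all_est)) else 0.0
        hit = total.per_column > 0
        mean_cross = float(total.per_column[hit].mean()) if np.any(hit) else 0.0
        under = g_mean * mean_cross
    else:
        under = 0.0
        for zone in (basal, median, apical):
            zrows = gpc.rows[zone]
            if len(zrows) == 0:
                continue
            zest = gpc.estimate[zone]
            if not np.any(np.isfinite(zest)):
                continue
            rng = (int(zrows.min()), int(zrows.max()))
            under += float(np.nanmean(zest)) * _zone_mean_crossings(
                grains, mask_width, rng
            )
    return ViewGrainEstimate(over=over, under=under)


def grain_number_per_ear(view_estimates: list[ViewGrainEstimate]) -> float:
    """Per-ear grain number: mean over views of (over + under) / 2."""
    if not view_estimates:
        return 0.0
    return float(np.mean([v.value for v in view_estimates]))
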