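"""Grain-set-ratio profile and fertile/aborted zone segmentation.

Per one-pixel ear section the grain set ratio (GSR) is the fraction of the
ear's visible width occupied by grain pixels — a proxy for set versus
aborted ovaries.  The raw profile is smoothed by a running average over 2%
of the ear's vertical pixels, and the ear is split into a single fertile
zone (the envelope from the first to the last section whose smoothed GSR
exceeds 50%) flanked by basal and apical aborted zones.  When no section
exceeds the threshold the fertile length is 0 and each aborted zone takes
half the ear length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["GSRProfile", "ZoneSummary", "gsr_profile", "smooth_gsr",
           "segment_zones"]


@dataclass
class GSRProfile:
    """Grain set ratio per ear row, ordered bottom -> top."""

    rows: np.ndarray              # raster row indices, bottom first
    raw: np.ndarray               # ratios in [0, 1]
    smoothed: np.ndarray | None = None
    window: int | None = None     # smoothing window, rows

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def values(self) -> np.ndarray:
        """Smoothed profile if available, else raw."""
        return self.raw if self.smoothed is None else self.smoothed


@dataclass
class ZoneSummary:
    """Fertile and aborted zone lengths; the three partition the ear length."""

    fertile_length: float
    basal_aborted_length: float
    apical_aborted_length: float
    fertile_row_bounds: tuple[int, int] | None   # raster rows (bottom, top)


def gsr_profile(ear_mask: np.ndarray, grain_label_mask: np.ndarray) -> GSRProfile:
    """Raw GSR per ear row: grain pixels / ear diameter pixels.

    Grain pixels outside the ear mask are still counted but signal a
    registration fault, reported as a warning.
    """
    mask = np.asarray(ear_mask, dtype=bool)
    labels = np.asarray(grain_label_mask)
    if mask.shape != labels.shape:
        raise ValueError("ear mask and grain mask shapes differ")
    grain = labels > 0
    if np.any(grain & ~mask):
        warnings.warn("grain pixels outside the ear mask: registration fault?",
                      stacklevel=2)
    any_fg = mask.any(axis=1)
    rows = np.flatnonzero(any_fg)[::-1]                  # bottom -> top
    if rows.size == 0:
        return GSRProfile(rows=rows, raw=np.empty(0))
    left = np.argmax(mask[rows], axis=1)
    right = mask.shape[1] - 1 - np.argmax(mask[rows, ::-1], axis=1)
    widths = (right - left + 1).astype(float)
    grain_counts = grain[rows].sum(axis=1).astype(float)
    return GSRProfile(rows=rows, raw=np.clip(grain_counts / widths, 0.0, 1.0))


def smooth_gsr(profile: GSRProfile, fraction: float = 0.02) -> GSRProfile:
    """Centred running average over ``fraction`` of the ear's rows.

    The window is ``max(1, round(fraction * n_rows))`` and is truncated
    (renormalized, not reflected) at the profile ends, so no data beyond
    the ear is invented.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    n = len(profile.raw)
    if n == 0:
        return GSRProfile(rows=profile.rows, raw=profile.raw,
                          smoothed=profile.raw.copy(), window=1)
    window = max(1, int(round(fraction * n)))
    if window == 1:
        return GSRProfile(rows=profile.rows, raw=profile.raw,
                          smoothed=profile.raw.copy(), window=1)
    lo, hi = (window - 1) // 2, window // 2      # centred: [i - lo, i + hi]
    csum = np.concatenate(([0.0], np.cumsum(profile.raw)))
    idx = np.arange(n)
    a = np.maximum(idx - lo, 0)
    b = np.minimum(idx + hi, n - 1)
    smoothed = (csum[b + 1] - csum[a]) / (b - a + 1)
    return GSRProfile(rows=profile.rows, raw=profile.raw, smoothed=smoothed,
                      window=window)


def segment_zones(profile: GSRProfile, ear_length_cm: float,
                  threshold: float = 0.5) -> ZoneSummary:
    """Split the ear into fertile / basal aborted / apical aborted zones.

    The fertile zone is the envelope from the first to the last row whose
    smoothed GSR is strictly greater than the threshold (interior dips
    stay inside it).  Zone lengths are row fractions of ``ear_length_cm``,
    so the three lengths partition the ear length exactly.  When no row
    exceeds the threshold, the fertile length is 0 and each aborted zone
    is half the ear length.
    """
    values = profile.values
    n = len(values)
    above = np.flatnonzero(values > threshold) if n else np.empty(0, int)
    if above.size == 0:
        half = ear_length_cm / 2.0
        return ZoneSummary(fertile_length=0.0, basal_aborted_length=half,
                           apical_aborted_length=half, fertile_row_bounds=None)
    i0, i1 = int(above[0]), int(above[-1])       # bottom -> top indices
    basal = (i0 / n) * ear_length_cm
    fertile = ((i1 - i0 + 1) / n) * ear_length_cm
    apical = ((n - 1 - i1) / n) * ear_length_cm
    bounds = (int(profile.rows[i0]), int(profile.rows[i1]))
    return ZoneSummary(fertile_length=fertile, basal_aborted_length=basal,
                       apical_aborted_length=apical, fertile_row_bounds=bounds)
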