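"""Pipeline orchestration: per-view measurement, per-ear aggregation, run I/O.

``run_traits`` walks a directory of per-ear view masks, runs the full
measurement chain per view (morphometry -> grains -> cohorts -> crossing
profiles -> GSR -> zones), averages across the views of each ear, and
writes a per-ear traits table plus per-view profile CSVs.  Everything is
deterministic under a fixed configuration, so reruns are byte-identical.

Coordinate convention throughout: raster row 0 is the image top, the ear
base is at the maximum row, and all profiles are reported bottom -> top.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abortion, clustering, grains as grains_mod, morphometry, topology
from .io import read_ear_directory, write_traits

__all__ = ["RunConfig", "EarTraits", "ViewResult", "process_view", "process_ear",
           "run_traits"]

logger = logging.getLogger("earbox")


@dataclass
class RunConfig:
    """Tunable parameters of a measurement run."""

    input_dir: str = "."
    output_dir: str = "earbox_out"
    pixel_scale: float | None = None     # px/cm; None = read per-ear metadata
    smoothing_fraction: float = 0.02     # running-average window, ear fraction
    gsr_threshold: float = 0.5           # fertile-zone threshold
    cohort_window_factor: float = 0.5    # x mean grain width
    capture_arc: float = 120.0           # reliably captured arc per view, deg
    under_strategy: str = "zonal"        # grain-number under-estimator
    clustering_method: str = "ward"
    clustering_k: int = 5
    n_profile_points: int = 100
    seed: int = 0
    write_profiles: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.smoothing_fraction <= 0.5):
            raise ValueError("smoothing_fraction must lie in (0, 0.5]")
        if not (0 <= self.gsr_threshold < 1):
            raise ValueError("gsr_threshold must lie in [0, 1)")
        if self.cohort_window_factor <= 0:
            raise ValueError("cohort_window_factor must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class ViewResult:
    """All measurements of one view."""

    view_index: int
    ear_length_cm: float
    max_diameter_cm: float
    cohort_count: int
    gpc_zone_means: tuple[float, float, float]
    grain_estimate: topology.ViewGrainEstimate
    n_grains_detected: int
    gsr: abortion.GSRProfile
    zones: abortion.ZoneSummary
    normalized_profile: np.ndarray
    grains: list


@dataclass
class EarTraits:
    """Per-ear aggregation over views (means unless noted)."""

    ear_id: str
    n_views: int
    ear_length_cm: float
    max_diameter_cm: float
    n_cohorts: float                  # mean over views of per-view maxima
    grains_per_cohort_basal: float
    grains_per_cohort_median: float
    grains_per_cohort_apical: float
    grain_number: float
    fertile_length_cm: float
    basal_aborted_length_cm: float
    apical_aborted_length_cm: float

    def as_row(self) -> dict:
        return asdict(self)


def process_view(ear_mask: np.ndarray, grain_labels: np.ndarray,
                 pixel_scale: float, config: RunConfig | None = None,
                 view_index: int = 0) -> ViewResult:
    """Run the whole measurement chain on one co-registered view."""
    cfg = config or RunConfig()
    axis = morphometry.central_axis(ear_mask)
    diam = morphometry.diameter_profile(ear_mask, pixel_scale)
    length = morphometry.ear_length(axis, pixel_scale)

    grain_list = grains_mod.extract_grains(grain_labels, view_index=view_index)
    for g in grain_list:
        grains_mod.grain_dimensions(g, axis, diam, pixel_scale)
    topology.assign_cohorts(grain_list, window_factor=cfg.cohort_window_factor)

    width = ear_mask.shape[1]
    crossings = topology.cohort_count_profile(grain_list, width)
    gpc = topology.grains_per_cohort_profile(grain_list, axis, diam,
                                             capture_arc=cfg.capture_arc)
    zone_means = []
    for sl in gpc.zone_slices():
        vals = gpc.estimate[sl]
        zone_means.append(float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else 0.0)
    estimate = topology.view_grain_estimate(grain_list, gpc, width,
                                            under_strategy=cfg.under_strategy)

    gsr = abortion.smooth_gsr(abortion.gsr_profile(ear_mask, grain_labels),
                              fraction=cfg.smoothing_fraction)
    zones = abortion.segment_zones(gsr, length, threshold=cfg.gsr_threshold)
    norm = clustering.normalize_profile(gsr, length, n_points=cfg.n_profile_points)

    return ViewResult(
        view_index=view_index,
        ear_length_cm=length,
        max_diameter_cm=diam.max_diameter_cm,
        cohort_count=crossings.max_count,
        gpc_zone_means=tuple(zone_means),  # type: ignore[arg-type]
        grain_estimate=estimate,
        n_grains_detected=len(grain_list),
        gsr=gsr,
        zones=zones,
        normalized_profile=norm,
        grains=grain_list,
    )


def process_ear(ear_id: str, views: list[dict], pixel_scale: float,
                config: RunConfig | None = None) -> tuple[EarTraits, list[ViewResult]]:
    """Measure every view of one ear and aggregate to ear-scale traits."""
    cfg = config or RunConfig()
    results = [
        process_view(v["ear_mask"], v["grain_labels"], pixel_scale, cfg,
                     view_index=v.get("view_index", i))
        for i, v in enumerate(views)
    ]
    zone_means = np.array([r.gpc_zone_means for r in results])
    traits = EarTraits(
        ear_id=ear_id,
        n_views=len(results),
        ear_length_cm=float(np.mean([r.ear_length_cm for r in results])),
        max_diameter_cm=float(np.mean([r.max_diameter_cm for r in results])),
        n_cohorts=float(np.mean([r.cohort_count for r in results])),
        grains_per_cohort_basal=float(zone_means[:, 0].mean()),
        grains_per_cohort_median=float(zone_means[:, 1].mean()),
        grains_per_cohort_apical=float(zone_means[:, 2].mean()),
        grain_number=topology.grain_number_per_ear(
            [r.grain_estimate for r in results]
        ),
        fertile_length_cm=float(np.mean([r.zones.fertile_length for r in results])),
        basal_aborted_length_cm=float(
            np.mean([r.zones.basal_aborted_length for r in results])
        ),
        apical_aborted_length_cm=float(
            np.mean([r.zones.apical_aborted_length for r in results])
        ),
    )
    return traits, results


def run_traits(config: RunConfig) -> pd.DataFrame:
    """Process every per-ear directory under ``config.input_dir``.

    Ears missing view files are skipped with a logged reason; mismatched
    raster sizes within an ear are a hard error.  Writes ``traits.csv``,
    per-view profile CSVs and a run manifest (config echo) to
    ``config.output_dir`` and returns the traits table.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    processed: list[str] = []
    skipped: list[dict] = []
    ear_dirs = sorted(p for p in in_dir.iterdir() if p.is_dir()) if in_dir.is_dir() else []
    for ear_dir in ear_dirs:
        try:
            ear_id, scale, views = read_ear_directory(ear_dir)
        except FileNotFoundError as exc:
            logger.warning("skipping %s: %s", ear_dir.name, exc)
            skipped.append({"ear": ear_dir.name, "reason": str(exc)})
            continue
        scale = config.pixel_scale if config.pixel_scale is not None else scale
        traits, results = process_ear(ear_id, views, scale, config)
        rows.append(traits.as_row())
        processed.append(ear_id)
        if config.write_profiles:
            prof_dir = out_dir / "profiles"
            prof_dir.mkdir(exist_ok=True)
            for r in results:
                pd.DataFrame({
                    "row": r.gsr.rows,
                    "gsr_raw": r.gsr.raw,
                    "gsr_smoothed": r.gsr.smoothed,
                }).to_csv(prof_dir / f"{ear_id}_view{r.view_index:02d}_gsr.csv",
                          index=False, float_format="%.6g")
            norm = np.vstack([r.normalized_profile for r in results]).mean(axis=0)
            pd.DataFrame({
                "relative_position": np.linspace(0, 1, len(norm)),
                "gsr": norm,
            }).to_csv(prof_dir / f"{ear_id}_normalized_gsr.csv",
                      index=False, float_format="%.6g")

    table = pd.DataFrame(rows)
    write_traits(table, out_dir / "traits.csv")
    manifest = {
        "config": asdict(config),
        "n_ears": len(rows),
        "ears": processed,
        "skipped": skipped,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    if not rows:
        logger.warning("no ears processed from %s", in_dir)
    return table
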