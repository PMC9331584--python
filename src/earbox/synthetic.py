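"""Parametric generator of synthetic multi-view maize ears with ground truth.

The model is a cylinder-lattice idealization of a maize ear: grains sit on a
vertical cylinder (optionally tapered, barrelled or bowed) at ``n_cohorts``
heights (rings) x ``grains_per_cohort`` angular positions (vertical files).
Cohorts are initiated bottom (oldest) to apex (youngest); under stress,
abortion removes grains starting at the apex, then the base, with a soft
logistic edge in the per-cohort set probability.  Each of the ``n_views``
images is a 2D orthographic render of the grains within a fixed angular
window around the view direction: a grain at angular distance ``dtheta``
from the view axis appears at horizontal offset ``R*sin(dtheta)`` from the
centreline with its width foreshortened by ``cos(dtheta)`` — exactly the
cylindrical-projection model the arc correction inverts.

Every generated ear carries exhaustive ground truth (per-grain lattice
coordinates and set flags, true length, diameter and grain-set-ratio
profiles, zone extents), so the whole measurement pipeline is testable
without real images.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AcquisitionPlan, ear_rotation_step

__all__ = [
    "SyntheticEarSpec",
    "EarGroundTruth",
    "ViewRender",
    "EarImageSet",
    "generate_ear",
    "archetype_spec",
    "ARCHETYPE_IDS",
]

DIAMETER_SHAPES = ("cylinder", "tapered", "barrel")
ABORTION_MODELS = ("none", "apical", "apical_basal", "full", "scattered")
ARCHETYPE_IDS = (1, 2, 3, 4, 5)

#: a logistic crosses from 10% to 90% over ~4.394 scale units
_LOGISTIC_10_90 = 2.0 * np.log(9.0)

_RENDER_MARGIN_PX = 4
_COB_GRAY = 60
_GRAIN_IR = 220
_COB_RGB = (150, 90, 60)
_GRAIN_RGB = (235, 205, 70)


@dataclass(frozen=True)
class SyntheticEarSpec:
    """Parameters of one synthetic ear.

    All dimensions are in cm; ``pixel_scale`` is px per cm.  ``curvature``
    is the amplitude of a sinusoidal bow of the centreline.  Abortion
    fractions are fractions of ear length aborted at apex/base;
    ``set_probability`` is the per-grain Bernoulli set probability of the
    scattered (pollination-failure) model; ``transition_cohorts`` is the
    10-90% span, in cohorts, of the logistic abortion edge.
    """

    ear_length: float = 12.0
    max_diameter: float = 4.0
    diameter_profile_shape: str = "cylinder"
    n_cohorts: int = 24
    grains_per_cohort: int = 14
    grain_height: float = 0.46
    grain_width: float = 0.85
    abortion_model: str = "none"
    apical_fraction: float = 0.30
    basal_fraction: float = 0.10
    set_probability: float = 0.5
    transition_cohorts: float = 2.0
    pixel_scale: float = 40.0
    curvature: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ear_length", "max_diameter", "grain_height", "grain_width",
                     "pixel_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cohorts < 1 or self.grains_per_cohort < 1:
            raise ValueError("n_cohorts and grains_per_cohort must be >= 1")
        if self.diameter_profile_shape not in DIAMETER_SHAPES:
            raise ValueError(f"diameter_profile_shape must be one of {DIAMETER_SHAPES}")
        if self.abortion_model not in ABORTION_MODELS:
            raise ValueError(f"abortion_model must be one of {ABORTION_MODELS}")
        for name in ("apical_fraction", "basal_fraction", "set_probability"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.apical_fraction + self.basal_fraction > 1.0:
            raise ValueError("apical_fraction + basal_fraction must be <= 1")
        if self.n_cohorts * self.grain_height > self.ear_length:
            raise ValueError(
                "lattice does not fit: n_cohorts * grain_height exceeds ear_length"
            )

    # --- derived lattice geometry -------------------------------------

    @property
    def cohort_pitch(self) -> float:
        """Vertical spacing between cohort centres, cm."""
        return self.ear_length / self.n_cohorts

    def cohort_heights(self) -> np.ndarray:
        """Centre height of each cohort, bottom to top, cm."""
        return (np.arange(self.n_cohorts) + 0.5) * self.cohort_pitch

    def grain_angles(self) -> np.ndarray:
        """Angular position (radians) of each vertical file; files are
        aligned across cohorts, as grain rows are on a real ear."""
        return 2.0 * np.pi * np.arange(self.grains_per_cohort) / self.grains_per_cohort

    def diameter_at(self, z) -> np.ndarray:
        """Silhouette diameter (cm) at height ``z`` (cm from ear base)."""
        t = np.clip(np.asarray(z, dtype=float) / self.ear_length, 0.0, 1.0)
        d = self.max_diameter
        if self.diameter_profile_shape == "cylinder":
            out = np.full_like(t, d)
        elif self.diameter_profile_shape == "tapered":
            out = d * (1.0 - 0.35 * t)
        else:  # barrel
            out = d * (0.75 + 0.25 * np.sin(np.pi * t))
        return out

    def bow_at(self, z) -> np.ndarray:
        """Horizontal centreline displacement (cm) at height ``z``."""
        z = np.asarray(z, dtype=float)
        return self.curvature * np.sin(np.pi * z / self.ear_length)

    def centreline_length(self, n: int = 4001) -> float:
        """Arc length (cm) of the bowed centreline — the true ear length."""
        z = np.linspace(0.0, self.ear_length, n)
        dxdz = (self.curvature * np.pi / self.ear_length) * np.cos(
            np.pi * z / self.ear_length
        )
        return float(np.trapezoid(np.sqrt(1.0 + dxdz**2), z))

    def replace(self, **changes) -> "SyntheticEarSpec":
        return dataclasses.replace(self, **changes)


@dataclass
class ViewRender:
    """One rendered side of an ear."""

    view_index: int
    rotation_deg: float
    ear_mask: np.ndarray          # bool (H, W)
    grain_labels: np.ndarray      # uint16 (H, W), 0 = background
    rgb: np.ndarray | None = None  # uint8 (H, W, 3)
    ir: np.ndarray | None = None   # uint8 (H, W)
    visible_grain_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))


@dataclass
class EarImageSet:
    """All views of one ear plus the shared raster metadata."""

    ear_id: str
    views: list[ViewRender]
    pixel_scale: float


@dataclass
class EarGroundTruth:
    """Known answers for one generated ear.

    Profile arrays are indexed by raster row, ordered bottom -> top, with
    ``row_indices`` giving the corresponding (descending) raster rows —
    the same convention the measurement modules use.
    """

    grains: pd.DataFrame            # grain_id, cohort, file_index, theta_deg, z_cm, is_set
    ear_length: float               # centreline arc length, cm
    vertical_extent: float          # cm
    max_diameter: float             # cm
    n_cohorts: int
    grains_per_cohort: int
    total_set_grains: int
    set_per_zone: tuple[int, int, int]   # basal/median/apical thirds by height
    fertile_length: float
    basal_aborted_length: float
    apical_aborted_length: float
    row_indices: np.ndarray         # raster rows, bottom -> top
    diameter_profile: np.ndarray    # cm per row
    gsr_profile: np.ndarray         # true grain set ratio per row
    pixel_scale: float


def _cohort_set_probability(spec: SyntheticEarSpec) -> np.ndarray:
    """Set probability per cohort under the apical/basal logistic model."""
    z = spec.cohort_heights()
    scale = max(spec.transition_cohorts * spec.cohort_pitch / _LOGISTIC_10_90, 1e-9)
    p = np.ones(spec.n_cohorts)
    if spec.abortion_model == "full":
        return np.zeros(spec.n_cohorts)
    if spec.abortion_model in ("apical", "apical_basal"):
        z_apex = spec.ear_length * (1.0 - spec.apical_fraction)
        p = p / (1.0 + np.exp((z - z_apex) / scale))
    if spec.abortion_model == "apical_basal":
        z_base = spec.ear_length * spec.basal_fraction
        p = p / (1.0 + np.exp((z_base - z) / scale))
    return p


def _draw_set_flags(spec: SyntheticEarSpec, rng: np.random.Generator) -> np.ndarray:
    """Set/aborted flags, shape (n_cohorts, grains_per_cohort).

    For the graded (non-scattered) models the number set per cohort is the
    rounded expectation ``round(K * p)``, placed evenly around the ring at
    a random rotation: the planted fertile boundary is then well defined
    even for a single ear, and every view sees a representative share of a
    partially aborted cohort.  The scattered (pollination-failure) model
    is i.i.d. Bernoulli per grain.
    """
    n, k = spec.n_cohorts, spec.grains_per_cohort
    if spec.abortion_model == "scattered":
        return rng.random((n, k)) < spec.set_probability
    p = _cohort_set_probability(spec)
    flags = np.zeros((n, k), dtype=bool)
    for c in range(n):
        n_set = int(round(k * p[c]))
        if n_set > 0:
            start = int(rng.integers(k))
            files = (start + np.floor(np.arange(n_set) * k / n_set).astype(int)) % k
            flags[c, files] = True
    return flags


def _true_zone_lengths(spec: SyntheticEarSpec) -> tuple[float, float, float]:
    """(fertile, basal aborted, apical aborted) lengths implied by the spec."""
    length = spec.ear_length
    model = spec.abortion_model
    if model == "none":
        return length, 0.0, 0.0
    if model == "full":
        return 0.0, length / 2.0, length / 2.0
    if model == "scattered":
        if spec.set_probability > 0.5:
            return length, 0.0, 0.0
        return 0.0, length / 2.0, length / 2.0
    basal = length * spec.basal_fraction if model == "apical_basal" else 0.0
    apical = length * spec.apical_fraction
    return length - basal - apical, basal, apical


def _wrap_deg(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


def generate_ear(
    spec: SyntheticEarSpec,
    plan: AcquisitionPlan | None = None,
    ear_id: str = "ear",
    render_pseudo: bool = True,
    render_arc: float = 180.0,
) -> tuple[EarImageSet, EarGroundTruth]:
    """Render one synthetic ear as multi-view masks with ground truth.

    Fully deterministic for a fixed ``spec`` (the seed lives in the spec).
    Grain rasters are instance label masks (uint16, one positive label per
    grain, background 0); labels equal the global grain id so a grain can
    be matched across views and against the ground-truth table.

    ``render_arc`` is the arc of circumference rendered per view.  The
    default (180 deg) draws every grain on the camera-facing hemisphere,
    as an orthographic photograph would; a grain at angular distance
    ``dtheta`` from the view axis spans the exact projected chord of its
    wrapped arc, ``[R*sin(dtheta - w/2R), R*sin(dtheta + w/2R)]``, so the
    arc correction inverts the rendering exactly.  ``plan.view_arc``
    remains the *reliably captured* arc of the acquisition-coverage model
    and is narrower than what the image shows, as on a real photograph.
    """
    if plan is None:
        plan = AcquisitionPlan()
    if not (0 < render_arc <= 360):
        raise ValueError("render_arc must lie in (0, 360]")
    rng = np.random.default_rng(spec.seed)

    n, k = spec.n_cohorts, spec.grains_per_cohort
    s = spec.pixel_scale
    length = spec.ear_length
    z_cohort = spec.cohort_heights()
    theta = spec.grain_angles()
    flags = _draw_set_flags(spec, rng)
    # per-grain colour jitter drawn up front so it is view-order independent
    jitter = rng.integers(-25, 26, size=(n * k, 3))

    # ---- ground-truth table -----------------------------------------
    cohort_idx = np.repeat(np.arange(n), k)
    file_idx = np.tile(np.arange(k), n)
    grains = pd.DataFrame(
        {
            "grain_id": np.arange(1, n * k + 1, dtype=int),
            "cohort": cohort_idx + 1,
            "file_index": file_idx,
            "theta_deg": np.degrees(theta[file_idx]),
            "z_cm": z_cohort[cohort_idx],
            "is_set": flags.ravel(),
        }
    )

    # ---- raster frame ------------------------------------------------
    margin = _RENDER_MARGIN_PX
    half_w_cm = spec.max_diameter / 2.0 + abs(spec.curvature)
    height = int(np.ceil(length * s)) + 2 * margin + 1
    width = int(np.ceil(2.0 * half_w_cm * s)) + 2 * margin + 1
    cx0 = width / 2.0
    row_bottom = margin + length * s          # raster row of z = 0 (float)

    def row_of(z):
        return row_bottom - np.asarray(z, dtype=float) * s

    rows = np.arange(height)
    z_rows = (row_bottom - rows) / s
    on_ear = (z_rows >= 0.0) & (z_rows <= length)
    ear_rows = rows[on_ear]
    d_rows = spec.diameter_at(z_rows[on_ear])
    cx_rows = cx0 + spec.bow_at(z_rows[on_ear]) * s

    ear_mask = np.zeros((height, width), dtype=bool)
    for r, d, cx in zip(ear_rows, d_rows, cx_rows):
        c0 = int(round(cx - d * s / 2.0))
        c1 = int(round(cx + d * s / 2.0))
        ear_mask[r, max(c0, 0): min(c1, width - 1) + 1] = True

    # ---- per-view grain rendering ------------------------------------
    step = ear_rotation_step(plan, spec.max_diameter)
    pitch_px = spec.cohort_pitch * s
    ay_px = min(spec.grain_height * s / 2.0, (pitch_px - 1.0) / 2.0)
    set_ids = grains.loc[grains["is_set"], "grain_id"].to_numpy()

    views: list[ViewRender] = []
    shrink_warned = False
    for v in range(plan.n_views):
        phi = v * step
        labels = np.zeros((height, width), dtype=np.uint16)
        visible: list[int] = []
        for c in range(n):
            set_files = np.flatnonzero(flags[c])
            if set_files.size == 0:
                continue
            dtheta = np.radians(_wrap_deg(np.degrees(theta[set_files]) - phi))
            vis = np.abs(np.degrees(dtheta)) < render_arc / 2.0
            if not np.any(vis):
                continue
            radius = float(spec.diameter_at(z_cohort[c])) / 2.0
            dt = dtheta[vis]
            ids = (c * k + set_files[vis] + 1).astype(int)
            # exact projected chord of the wrapped grain arc [dt-hw, dt+hw]
            half_arc = (spec.grain_width / 2.0) / radius
            th1 = np.clip(dt - half_arc, -np.pi / 2.0, np.pi / 2.0)
            th2 = np.clip(dt + half_arc, -np.pi / 2.0, np.pi / 2.0)
            edge1 = radius * np.sin(th1)
            edge2 = radius * np.sin(th2)
            cx_c = cx0 + float(spec.bow_at(z_cohort[c])) * s
            x_px = cx_c + (edge1 + edge2) / 2.0 * s
            ax_px = (edge2 - edge1) / 2.0 * s
            # enforce a 1-px gap between neighbouring grains of a cohort
            order = np.argsort(x_px)
            x_px, ax_px, dt, ids = x_px[order], ax_px[order], dt[order], ids[order]
            for i in range(len(x_px) - 1):
                avail = x_px[i + 1] - x_px[i] - 1.0
                need = ax_px[i] + ax_px[i + 1]
                if need > avail and need > 0:
                    # genuine overlap (not mere pixel rounding at the limb)
                    # means the spec grain width exceeds the arc pitch
                    if need > avail + 1.0 and not shrink_warned:
                        warnings.warn(
                            f"{ear_id}: foreshortened grains overlap; "
                            "shrinking ellipse minor axes to keep a 1-px gap",
                            stacklevel=2,
                        )
                        shrink_warned = True
                    scale = max(avail, 0.5) / need
                    ax_px[i] *= scale
                    ax_px[i + 1] *= scale
            y0 = float(row_of(z_cohort[c]))
            for gid, x0, ax in zip(ids, x_px, ax_px):
                ax = max(ax, 0.6)
                r0, r1 = int(np.floor(y0 - ay_px)), int(np.ceil(y0 + ay_px))
                c0_, c1_ = int(np.floor(x0 - ax)), int(np.ceil(x0 + ax))
                r0, r1 = max(r0, 0), min(r1, height - 1)
                c0_, c1_ = max(c0_, 0), min(c1_, width - 1)
                rr, cc = np.mgrid[r0: r1 + 1, c0_: c1_ + 1]
                inside = (((rr - y0) / ay_px) ** 2 + ((cc - x0) / ax) ** 2) <= 1.0
                inside &= ear_mask[r0: r1 + 1, c0_: c1_ + 1]
                patch = labels[r0: r1 + 1, c0_: c1_ + 1]
                patch[inside & (patch == 0)] = gid
                if np.any(inside):
                    visible.append(int(gid))

        rgb = ir = None
        if render_pseudo:
            ir = np.zeros((height, width), dtype=np.uint8)
            ir[ear_mask] = _COB_GRAY
            ir[labels > 0] = _GRAIN_IR
            rgb = np.zeros((height, width, 3), dtype=np.uint8)
            rgb[ear_mask] = _COB_RGB
            for gid in visible:
                colour = np.clip(np.array(_GRAIN_RGB) + jitter[gid - 1], 0, 255)
                rgb[labels == gid] = colour.astype(np.uint8)

        views.append(
            ViewRender(
                view_index=v,
                rotation_deg=float(phi),
                ear_mask=ear_mask.copy(),
                grain_labels=labels,
                rgb=rgb,
                ir=ir,
                visible_grain_ids=np.array(sorted(visible), dtype=int),
            )
        )

    # ---- ground-truth profiles ---------------------------------------
    order = np.argsort(-ear_rows)                  # bottom -> top
    rows_bt = ear_rows[order]
    z_bt = z_rows[on_ear][order]
    d_bt = d_rows[order]
    n_set_per_cohort = flags.sum(axis=1)
    gsr_true = np.zeros_like(z_bt)
    half_h = spec.grain_height / 2.0
    for c in range(n):
        dz = z_bt - z_cohort[c]
        band = np.abs(dz) < half_h
        if not np.any(band) or n_set_per_cohort[c] == 0:
            continue
        w_z = spec.grain_width * np.sqrt(1.0 - (dz[band] / half_h) ** 2)
        gsr_true[band] += n_set_per_cohort[c] * w_z / (np.pi * d_bt[band])
    gsr_true = np.clip(gsr_true, 0.0, 1.0)

    thirds = np.clip((3 * grains["z_cm"].to_numpy() / length).astype(int), 0, 2)
    set_per_zone = tuple(
        int(np.sum(flags.ravel() & (thirds == zone))) for zone in range(3)
    )
    fertile, basal, apical = _true_zone_lengths(spec)

    truth = EarGroundTruth(
        grains=grains,
        ear_length=spec.centreline_length(),
        vertical_extent=length,
        max_diameter=float(np.max(d_rows)),
        n_cohorts=n,
        grains_per_cohort=k,
        total_set_grains=int(flags.sum()),
        set_per_zone=set_per_zone,  # type: ignore[arg-type]
        fertile_length=fertile,
        basal_aborted_length=basal,
        apical_aborted_length=apical,
        row_indices=rows_bt,
        diameter_profile=d_bt,
        gsr_profile=gsr_true,
        pixel_scale=s,
    )
    return EarImageSet(ear_id=ear_id, views=views, pixel_scale=s), truth


def true_normalized_gsr(spec: SyntheticEarSpec, n_points: int = 100) -> np.ndarray:
    """Ground-truth cohort-envelope GSR on ``n_points`` relative positions.

    Computed directly from the lattice model (no rasters): per position,
    the angular-coverage fraction of set grains of the *nearest cohort*
    (inter-cohort gaps filled, as a smoothed profile would show), using
    the same set flags :func:`generate_ear` would draw for this spec/seed.
    The per-raster-row, band-resolved truth lives in
    :attr:`EarGroundTruth.gsr_profile`.
    """
    rng = np.random.default_rng(spec.seed)
    flags = _draw_set_flags(spec, rng)
    n_set = flags.sum(axis=1)
    z = np.linspace(0.0, spec.ear_length, n_points)
    d = spec.diameter_at(z)
    nearest = np.clip((z / spec.cohort_pitch).astype(int), 0, spec.n_cohorts - 1)
    gsr = n_set[nearest] * spec.grain_width / (np.pi * d)
    return np.clip(gsr, 0.0, 1.0)


def archetype_panel_specs(
    n_ears: int = 50,
    archetypes: tuple[int, ...] = (1, 2, 3, 4),
    seed: int = 0,
) -> list[tuple[SyntheticEarSpec, int]]:
    """A panel of varied ear specs cycling through abortion archetypes.

    Ears vary realistically in length (9-14 cm), diameter (3.4-4.6 cm) and
    grains per cohort (12-16); cohort pitch stays near 0.5 cm and grain
    dimensions are derived from the lattice so every spec fits (grains
    nearly touching, as on a densely set ear).  Deterministic for a fixed
    seed; each ear gets its own derived seed.
    """
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_ears):
        arch = archetypes[i % len(archetypes)]
        length = float(rng.uniform(9.0, 14.0))
        diameter = float(rng.uniform(3.4, 4.6))
        k = int(rng.integers(12, 17))
        n_cohorts = max(4, int(round(length / 0.5)))
        pitch = length / n_cohorts
        chord_pitch = diameter * np.sin(np.pi / k)
        base = SyntheticEarSpec(
            ear_length=length,
            max_diameter=diameter,
            n_cohorts=n_cohorts,
            grains_per_cohort=k,
            grain_height=round(0.9 * pitch, 3),
            grain_width=round(min(0.95 * chord_pitch, 0.95 * np.pi * diameter / k), 3),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        panel.append((archetype_spec(arch, base), arch))
    return panel


def archetype_spec(cluster_id: int, base: SyntheticEarSpec) -> SyntheticEarSpec:
    """Abortion archetype ``cluster_id`` in 1..5, from least to most aborted.

    1: no/limited abortion; 2: apical only; 3: apical plus basal onset;
    4: wide apical and basal aborted zones; 5: abortion over the entire
    vertical profile.  The true fertile fraction decreases monotonically
    with the archetype id (0.95, 0.70, 0.60, 0.35, 0).
    """
    if cluster_id not in ARCHETYPE_IDS:
        raise ValueError(f"cluster_id must be in {ARCHETYPE_IDS}")
    params = {
        1: dict(abortion_model="apical", apical_fraction=0.05, basal_fraction=0.0),
        2: dict(abortion_model="apical", apical_fraction=0.30, basal_fraction=0.0),
        3: dict(abortion_model="apical_basal", apical_fraction=0.30, basal_fraction=0.10),
        4: dict(abortion_model="apical_basal", apical_fraction=0.45, basal_fraction=0.20),
        5: dict(abortion_model="full"),
    }[cluster_id]
    return base.replace(**params)
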