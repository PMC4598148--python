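"""Seeded synthetic-cohort generator.

Produces, for every rabbit in a configured cohort: ground-truth segment labels,
rendered closed- and open-view fluorescence images (16-bit grayscale TIFF plus
ROI annotations), and an MRI-derived per-slice table of vessel areas and wall
intensities.  The generator emulates the *statistical* structure the analysis
assumes — per-segment fluorescence enhancement ratios, outward remodeling on a
linearly tapering vessel, contrast-enhanced wall intensities — not the optical
or MR physics.

Axial convention: millimetres from the left renal bifurcation, increasing
toward the iliac bifurcation.  Segment ``i`` covers the half-open interval
``[i*L, (i+1)*L)`` with ``L`` the segment length (default 4 mm); MRI slices sit
at the segment centres so the slice-to-segment map is a bijection.

Rendering convention: image rows are the transverse direction, columns the
axial direction; pixel (i, j) has its centre at continuous coordinate (i, j),
so a pixel spans ``[i-0.5, i+0.5] x [j-0.5, j+0.5]``.  ROIs are stored as
polygons over these coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from .config import TARGETED_PROBES, ArmConfig, CohortConfig, Probe, save_config

__all__ = [
    "Segment",
    "FluorescenceImage",
    "VesselSliceSeries",
    "Rabbit",
    "Cohort",
    "generate_cohort",
    "render_closed_view",
    "render_open_view",
    "simulate_mri_series",
    "write_cohort",
    "rect_polygon",
]

# ---------------------------------------------------------------------------
# Rendering constants (counts are arbitrary camera units; the analysis only
# ever uses ratios, so the absolute scale is irrelevant by construction).
# ---------------------------------------------------------------------------

PIXEL_PITCH_MM = 0.1  # mm per pixel
EXPOSURE_S = 1.0  # s
REFERENCE_INTENSITY = 1000.0  # counts at the femoral reference
BACKGROUND_INTENSITY = 100.0  # counts off-tissue
NOISE_FRACTION = 0.01  # additive Gaussian SD as a fraction of the reference

AORTA_ROWS = (20, 60)  # closed-view aortic strip (row_start, row_stop)
FEMORAL_ROWS = (80, 110)
FEMORAL_COLS = (5, 35)
IMAGE_ROWS = 130

# Open-view site layout (pixels): plaque patch, gap, detached thrombus patch.
OPEN_SITE_STRIDE = 90
OPEN_PLAQUE_COLS = 40
OPEN_THROMBUS_COLS = 30

# MRI table constants.
VESSEL_AREA_BASE_MM2 = 10.0  # VA at the renal bifurcation, lesion-free
VESSEL_TAPER_SLOPE = -0.03  # mm^2 per mm toward the iliac bifurcation
WALL_NC_INTENSITY = (1000.0, 100.0)  # (mean, sd) non-contrast wall intensity
LESION_FREE_FRACTION = 0.2  # fraction of non-disrupted slices held out
MIN_LESION_FREE = 2  # taper fit needs at least two points


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One 4 mm axial aortic slot with its ground truth and sampled targets."""

    rabbit_id: str
    index: int
    axial_start_mm: float
    disrupted: bool = False
    fer_target: float = np.nan  # closed-view FER the renderer aims for
    open_plaque_target: float = np.nan  # open-view plaque FER (disrupted only)
    rr_target: float = np.nan  # outward-remodeling multiplier on VA
    gdr_target: float = np.nan  # CE/NC wall-intensity ratio
    lesion_free: bool = False  # held out of remodeling, used for taper fit


@dataclass
class FluorescenceImage:
    """2-D intensity raster with pixel pitch, view, exposure and named ROIs."""

    pixels: np.ndarray  # float counts, finite and >= 0
    pixel_pitch_mm: float
    view: str  # "closed" | "open"
    exposure_s: float
    rois: dict[str, list[tuple[float, float]]]  # name -> polygon [(row, col)]
    axial_axis: int = 1  # columns are axial
    axial_origin_col: float = 0.0  # column edge coordinate of axial 0 mm

    def __post_init__(self) -> None:
        if "femoral_reference" not in self.rois:
            raise ValueError("every image must carry a femoral_reference ROI")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be finite and >= 0")


@dataclass
class VesselSliceSeries:
    """Per-MRI-slice vessel areas and wall intensities along one aorta."""

    rabbit_id: str
    axial_position_mm: np.ndarray
    vessel_area_mm2: np.ndarray
    wall_intensity_ce: np.ndarray
    wall_intensity_nc: np.ndarray
    lesion_free: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.axial_position_mm, float)
        if x.size and np.any(np.diff(x) <= 0):
            raise ValueError("slice positions must be strictly increasing")
        for name in ("vessel_area_mm2", "wall_intensity_ce", "wall_intensity_nc"):
            if np.any(np.asarray(getattr(self, name), float) <= 0):
                raise ValueError(f"{name} must be > 0")

    def __len__(self) -> int:
        return len(self.axial_position_mm)


@dataclass
class Rabbit:
    rabbit_id: str
    probe: Probe
    segments: list[Segment]
    closed_image: Optional[FluorescenceImage] = None
    open_image: Optional[FluorescenceImage] = None
    mri: Optional[VesselSliceSeries] = None


@dataclass
class Cohort:
    config: CohortConfig
    rabbits: list[Rabbit]

    @property
    def segments(self) -> list[Segment]:
        return [s for r in self.rabbits for s in r.segments]

    def segments_frame(self) -> pd.DataFrame:
        probe_of = {r.rabbit_id: r.probe.value for r in self.rabbits}
        return pd.DataFrame(
            {
                "rabbit_id": [s.rabbit_id for s in self.segments],
                "probe": [probe_of[s.rabbit_id] for s in self.segments],
                "segment_index": [s.index for s in self.segments],
                "axial_start_mm": [s.axial_start_mm for s in self.segments],
                "disrupted": [s.disrupted for s in self.segments],
            }
        )

    def mri_frame(self) -> pd.DataFrame:
        parts = []
        for r in self.rabbits:
            parts.append(
                pd.DataFrame(
                    {
                        "rabbit_id": r.rabbit_id,
                        "axial_position_mm": r.mri.axial_position_mm,
                        "va_mm2": r.mri.vessel_area_mm2,
                        "wall_ce": r.mri.wall_intensity_ce,
                        "wall_nc": r.mri.wall_intensity_nc,
                        "lesion_free": r.mri.lesion_free,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# RNG plumbing and sampling helpers
# ---------------------------------------------------------------------------


def _stable_hash32(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


def rabbit_rng(root_seed: int, rabbit_id: str) -> np.random.Generator:
    """Per-rabbit substream keyed by a stable hash of the rabbit id.

    Keying on the id (not the insertion order) means adding or reordering
    rabbits does not perturb the draws of the others.
    """
    return np.random.default_rng([int(root_seed), _stable_hash32(rabbit_id)])


def truncated_normal(
    rng: np.random.Generator, mean_sd: tuple[float, float], size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf); degenerate at sd = 0."""
    mean, sd = mean_sd
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def rect_polygon(
    row_start: int, row_stop: int, col_start: int, col_stop: int
) -> list[tuple[float, float]]:
    """Polygon covering exactly the pixels rows [row_start, row_stop) x
    cols [col_start, col_stop) under the pixel-centre rasterization rule."""
    r0, r1 = row_start - 0.5, row_stop - 0.5
    c0, c1 = col_start - 0.5, col_stop - 0.5
    return [(r0, c0), (r0, c1), (r1, c1), (r1, c0)]


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

_PROBE_PREFIX = {
    Probe.MMP_ACPP: "MMP",
    Probe.THROMBIN_ACPP: "THR",
    Probe.PEG_ACPP: "PEG",
}


def _segment_counts(config: CohortConfig) -> list[tuple[ArmConfig, str, int]]:
    """(arm, rabbit_id, n_segments) for every rabbit, trimming the last
    rabbit when replica mode prescribes an exact cohort total."""
    out: list[tuple[ArmConfig, str, int]] = []
    for arm in config.arms:
        prefix = _PROBE_PREFIX[arm.probe]
        for k in range(arm.n_rabbits):
            out.append((arm, f"{prefix}{k + 1:02d}", arm.segments_per_rabbit))
    if config.total_segments is not None:
        excess = sum(n for _, _, n in out) - config.total_segments
        if excess:
            arm, rid, n = out[-1]
            out[-1] = (arm, rid, n - excess)
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort: labels, images and MRI tables.

    Replica mode draws exactly ``config.n_disrupted`` disrupted segments
    uniformly among targeted-arm segments; probability mode flips an
    independent coin per segment.  Identical (config, seed) yields
    byte-identical output.
    """
    counts = _segment_counts(config)
    length = config.axial_segment_length_mm

    rabbits: list[Rabbit] = []
    for arm, rid, n_seg in counts:
        segs = [Segment(rid, i, i * length) for i in range(n_seg)]
        rabbits.append(Rabbit(rid, arm.probe, segs))

    arm_of = {r.rabbit_id: arm for (arm, rid, _), r in zip(counts, rabbits)}

    # --- ground-truth disruption labels -----------------------------------
    if config.replica_mode:
        pool = sorted(
            (
                s
                for r in rabbits
                if r.probe in TARGETED_PROBES
                for s in r.segments
            ),
            key=lambda s: (s.rabbit_id, s.index),
        )
        root = np.random.default_rng(config.seed)
        for idx in root.choice(len(pool), size=config.n_disrupted, replace=False):
            pool[idx].disrupted = True
    else:
        p = config.disruption_probability
        for r in rabbits:
            rng = rabbit_rng(config.seed, r.rabbit_id + "/labels")
            flips = rng.random(len(r.segments)) < p
            for s, f in zip(r.segments, flips):
                s.disrupted = bool(f)

    # --- per-rabbit quantitative targets, images and MRI table ------------
    for rabbit in rabbits:
        arm = arm_of[rabbit.rabbit_id]
        rng = rabbit_rng(config.seed, rabbit.rabbit_id)
        _sample_segment_targets(rabbit, arm, rng)
        rabbit.closed_image = render_closed_view(rabbit, arm, rng, length)
        rabbit.open_image = render_open_view(rabbit, arm, rng)
        rabbit.mri = simulate_mri_series(rabbit, arm, rng, config.mri_slice_pitch_mm)

    return Cohort(config, rabbits)


def _sample_segment_targets(
    rabbit: Rabbit, arm: ArmConfig, rng: np.random.Generator
) -> None:
    """Draw FER/RR/GdR targets per segment and designate lesion-free slots."""
    disrupted = [s for s in rabbit.segments if s.disrupted]
    stable = [s for s in rabbit.segments if not s.disrupted]

    for group, fer_ms, rr_ms, gdr_ms in (
        (disrupted, arm.fer_disrupted, arm.rr_disrupted, arm.gdr_disrupted),
        (stable, arm.fer_nondisrupted, arm.rr_nondisrupted, arm.gdr_nondisrupted),
    ):
        if not group:
            continue
        fer = truncated_normal(rng, fer_ms, len(group))
        rr = truncated_normal(rng, rr_ms, len(group))
        gdr = truncated_normal(rng, gdr_ms, len(group))
        for s, f, r_, g in zip(group, fer, rr, gdr):
            s.fer_target, s.rr_target, s.gdr_target = float(f), float(r_), float(g)

    if disrupted:
        targets = truncated_normal(rng, arm.fer_openview_plaque, len(disrupted))
        for s, t in zip(disrupted, targets):
            s.open_plaque_target = float(t)

    n_free = max(MIN_LESION_FREE, round(LESION_FREE_FRACTION * len(stable)))
    if len(stable) < MIN_LESION_FREE:
        raise ValueError(
            f"rabbit {rabbit.rabbit_id}: {len(stable)} non-disrupted segments; "
            f"at least {MIN_LESION_FREE} are needed as lesion-free taper anchors"
        )
    chosen = rng.choice(len(stable), size=min(n_free, len(stable)), replace=False)
    for idx in chosen:
        stable[idx].lesion_free = True
        stable[idx].rr_target = 1.0  # anchors carry no remodeling


# ---------------------------------------------------------------------------
# Fluorescence rendering
# ---------------------------------------------------------------------------


def _finish(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, NOISE_FRACTION * REFERENCE_INTENSITY, pixels.shape)
    return np.clip(pixels + noise, 0.0, None)


def render_closed_view(
    rabbit: Rabbit,
    arm: ArmConfig,
    rng: np.random.Generator,
    segment_length_mm: float = 4.0,
) -> FluorescenceImage:
    """Render the intact-aorta view: one axial strip, one segment per block.

    Each segment's plaque region is painted so its mean intensity equals
    (FER target x femoral reference intensity) before noise; the additive
    noise is 1% of the reference, so the quantified FER round-trips to well
    under 2% relative error.
    """
    n_seg = len(rabbit.segments)
    cols_per_seg = int(round(segment_length_mm / PIXEL_PITCH_MM))
    n_cols = max(n_seg * cols_per_seg, FEMORAL_COLS[1] + 5)
    img = np.full((IMAGE_ROWS, n_cols), BACKGROUND_INTENSITY)

    r0, r1 = AORTA_ROWS
    for s in rabbit.segments:
        c0 = s.index * cols_per_seg
        img[r0:r1, c0 : c0 + cols_per_seg] = s.fer_target * REFERENCE_INTENSITY
    fr0, fr1 = FEMORAL_ROWS
    fc0, fc1 = FEMORAL_COLS
    img[fr0:fr1, fc0:fc1] = REFERENCE_INTENSITY

    rois = {
        "aorta": rect_polygon(r0, r1, 0, n_seg * cols_per_seg),
        "femoral_reference": rect_polygon(fr0, fr1, fc0, fc1),
    }
    return FluorescenceImage(
        pixels=_finish(img, rng),
        pixel_pitch_mm=PIXEL_PITCH_MM,
        view="closed",
        exposure_s=EXPOSURE_S,
        rois=rois,
    )


def render_open_view(
    rabbit: Rabbit, arm: ArmConfig, rng: np.random.Generator
) -> FluorescenceImage:
    """Render the longitudinally opened aorta after thrombus detachment.

    One site per disrupted segment: an underlying-plaque patch painted at the
    open-view plaque FER target and, beside it, the detached thrombus painted
    at ``thrombus_to_plaque_signal_ratio`` times the plaque intensity.
    """
    sites = [s for s in rabbit.segments if s.disrupted]
    n_cols = max(len(sites) * OPEN_SITE_STRIDE, FEMORAL_COLS[1] + 5)
    img = np.full((IMAGE_ROWS, n_cols), BACKGROUND_INTENSITY)

    r0, r1 = AORTA_ROWS
    rois: dict[str, list[tuple[float, float]]] = {}
    for j, s in enumerate(sites):
        plaque_val = s.open_plaque_target * REFERENCE_INTENSITY
        pc0 = j * OPEN_SITE_STRIDE
        pc1 = pc0 + OPEN_PLAQUE_COLS
        tc0 = pc1 + 10
        tc1 = tc0 + OPEN_THROMBUS_COLS
        img[r0:r1, pc0:pc1] = plaque_val
        img[r0:r1, tc0:tc1] = arm.thrombus_to_plaque_signal_ratio * plaque_val
        rois[f"plaque_under_thrombus_{s.index}"] = rect_polygon(r0, r1, pc0, pc1)
        rois[f"thrombus_{s.index}"] = rect_polygon(r0, r1, tc0, tc1)

    fr0, fr1 = FEMORAL_ROWS
    fc0, fc1 = FEMORAL_COLS
    img[fr0:fr1, fc0:fc1] = REFERENCE_INTENSITY
    rois["femoral_reference"] = rect_polygon(fr0, fr1, fc0, fc1)

    return FluorescenceImage(
        pixels=_finish(img, rng),
        pixel_pitch_mm=PIXEL_PITCH_MM,
        view="open",
        exposure_s=EXPOSURE_S,
        rois=rois,
    )


# ---------------------------------------------------------------------------
# MRI table simulation
# ---------------------------------------------------------------------------


def simulate_mri_series(
    rabbit: Rabbit,
    arm: ArmConfig,
    rng: np.random.Generator,
    slice_pitch_mm: float = 4.0,
) -> VesselSliceSeries:
    """Simulate the per-slice vessel-area / wall-intensity table.

    Baseline vessel area tapers linearly along the aorta; each slice's VA is
    the baseline times its segment's remodeling multiplier (1 for lesion-free
    anchors).  CE and NC wall intensities are drawn so their ratio equals the
    segment's GdR target.  Slices sit at segment centres, one per segment.
    """
    segs = rabbit.segments
    x = np.array([s.axial_start_mm for s in segs]) + slice_pitch_mm / 2.0
    baseline = VESSEL_AREA_BASE_MM2 + VESSEL_TAPER_SLOPE * x
    if np.any(baseline <= 0):
        raise ValueError("vessel taper drives baseline area non-positive")
    rr = np.array([s.rr_target for s in segs])
    gdr = np.array([s.gdr_target for s in segs])
    wall_nc = truncated_normal(rng, WALL_NC_INTENSITY, len(segs))
    return VesselSliceSeries(
        rabbit_id=rabbit.rabbit_id,
        axial_position_mm=x,
        vessel_area_mm2=baseline * rr,
        wall_intensity_ce=wall_nc * gdr,
        wall_intensity_nc=wall_nc,
        lesion_free=np.array([s.lesion_free for s in segs]),
    )


# ---------------------------------------------------------------------------
# On-disk artifact writers (TIFF + ROI JSON + CSV + config echo)
# ---------------------------------------------------------------------------


def image_paths(out_dir: Path, rabbit_id: str, view: str) -> tuple[Path, Path]:
    base = Path(out_dir) / "images" / f"{rabbit_id}_{view}"
    return base.with_suffix(".tif"), base.with_suffix(".rois.json")


def write_image(image: FluorescenceImage, tif_path: Path, roi_path: Path) -> None:
    counts = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tif_path, counts)
    meta = {
        "pixel_pitch_mm": image.pixel_pitch_mm,
        "exposure_s": image.exposure_s,
        "view": image.view,
        "axial_axis": image.axial_axis,
        "axial_origin_col": image.axial_origin_col,
        "rois": {name: [list(v) for v in poly] for name, poly in image.rois.items()},
    }
    roi_path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write segments.csv, mri_slices.csv, per-rabbit TIFF/ROI pairs and a
    config echo under ``out_dir``; returns the directory."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for rabbit in cohort.rabbits:
        for view, image in (("closed", rabbit.closed_image), ("open", rabbit.open_image)):
            tif_path, roi_path = image_paths(out, rabbit.rabbit_id, view)
            write_image(image, tif_path, roi_path)
    cohort.segments_frame().to_csv(out / "segments.csv", index=False)
    cohort.mri_frame().to_csv(out / "mri_slices.csv", index=False)
    save_config(cohort.config, out / "config.yaml")
    return out
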