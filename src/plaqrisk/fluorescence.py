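"""Fluorescence quantification: per-segment FER and open-view contrasts.

The fluorescence enhancement ratio (FER) of an aortic segment is the mean
pixel intensity under the segment's ROI, exposure-normalized to counts/s,
divided by the same quantity over the non-atherosclerotic left femoral artery
of the same image.  Closed-view images are segmented into contiguous 4 mm
axial slots; open-view images carry manually traced (here: generated)
thrombus / underlying-plaque ROI pairs, one per disrupted site.

ROI rasterization: a pixel belongs to a polygon iff its centre lies inside
under the even-odd rule; pixel centres sit at integer (row, col) coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import FluorescenceImage, image_paths

__all__ = [
    "SegmentRoi",
    "FerRecord",
    "polygon_mask",
    "segment_axially",
    "mean_roi_signal",
    "compute_fer",
    "quantify_closed_image",
    "open_view_contrast",
    "load_image",
    "quantify_directory",
]

EPS_REFERENCE = 1e-9  # below this the femoral ROI is considered degenerate


@dataclass
class SegmentRoi:
    """Pixel mask of one axial segment slot on a closed-view image."""

    index: int
    axial_start_mm: float
    axial_stop_mm: float
    mask: np.ndarray  # boolean, image-shaped


@dataclass
class FerRecord:
    segment_index: int
    mean_signal: float  # counts/s under the segment ROI
    reference_signal: float  # counts/s under the femoral ROI
    fer: float


# ---------------------------------------------------------------------------
# ROI rasterization
# ---------------------------------------------------------------------------


def polygon_mask(shape: tuple[int, int], vertices) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon.

    Even-odd (crossing-number) rule; vertices are (row, col) in continuous
    pixel coordinates with centres at integers.  Vertices placed at
    half-integers therefore select whole pixels unambiguously.
    """
    verts = np.asarray(vertices, float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    inside = np.zeros(shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if r1 == r2:  # horizontal edge never crosses a horizontal ray
            continue
        spans = (r1 > rows) != (r2 > rows)
        # column where the edge crosses each pixel row (valid where spans)
        cross = c1 + (rows - r1) * (c2 - c1) / (r2 - r1)
        inside ^= spans & (cols < cross)
    return inside


def _roi_mask(image: FluorescenceImage, roi) -> np.ndarray:
    """Resolve an ROI given as a name, a polygon, or a boolean mask."""
    if isinstance(roi, str):
        if roi not in image.rois:
            raise KeyError(f"image has no ROI named {roi!r}")
        roi = image.rois[roi]
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != image.pixels.shape:
            raise ValueError("mask shape does not match image")
        return roi
    verts = np.asarray(roi, float)
    nrows, ncols = image.pixels.shape
    if (
        verts[:, 0].min() < -0.5
        or verts[:, 0].max() > nrows - 0.5
        or verts[:, 1].min() < -0.5
        or verts[:, 1].max() > ncols - 0.5
    ):
        raise ValueError("ROI polygon extends outside the image bounds")
    return polygon_mask(image.pixels.shape, verts)


# ---------------------------------------------------------------------------
# Core quantification operations
# ---------------------------------------------------------------------------


def segment_axially(
    image: FluorescenceImage,
    aorta_extent_mm: float,
    segment_length_mm: float = 4.0,
) -> list[SegmentRoi]:
    """Divide the annotated aortic strip into contiguous axial segments.

    Returns ``floor(extent / length)`` full segments anchored at the
    renal-bifurcation end (axial 0); a trailing partial slot shorter than one
    segment is dropped.  Intervals are half-open ``[a, a + L)``; a pixel
    column belongs to the interval containing its centre.
    """
    if aorta_extent_mm < segment_length_mm:
        raise ValueError(
            f"aortic extent {aorta_extent_mm} mm is shorter than one "
            f"{segment_length_mm} mm segment"
        )
    if "aorta" not in image.rois:
        raise KeyError("image has no 'aorta' ROI to segment")
    aorta = _roi_mask(image, "aorta")
    if image.axial_axis != 1:
        raise ValueError("only column-axial images are supported")

    n_seg = int(np.floor(aorta_extent_mm / segment_length_mm + 1e-9))
    pitch = image.pixel_pitch_mm
    # axial coordinate (mm) of each pixel-column centre
    col_mm = (np.arange(image.pixels.shape[1]) + 0.5 - image.axial_origin_col) * pitch

    rois = []
    for i in range(n_seg):
        a, b = i * segment_length_mm, (i + 1) * segment_length_mm
        in_slot = (col_mm >= a) & (col_mm < b)
        rois.append(SegmentRoi(i, a, b, aorta & in_slot[None, :]))
    return rois


def mean_roi_signal(image: FluorescenceImage, roi) -> float:
    """Mean pixel intensity under the ROI, normalized to counts/s."""
    mask = _roi_mask(image, roi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI covers no pixels")
    return float(image.pixels[mask].mean()) / image.exposure_s


def compute_fer(segment_signal: float, reference_signal: float) -> float:
    """Fluorescence enhancement ratio: segment mean over femoral mean."""
    if not reference_signal > EPS_REFERENCE:
        raise ValueError(
            f"degenerate femoral reference signal ({reference_signal!r})"
        )
    return segment_signal / reference_signal


def quantify_closed_image(
    image: FluorescenceImage, segment_length_mm: float = 4.0
) -> list[FerRecord]:
    """Per-segment FER for one closed-view image.

    The aortic extent is taken from the annotated aorta ROI's axial span.
    """
    if image.view != "closed":
        raise ValueError(f"expected a closed-view image, got {image.view!r}")
    verts = np.asarray(image.rois["aorta"], float)
    extent_mm = (verts[:, 1].max() - verts[:, 1].min()) * image.pixel_pitch_mm
    reference = mean_roi_signal(image, "femoral_reference")
    records = []
    for roi in segment_axially(image, extent_mm, segment_length_mm):
        signal = mean_roi_signal(image, roi.mask)
        records.append(
            FerRecord(roi.index, signal, reference, compute_fer(signal, reference))
        )
    return records


def open_view_contrast(image: FluorescenceImage) -> list[dict]:
    """Paired thrombus / underlying-plaque FERs for one open-view image.

    Returns one dict per disrupted site: ``{"site", "thrombus_fer",
    "plaque_fer"}``, both normalized by the femoral reference.  An image
    with no thrombus ROIs yields an empty list.
    """
    if image.view != "open":
        raise ValueError(f"expected an open-view image, got {image.view!r}")
    thrombi = {
        name[len("thrombus_") :]
        for name in image.rois
        if name.startswith("thrombus_")
    }
    plaques = {
        name[len("plaque_under_thrombus_") :]
        for name in image.rois
        if name.startswith("plaque_under_thrombus_")
    }
    if thrombi != plaques:
        raise ValueError(
            f"unpaired open-view ROIs: thrombi {sorted(thrombi)} vs "
            f"plaques {sorted(plaques)}"
        )
    if not thrombi:
        return []
    reference = mean_roi_signal(image, "femoral_reference")
    out = []
    for site in sorted(thrombi, key=lambda t: (len(t), t)):
        t_sig = mean_roi_signal(image, f"thrombus_{site}")
        p_sig = mean_roi_signal(image, f"plaque_under_thrombus_{site}")
        out.append(
            {
                "site": site,
                "thrombus_fer": compute_fer(t_sig, reference),
                "plaque_fer": compute_fer(p_sig, reference),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Directory-level IO (consumes the generator's on-disk artifacts)
# ---------------------------------------------------------------------------


def load_image(tif_path: str | Path) -> FluorescenceImage:
    """Load a TIFF plus its sibling ``.rois.json`` annotation file."""
    tif_path = Path(tif_path)
    roi_path = tif_path.with_suffix("").with_suffix(".rois.json")
    meta = json.loads(roi_path.read_text())
    return FluorescenceImage(
        pixels=tifffile.imread(tif_path).astype(float),
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        view=meta["view"],
        exposure_s=meta["exposure_s"],
        rois={k: [tuple(v) for v in poly] for k, poly in meta["rois"].items()},
        axial_axis=meta["axial_axis"],
        axial_origin_col=meta["axial_origin_col"],
    )


def quantify_directory(
    in_dir: str | Path, out_dir: str | Path, segment_length_mm: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every rabbit's images under a simulate output directory.

    Writes ``fer.csv`` (rabbit_id, segment_index, mean_signal,
    reference_signal, fer) and ``open_view.csv`` (rabbit_id, site,
    thrombus_fer, plaque_fer) to ``out_dir`` and returns both tables.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    segments = pd.read_csv(in_dir / "segments.csv")
    rabbit_ids = sorted(segments["rabbit_id"].unique())

    fer_rows, open_rows = [], []
    for rid in rabbit_ids:
        closed = load_image(image_paths(in_dir, rid, "closed")[0])
        for rec in quantify_closed_image(closed, segment_length_mm):
            fer_rows.append(
                {
                    "rabbit_id": rid,
                    "segment_index": rec.segment_index,
                    "mean_signal": rec.mean_signal,
                    "reference_signal": rec.reference_signal,
                    "fer": rec.fer,
                }
            )
        open_img = load_image(image_paths(in_dir, rid, "open")[0])
        for site in open_view_contrast(open_img):
            open_rows.append({"rabbit_id": rid, **site})

    fer = pd.DataFrame(fer_rows)
    open_view = pd.DataFrame(
        open_rows, columns=["rabbit_id", "site", "thrombus_fer", "plaque_fer"]
    )
    fer.to_csv(out_dir / "fer.csv", index=False)
    open_view.to_csv(out_dir / "open_view.csv", index=False)
    return fer, open_view
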