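"""MRI-derived metrics: taper-corrected remodeling ratio and Gd enhancement.

The vessel area (VA) of a healthy abdominal aorta shrinks roughly linearly
from the renal toward the iliac bifurcation.  To compare lesion slices along
the vessel, that taper is removed first: an ordinary least-squares line is
fitted to VA on lesion-free slices only and every slice's VA is rescaled to a
common anchor position.  The slice with the least corrected VA — a proxy for
the least plaque — serves as the reference, and the remodeling ratio is
RR_i = VA_corrected_i / VA_corrected_reference, so RR > 1 indicates outward
(expansive) remodeling.  The Gd enhancement ratio is the contrast-enhanced
wall intensity over the matched non-enhanced intensity of the same slice.

Slices are registered to 4 mm fluorescence segments on the shared axial axis
(mm from the left renal bifurcation, half-open segment intervals).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import VesselSliceSeries

__all__ = [
    "taper_correct",
    "select_reference_slice",
    "remodeling_ratio",
    "gd_enhancement_ratio",
    "register_slices_to_segments",
    "quantify_series",
    "quantify_mri_directory",
]

EPS_INTENSITY = 1e-9


def taper_correct(series: VesselSliceSeries) -> np.ndarray:
    """Remove the linear vessel taper from the VA profile.

    Fits VA ~ axial position by OLS on lesion-free slices and rescales each
    slice by fitted(anchor)/fitted(position), anchor = the series midpoint.
    A lesion-free linear series therefore becomes flat, while remodeling
    (multiplicative VA excess) is preserved.
    """
    x = np.asarray(series.axial_position_mm, float)
    va = np.asarray(series.vessel_area_mm2, float)
    free = np.asarray(series.lesion_free, bool)
    if free.sum() < 2:
        raise ValueError(
            f"taper fit needs >= 2 lesion-free slices, got {int(free.sum())}"
        )
    slope, intercept = np.polyfit(x[free], va[free], 1)
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("taper fit produced a non-finite line")
    anchor = (x.min() + x.max()) / 2.0
    fitted = intercept + slope * x
    if np.any(fitted <= 0):
        raise ValueError("fitted taper line non-positive at some slice")
    return va * (intercept + slope * anchor) / fitted


def select_reference_slice(corrected_va: np.ndarray) -> int:
    """Index of the slice with the least corrected VA (least-plaque proxy).

    Ties resolve to the smallest axial position, i.e. the first index.
    """
    corrected_va = np.asarray(corrected_va, float)
    if corrected_va.size == 0:
        raise ValueError("empty series")
    return int(np.argmin(corrected_va))


def remodeling_ratio(corrected_va: np.ndarray, reference_index: int) -> np.ndarray:
    """RR per slice: corrected VA over the reference slice's corrected VA."""
    corrected_va = np.asarray(corrected_va, float)
    ref = corrected_va[reference_index]
    if not ref > 0:
        raise ValueError(f"non-positive reference vessel area ({ref})")
    return corrected_va / ref


def gd_enhancement_ratio(wall_ce, wall_nc) -> np.ndarray:
    """GdR per slice: contrast-enhanced over non-enhanced wall intensity."""
    ce = np.asarray(wall_ce, float)
    nc = np.asarray(wall_nc, float)
    if np.any(nc <= EPS_INTENSITY):
        raise ValueError("non-positive non-contrast wall intensity")
    return ce / nc


def register_slices_to_segments(
    slice_positions_mm,
    segment_starts_mm,
    segment_length_mm: float = 4.0,
) -> tuple[dict[int, int], list[int]]:
    """Assign each slice to the segment whose half-open interval contains it.

    Both coordinates are mm from the left renal bifurcation.  Returns
    ``(mapping, unmapped)`` where ``mapping[slice_idx] = segment position in
    segment_starts_mm`` and ``unmapped`` lists slices outside every segment.
    """
    pos = np.asarray(slice_positions_mm, float)
    starts = np.asarray(segment_starts_mm, float)
    order = np.argsort(starts)
    sorted_starts = starts[order]
    mapping: dict[int, int] = {}
    unmapped: list[int] = []
    for i, p in enumerate(pos):
        j = int(np.searchsorted(sorted_starts, p, side="right")) - 1
        if j >= 0 and p < sorted_starts[j] + segment_length_mm:
            mapping[i] = int(order[j])
        else:
            unmapped.append(i)
    return mapping, unmapped


def quantify_series(
    series: VesselSliceSeries,
    segment_starts_mm,
    segment_length_mm: float = 4.0,
) -> pd.DataFrame:
    """RR and GdR per slice of one rabbit, registered to its segments.

    Returns a frame with columns (segment_pos, rr, gdr) where segment_pos
    indexes into ``segment_starts_mm``; unmapped slices are dropped after
    being counted (they are reported by ``register_slices_to_segments``).
    """
    corrected = taper_correct(series)
    ref = select_reference_slice(corrected)
    rr = remodeling_ratio(corrected, ref)
    gdr = gd_enhancement_ratio(series.wall_intensity_ce, series.wall_intensity_nc)
    mapping, _ = register_slices_to_segments(
        series.axial_position_mm, segment_starts_mm, segment_length_mm
    )
    rows = [
        {"segment_pos": seg_pos, "rr": rr[i], "gdr": gdr[i]}
        for i, seg_pos in mapping.items()
    ]
    return pd.DataFrame(rows, columns=["segment_pos", "rr", "gdr"])


def quantify_mri_directory(
    in_dir: str | Path, out_dir: str | Path, segment_length_mm: float = 4.0
) -> pd.DataFrame:
    """Compute per-segment RR and GdR for every rabbit in a simulate output.

    Reads ``mri_slices.csv`` and ``segments.csv``; writes and returns
    ``mri_metrics.csv`` (rabbit_id, segment_index, rr, gdr).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slices = pd.read_csv(in_dir / "mri_slices.csv")
    segments = pd.read_csv(in_dir / "segments.csv")

    rows = []
    for rid, chunk in slices.groupby("rabbit_id", sort=True):
        chunk = chunk.sort_values("axial_position_mm")
        series = VesselSliceSeries(
            rabbit_id=str(rid),
            axial_position_mm=chunk["axial_position_mm"].to_numpy(),
            vessel_area_mm2=chunk["va_mm2"].to_numpy(),
            wall_intensity_ce=chunk["wall_ce"].to_numpy(),
            wall_intensity_nc=chunk["wall_nc"].to_numpy(),
            lesion_free=chunk["lesion_free"].to_numpy(bool),
        )
        segs = segments[segments["rabbit_id"] == rid].sort_values("segment_index")
        per_slice = quantify_series(
            series, segs["axial_start_mm"].to_numpy(), segment_length_mm
        )
        seg_index = segs["segment_index"].to_numpy()
        for _, row in per_slice.iterrows():
            rows.append(
                {
                    "rabbit_id": rid,
                    "segment_index": int(seg_index[int(row["segment_pos"])]),
                    "rr": row["rr"],
                    "gdr": row["gdr"],
                }
            )
    metrics = pd.DataFrame(rows, columns=["rabbit_id", "segment_index", "rr", "gdr"])
    metrics.to_csv(out_dir / "mri_metrics.csv", index=False)
    return metrics
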