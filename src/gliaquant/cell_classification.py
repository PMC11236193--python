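"""Marker classification of segmented cells and density computation.

Implements the background-corrected intensity chain used to call a
segmented cell positive for an immunomarker: each nucleus is dilated by
1 um, the marker channel's mean intensity over the dilated region is
corrected by the scene background (``meanIntCor = meanInt - bg``, where
``bg`` is the mean of the darkest pixels of the projection), and a strict
greater-than threshold on meanIntCor yields the call. Cell counts convert
to volumetric densities via the projected ROI area times the imaged depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

from .segmentation import LabelMap, ProjectedImage

__all__ = [
    "CellRecord",
    "DensityResult",
    "dilate_nucleus",
    "estimate_background",
    "mean_int_cor",
    "measure_markers",
    "classify_cells",
    "auto_marker_thresholds",
    "cell_density",
    "records_to_frame",
]


@dataclass
class CellRecord:
    """One segmented nucleus and everything measured on it."""

    label_id: int
    centroid_um: tuple[float, float]
    nucleus_area_um2: float
    gfp_pos: bool
    marker_values: dict[str, float] = field(default_factory=dict)  # meanIntCor
    marker_calls: dict[str, bool] = field(default_factory=dict)
    puncta_surface: dict[str, float] = field(default_factory=dict)  # um^2 per probe


@dataclass(frozen=True)
class DensityResult:
    """Cell count over an ROI volume, as cells per mm^3."""

    region: str
    n_cells: int
    roi_area_um2: float
    depth_um: float
    density_per_mm3: float


def _radius_px(radius_um: float, pixel_size_um: tuple[float, float]) -> int:
    # ceiling so the stated physical radius is never under-dilated
    return int(math.ceil(radius_um / min(pixel_size_um)))


def dilate_nucleus(labelmap: LabelMap, label_id: int, radius_um: float) -> np.ndarray:
    """Boolean pixel set of one nucleus dilated by a disk of ``radius_um``.

    Radius 0 returns the nucleus pixel set unchanged; the dilated set always
    contains the original. Unknown labels raise ``ValueError``.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    mask = labelmap.labels == label_id
    if not mask.any():
        raise ValueError(f"label {label_id} not present in label map")
    r = _radius_px(radius_um, labelmap.pixel_size_um)
    if r == 0:
        return mask
    return ndi.binary_dilation(mask, structure=disk(r))


def estimate_background(
    proj: ProjectedImage, channel: str, percentile: float = 1.0
) -> float:
    """Mean of the darkest ``percentile`` % of pixels in the channel.

    Reduces to the single minimum pixel as percentile -> 0 and to the
    global mean at percentile = 100; a constant image of value c gives c.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    vals = np.asarray(proj.plane(channel), dtype=np.float64).ravel()
    k = max(1, int(math.ceil(percentile / 100.0 * vals.size)))
    darkest = np.partition(vals, k - 1)[:k]
    return float(darkest.mean())


def mean_int_cor(
    proj: ProjectedImage, channel: str, region: np.ndarray, bg: float
) -> float:
    """Background-corrected mean intensity over a pixel region.

    ``region`` is a boolean mask in the projection's frame. The result may
    be negative, and is linear in intensity: scaling the channel and the
    background by c scales the output by c. Empty regions are an error.
    """
    plane = proj.plane(channel)
    region = np.asarray(region, dtype=bool)
    if region.shape != plane.shape:
        raise ValueError("region mask shape does not match the projection")
    if not region.any():
        raise ValueError("cannot measure mean intensity over an empty region")
    return float(plane[region].mean() - bg)


def measure_markers(
    proj: ProjectedImage,
    nuclei: LabelMap,
    marker_channels: Sequence[str],
    gfp_flags: Mapping[int, bool] | None = None,
    dilation_radius_um: float = 1.0,
    bg_percentile: float = 1.0,
) -> list[CellRecord]:
    """Build one :class:`CellRecord` per segmented nucleus with meanIntCor
    values for every marker channel (calls are left empty; see
    :func:`classify_cells`)."""
    gfp_flags = gfp_flags or {}
    bgs = {ch: estimate_background(proj, ch, bg_percentile) for ch in marker_channels}
    planes = {ch: np.asarray(proj.plane(ch), dtype=np.float64) for ch in marker_channels}
    dx, dy = nuclei.pixel_size_um
    r = _radius_px(dilation_radius_um, nuclei.pixel_size_um)
    footprint = disk(r) if r > 0 else None
    records: list[CellRecord] = []
    for prop in regionprops(nuclei.labels):
        sl = prop.slice
        if footprint is not None:
            pad = r
            y0 = max(sl[0].start - pad, 0)
            y1 = min(sl[0].stop + pad, nuclei.labels.shape[0])
            x0 = max(sl[1].start - pad, 0)
            x1 = min(sl[1].stop + pad, nuclei.labels.shape[1])
            local = nuclei.labels[y0:y1, x0:x1] == prop.label
            local = ndi.binary_dilation(local, structure=footprint)
        else:
            y0, y1 = sl[0].start, sl[0].stop
            x0, x1 = sl[1].start, sl[1].stop
            local = nuclei.labels[y0:y1, x0:x1] == prop.label
        values = {
            ch: float(planes[ch][y0:y1, x0:x1][local].mean() - bgs[ch])
            for ch in marker_channels
        }
        cy, cx = prop.centroid
        records.append(
            CellRecord(
                label_id=int(prop.label),
                centroid_um=((cx + 0.5) * dx, (cy + 0.5) * dy),
                nucleus_area_um2=float(prop.area * nuclei.pixel_area_um2),
                gfp_pos=bool(gfp_flags.get(int(prop.label), False)),
                marker_values=values,
            )
        )
    return records


def classify_cells(
    records: Iterable[CellRecord], thresholds: Mapping[str, float]
) -> list[CellRecord]:
    """Set ``marker_calls`` on every record by a strict greater-than
    comparison of meanIntCor with the per-channel threshold. The number of
    positive cells is monotone non-increasing in the threshold. A channel
    without a threshold is an error."""
    records = list(records)
    for rec in records:
        for ch in rec.marker_values:
            if ch not in thresholds:
                raise ValueError(f"no threshold provided for marker channel {ch!r}")
            rec.marker_calls[ch] = rec.marker_values[ch] > thresholds[ch]
    return records


def auto_marker_thresholds(
    records: Sequence[CellRecord], channels: Sequence[str]
) -> dict[str, float]:
    """Otsu threshold over the per-cell meanIntCor distribution per channel.

    A reproducible stand-in for the user-picked threshold of the original
    protocol; sensible only when the scene contains both positive and
    negative cells for the channel.
    """
    out: dict[str, float] = {}
    for ch in channels:
        vals = np.asarray([r.marker_values[ch] for r in records], dtype=np.float64)
        if vals.size == 0:
            raise ValueError(f"no cells to derive a threshold for channel {ch!r}")
        if np.ptp(vals) == 0:
            out[ch] = float(vals[0])  # nothing separable: everything called negative
        else:
            out[ch] = float(threshold_otsu(vals, nbins=256))
    return out


def cell_density(
    n_cells: int, roi_area_um2: float, depth_um: float, region: str = "scene"
) -> DensityResult:
    """Convert a projected cell count into cells per mm^3.

    density = n / (area_um2 * depth_um) * 1e9, i.e. the count divided by
    the imaged ROI volume (projected area times the projected depth).
    """
    if roi_area_um2 <= 0 or depth_um <= 0:
        raise ValueError(
            f"ROI geometry must be positive (area {roi_area_um2}, depth {depth_um})"
        )
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    density = n_cells / (roi_area_um2 * depth_um) * 1e9
    return DensityResult(
        region=region,
        n_cells=int(n_cells),
        roi_area_um2=float(roi_area_um2),
        depth_um=float(depth_um),
        density_per_mm3=float(density),
    )


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Flatten records to one row per cell for CSV output."""
    rows = []
    for r in records:
        row: dict = {
            "label_id": r.label_id,
            "x_um": r.centroid_um[0],
            "y_um": r.centroid_um[1],
            "area_um2": r.nucleus_area_um2,
            "gfp_pos": r.gfp_pos,
        }
        for ch, v in r.marker_values.items():
            row[f"meanintcor_{ch}"] = v
        for ch, v in r.marker_calls.items():
            row[f"call_{ch}"] = v
        for pr, v in r.puncta_surface.items():
            row[f"surface_{pr}_um2"] = v
        rows.append(row)
    return pd.DataFrame(rows)
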