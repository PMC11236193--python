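"""Projection, nucleus instance segmentation and reporter colocalization.

Front end of the cell-counting chain: maximum (or mean/sum) projection of
the first N z-planes, classical nucleus instance segmentation (Gaussian
smoothing, Otsu threshold, distance-transform watershed) with an exact
projected-area filter, reporter-channel segmentation with a minimum
intensity threshold, and nucleus-reporter colocalization that defines
reporter-positive (oligolineage) cells.

The segmenter is deliberately a deterministic classical pipeline behind the
``segment_nuclei`` contract; a learned instance segmenter can be swapped in
by providing any function with the same signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .synthetic_data import ImageStack

__all__ = [
    "ProjectedImage",
    "LabelMap",
    "SizeFilter",
    "project",
    "segment_nuclei",
    "segment_reporter",
    "colocalize",
    "apply_size_filter",
]

_PROJECTORS: Mapping[str, Callable[[np.ndarray], np.ndarray]] = {
    "max": lambda a: a.max(axis=0),
    "mean": lambda a: a.mean(axis=0),
    "sum": lambda a: a.sum(axis=0),
}


@dataclass
class ProjectedImage:
    """2-D projection of a stack: one plane per channel."""

    planes: dict[str, np.ndarray]
    pixel_size_um: tuple[float, float]  # (dx, dy)
    z_planes_used: int
    z_step_um: float
    channel_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) > 1:
            raise ValueError(f"planes have differing shapes: {shapes}")
        if self.z_planes_used < 1:
            raise ValueError("z_planes_used must be >= 1")

    @property
    def depth_um(self) -> float:
        """Imaged depth represented by the projection."""
        return self.z_planes_used * self.z_step_um

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um[0] * self.pixel_size_um[1]

    def plane(self, channel: str) -> np.ndarray:
        try:
            return self.planes[channel]
        except KeyError:
            raise ValueError(
                f"channel {channel!r} not in projection; "
                f"available: {sorted(self.planes)}"
            ) from None


@dataclass
class LabelMap:
    """Integer instance labels of segmented nuclei (0 = background)."""

    labels: np.ndarray
    pixel_size_um: tuple[float, float]

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um[0] * self.pixel_size_um[1]

    def areas_um2(self) -> dict[int, float]:
        counts = np.bincount(self.labels.ravel())
        return {
            k: float(counts[k] * self.pixel_area_um2)
            for k in range(1, len(counts))
            if counts[k] > 0
        }

    def centroids_um(self) -> dict[int, tuple[float, float]]:
        """Label -> (x_um, y_um) centroid at pixel-center convention."""
        dx, dy = self.pixel_size_um
        out = {}
        idx = np.arange(1, self.n_labels + 1)
        if len(idx) == 0:
            return out
        cys, cxs = zip(*ndi.center_of_mass(np.ones_like(self.labels), self.labels, idx))
        for k, cy, cx in zip(idx, cys, cxs):
            out[int(k)] = ((cx + 0.5) * dx, (cy + 0.5) * dy)
        return out


@dataclass(frozen=True)
class SizeFilter:
    """Projected-area bounds (um^2) for keeping a segmented nucleus."""

    min_area_um2: float
    max_area_um2: float

    def __post_init__(self) -> None:
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError(
                "size filter requires 0 < min_area_um2 < max_area_um2, got "
                f"({self.min_area_um2}, {self.max_area_um2})"
            )


#: Defaults bracket glial nuclei of radius 2.5-4.5 um (areas ~20-64 um^2).
DEFAULT_SIZE_FILTER = SizeFilter(min_area_um2=10.0, max_area_um2=150.0)


def project(stack: ImageStack, n_planes: int = 15, method: str = "max") -> ProjectedImage:
    """Project the first ``n_planes`` z-planes of every channel.

    Raises ``ValueError`` when the stack has fewer planes than requested,
    stating how many are available.
    """
    if method not in _PROJECTORS:
        raise ValueError(f"unknown projection method {method!r}; use one of {sorted(_PROJECTORS)}")
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    if stack.n_planes < n_planes:
        raise ValueError(
            f"requested projection over {n_planes} planes but the stack has "
            f"only {stack.n_planes}"
        )
    reduce = _PROJECTORS[method]
    planes = {name: reduce(arr[:n_planes]) for name, arr in stack.channels.items()}
    dx, dy, dz = stack.voxel_size_um
    return ProjectedImage(
        planes=planes,
        pixel_size_um=(dx, dy),
        z_planes_used=n_planes,
        z_step_um=dz,
        channel_roles=dict(stack.channel_roles),
    )


def _smooth(plane: np.ndarray, pixel_size: tuple[float, float], sigma_um: float) -> np.ndarray:
    plane = np.asarray(plane, dtype=np.float64)
    if sigma_um <= 0:
        return plane
    dx, dy = pixel_size
    return ndi.gaussian_filter(plane, sigma=(sigma_um / dy, sigma_um / dx))


def apply_size_filter(labelmap: LabelMap, size_filter: SizeFilter) -> LabelMap:
    """Drop instances whose projected area falls outside [min, max] um^2
    (bounds inclusive), then compact labels to 1..K preserving order."""
    labels = labelmap.labels
    counts = np.bincount(labels.ravel())
    areas = counts * labelmap.pixel_area_um2
    bad = (areas < size_filter.min_area_um2) | (areas > size_filter.max_area_um2)
    bad[0] = False
    out = labels.copy()
    if bad.any():
        out[bad[labels]] = 0
    out, _, _ = relabel_sequential(out)
    return LabelMap(labels=out.astype(np.int32), pixel_size_um=labelmap.pixel_size_um)


def segment_nuclei(
    proj: ProjectedImage,
    nuclear_channel: str = "hoechst",
    size_filter: SizeFilter = DEFAULT_SIZE_FILTER,
    smooth_sigma_um: float = 1.0,
    min_peak_distance_um: float = 3.0,
) -> LabelMap:
    """Instance-segment nuclei on the projected nuclear plane.

    Pipeline: Gaussian smoothing -> global Otsu threshold -> Euclidean
    distance transform -> peak markers -> watershed split, followed by the
    projected-area filter and label compaction. A blank (constant) plane
    yields an empty label map rather than an error. The result is invariant
    to multiplying the intensities by a positive constant.
    """
    plane = proj.plane(nuclear_channel)
    dx, dy = proj.pixel_size_um
    sm = _smooth(plane, proj.pixel_size_um, smooth_sigma_um)
    empty = LabelMap(
        labels=np.zeros(plane.shape, dtype=np.int32), pixel_size_um=proj.pixel_size_um
    )
    if np.ptp(sm) == 0:
        return empty
    binary = sm > threshold_otsu(sm)
    if not binary.any():
        return empty
    dist = ndi.distance_transform_edt(binary, sampling=(dy, dx))
    min_dist_px = max(1, int(round(min_peak_distance_um / min(dx, dy))))
    comp_labels, _ = ndi.label(binary)
    coords = peak_local_max(
        dist, min_distance=min_dist_px, labels=comp_labels, exclude_border=False
    )
    if len(coords) == 0:
        return empty
    markers = np.zeros(plane.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-dist, markers, mask=binary)
    lm = LabelMap(labels=labels.astype(np.int32), pixel_size_um=proj.pixel_size_um)
    return apply_size_filter(lm, size_filter)


def segment_reporter(
    proj: ProjectedImage,
    reporter_channel: str = "gfp",
    min_intensity: float | None = None,
    smooth_sigma_um: float = 1.0,
) -> np.ndarray:
    """Binary reporter mask: smoothed intensity >= ``min_intensity``.

    When ``min_intensity`` is None the threshold is chosen by Otsu on the
    smoothed plane, standing in for the manual signal-versus-background
    threshold of the original protocol. Mask area is monotone
    non-increasing in ``min_intensity``.
    """
    plane = proj.plane(reporter_channel)
    sm = _smooth(plane, proj.pixel_size_um, smooth_sigma_um)
    if min_intensity is None:
        if np.ptp(sm) == 0:
            return np.zeros(plane.shape, dtype=bool)
        min_intensity = float(threshold_otsu(sm))
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    return sm >= min_intensity


def colocalize(
    nuclei: LabelMap, reporter_mask: np.ndarray, overlap_fraction: float = 0.5
) -> dict[int, bool]:
    """Flag each nucleus whose overlap with the reporter mask reaches
    ``overlap_fraction`` of its own area. Flags are monotone non-increasing
    in the overlap fraction."""
    if reporter_mask.shape != nuclei.labels.shape:
        raise ValueError(
            f"shape mismatch: nuclei {nuclei.labels.shape} vs mask {reporter_mask.shape}"
        )
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    n = nuclei.n_labels
    if n == 0:
        return {}
    areas = np.bincount(nuclei.labels.ravel(), minlength=n + 1)[1:]
    inside = np.bincount(
        nuclei.labels.ravel(), weights=reporter_mask.ravel().astype(float), minlength=n + 1
    )[1:]
    frac = np.divide(inside, areas, out=np.zeros(n), where=areas > 0)
    return {k + 1: bool(frac[k] >= overlap_fraction) for k in range(n)}
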