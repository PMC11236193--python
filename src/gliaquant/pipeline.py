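"""End-to-end scene analysis: stack in, per-cell table and densities out.

Chains the analysis modules exactly as the quantification protocol does:
projection of the first N z-planes, nucleus segmentation with size
filtering, reporter segmentation and colocalization (defining
reporter-positive oligolineage cells), marker measurement/classification,
smFISH puncta quantification, and density computation. Only the image
stack is consumed here; ground truth never enters the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from . import smfish as _smfish
from .cell_classification import (
    CellRecord,
    DensityResult,
    auto_marker_thresholds,
    cell_density,
    classify_cells,
    measure_markers,
    records_to_frame,
)
from .segmentation import (
    DEFAULT_SIZE_FILTER,
    LabelMap,
    ProjectedImage,
    SizeFilter,
    colocalize,
    project,
    segment_nuclei,
    segment_reporter,
)
from .synthetic_data import ImageStack

__all__ = ["AnalysisParams", "SceneResult", "analyze_scene"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable knobs of the full analysis chain with protocol defaults."""

    n_planes: int = 15
    projection: str = "max"
    nuclear_channel: str = "hoechst"
    reporter_channel: str = "gfp"
    size_filter: SizeFilter = DEFAULT_SIZE_FILTER
    smooth_sigma_um: float = 1.0
    min_peak_distance_um: float = 3.0
    reporter_min_intensity: float | None = None  # None -> Otsu
    overlap_fraction: float = 0.5
    dilation_radius_um: float = 1.0
    bg_percentile: float = 1.0
    marker_thresholds: Mapping[str, float] | None = None  # None -> Otsu per channel
    surface_threshold_um2: float = _smfish.SURFACE_THRESHOLD_UM2
    puncta_sigma_um: float = 0.35
    assign_radius_um: float = 0.0

    def with_(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)


@dataclass
class SceneResult:
    """Everything one scene's analysis produced."""

    proj: ProjectedImage
    nuclei: LabelMap
    gfp_flags: dict[int, bool]
    records: list[CellRecord] = field(default_factory=list)
    expression_calls: pd.DataFrame | None = None
    marker_thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def roi_area_um2(self) -> float:
        shape = next(iter(self.proj.planes.values())).shape
        return shape[0] * shape[1] * self.proj.pixel_area_um2

    @property
    def n_gfp(self) -> int:
        return sum(self.gfp_flags.values())

    def gfp_density(self, region: str = "scene") -> DensityResult:
        return cell_density(self.n_gfp, self.roi_area_um2, self.proj.depth_um, region)

    def marker_gfp_density(self, channel: str, region: str = "scene") -> DensityResult:
        n = sum(
            1 for r in self.records if r.gfp_pos and r.marker_calls.get(channel, False)
        )
        return cell_density(n, self.roi_area_um2, self.proj.depth_um, region)

    def gfp_positive_labels(self) -> list[int]:
        return [k for k, v in self.gfp_flags.items() if v]

    def coexpression(self, probe_a: str, probe_b: str) -> float | None:
        if self.expression_calls is None:
            raise ValueError("scene was analyzed without probe channels")
        return _smfish.coexpression_percentage(self.expression_calls, probe_a, probe_b)

    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def analyze_scene(
    stack: ImageStack,
    params: AnalysisParams = AnalysisParams(),
    marker_channels: Sequence[str] | None = None,
    probe_channels: Sequence[str] | None = None,
) -> SceneResult:
    """Run the full quantification chain on one stack.

    Marker and probe channels default to every channel whose declared role
    is ``marker`` / ``probe``. The reporter step is skipped when the stack
    has no reporter channel (all cells are then reporter-negative).
    """
    if marker_channels is None:
        marker_channels = [
            c for c, role in stack.channel_roles.items() if role == "marker"
        ]
    if probe_channels is None:
        probe_channels = [
            c for c, role in stack.channel_roles.items() if role == "probe"
        ]
    proj = project(stack, n_planes=params.n_planes, method=params.projection)
    nuclei = segment_nuclei(
        proj,
        nuclear_channel=params.nuclear_channel,
        size_filter=params.size_filter,
        smooth_sigma_um=params.smooth_sigma_um,
        min_peak_distance_um=params.min_peak_distance_um,
    )
    if params.reporter_channel in proj.planes:
        mask = segment_reporter(
            proj,
            reporter_channel=params.reporter_channel,
            min_intensity=params.reporter_min_intensity,
            smooth_sigma_um=params.smooth_sigma_um,
        )
        flags = colocalize(nuclei, mask, params.overlap_fraction)
    else:
        flags = {k: False for k in range(1, nuclei.n_labels + 1)}

    records = measure_markers(
        proj,
        nuclei,
        marker_channels=list(marker_channels),
        gfp_flags=flags,
        dilation_radius_um=params.dilation_radius_um,
        bg_percentile=params.bg_percentile,
    )
    thresholds: dict[str, float] = {}
    if marker_channels:
        if params.marker_thresholds is None:
            thresholds = auto_marker_thresholds(records, list(marker_channels))
        else:
            thresholds = dict(params.marker_thresholds)
        records = classify_cells(records, thresholds)

    calls: pd.DataFrame | None = None
    if probe_channels:
        all_puncta = []
        for ch in probe_channels:
            all_puncta.extend(
                _smfish.detect_puncta(proj, ch, sigma_um=params.puncta_sigma_um)
            )
        surfaces = _smfish.accumulate_per_nucleus(
            all_puncta, nuclei, assign_radius_um=params.assign_radius_um
        )
        calls = _smfish.make_expression_calls(surfaces, params.surface_threshold_um2)
        by_label = calls.set_index(["label_id", "probe"])["total_surface_um2"]
        for rec in records:
            for ch in probe_channels:
                rec.puncta_surface[ch] = float(by_label.get((rec.label_id, ch), 0.0))

    return SceneResult(
        proj=proj,
        nuclei=nuclei,
        gfp_flags=flags,
        records=records,
        expression_calls=calls,
        marker_thresholds=thresholds,
    )
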