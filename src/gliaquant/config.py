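"""YAML config parsing for the command-line interface.

A config file has two optional top-level blocks: ``scene`` (mapped onto
:class:`~gliaquant.synthetic_data.TissueSpec`) and ``analysis`` (mapped
onto :class:`~gliaquant.pipeline.AnalysisParams`, with
``classification:`` keys folded in).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .pipeline import AnalysisParams
from .segmentation import SizeFilter
from .synthetic_data import BandSpec, CellClassSpec, NoiseSpec, TissueSpec

__all__ = ["load_config", "tissue_spec_from_dict", "analysis_params_from_dict"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def tissue_spec_from_dict(d: Mapping[str, Any], seed: int | None = None) -> TissueSpec:
    d = dict(d)
    classes = tuple(
        CellClassSpec(
            name=c["name"],
            density=float(c["density"]),
            gfp_prob=float(c.get("gfp_prob", 0.0)),
            marker_probs={k: float(v) for k, v in (c.get("marker_probs") or {}).items()},
            probe_probs={k: float(v) for k, v in (c.get("probe_probs") or {}).items()},
        )
        for c in d.pop("classes", [])
    )
    band = d.pop("band", None)
    noise = d.pop("noise", None)
    kwargs: dict[str, Any] = {}
    for key in (
        "region_name",
        "puncta_rate_pos",
        "puncta_rate_neg",
        "punctum_radius_um",
        "psf_sigma_um",
        "marker_styles",
    ):
        if key in d:
            kwargs[key] = d[key]
    for key in ("extent_um", "voxel_size_um", "nucleus_radius_um"):
        if key in d:
            kwargs[key] = tuple(float(v) for v in d[key])
    if band:
        kwargs["band"] = BandSpec(
            center_y_um=float(band["center_y_um"]),
            thickness_um=float(band["thickness_um"]),
            intensity=float(band.get("intensity", 1000.0)),
            n_fibers=band.get("n_fibers"),
            fiber_thickness_um=float(band.get("fiber_thickness_um", 1.5)),
        )
    if noise:
        kwargs["noise"] = NoiseSpec(
            gaussian_sd=float(noise.get("gaussian_sd", 2.0)),
            poisson_scale=float(noise.get("poisson_scale", 0.05)),
        )
    if seed is not None:
        kwargs["seed"] = int(seed)
    elif "seed" in d:
        kwargs["seed"] = int(d["seed"])
    return TissueSpec(classes=classes, **kwargs)


def analysis_params_from_dict(d: Mapping[str, Any]) -> AnalysisParams:
    d = dict(d)
    d.update(d.pop("classification", {}) or {})
    kwargs: dict[str, Any] = {}
    if "min_area_um2" in d or "max_area_um2" in d:
        kwargs["size_filter"] = SizeFilter(
            min_area_um2=float(d.pop("min_area_um2", 10.0)),
            max_area_um2=float(d.pop("max_area_um2", 150.0)),
        )
    for key in (
        "n_planes",
        "projection",
        "nuclear_channel",
        "reporter_channel",
        "smooth_sigma_um",
        "min_peak_distance_um",
        "reporter_min_intensity",
        "overlap_fraction",
        "dilation_radius_um",
        "bg_percentile",
        "marker_thresholds",
        "surface_threshold_um2",
        "puncta_sigma_um",
        "assign_radius_um",
    ):
        if key in d:
            kwargs[key] = d[key]
    return AnalysisParams(**kwargs)
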