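"""Canonical synthetic study conditions and recovery experiments.

Defines the scene cohorts used by the test and acceptance suites: two-group
cell-density cohorts at the measured control/ablated oligolineage
densities, duplex smFISH scenes at a chosen true co-expression fraction,
and paired fiber-band scenes for morphometry. Each runner generates the
scenes, analyzes them through the image pipeline only (never the ground
truth), and compares the estimate with the generator's truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import band_thickness
from .pipeline import AnalysisParams, analyze_scene
from .segmentation import project
from .stats_reporting import percent_reduction
from .synthetic_data import (
    BandSpec,
    CellClassSpec,
    NoiseSpec,
    TissueSpec,
    place_cells,
    render_stack,
)

__all__ = [
    "density_scene_spec",
    "smfish_scene_spec",
    "band_scene_spec",
    "DensityRecovery",
    "density_reduction_recovery",
    "CoexpressionRecovery",
    "coexpression_recovery",
    "BandRecovery",
    "band_reduction_recovery",
]

# Measured oligolineage (GFP+) densities in the central corpus callosum,
# control vs ablated, in cells/mm^3 — the two-group study conditions.
CONTROL_DENSITY = 41.2e4
ABLATED_DENSITY = 13.9e4

#: density of reporter-negative (non-oligolineage) nuclei in every scene
OTHER_NUCLEI_DENSITY = 20e4


def density_scene_spec(
    oligo_density: float,
    seed: int,
    ng2_prob: float = 0.6,
    region_name: str = "cc_center",
) -> TissueSpec:
    """A 200 x 200 x 10.2 um field with a GFP+ oligolineage class at the
    given density plus reporter-negative background nuclei."""
    return TissueSpec(
        region_name=region_name,
        extent_um=(200.0, 200.0, 10.2),
        voxel_size_um=(0.5, 0.5, 0.68),
        classes=(
            CellClassSpec(
                "oligolineage",
                oligo_density,
                gfp_prob=1.0,
                marker_probs={"ng2": ng2_prob},
            ),
            CellClassSpec("other", OTHER_NUCLEI_DENSITY),
        ),
        seed=seed,
    )


def smfish_scene_spec(coexpression_fraction: float, seed: int) -> TissueSpec:
    """Duplex smFISH field: OPC-like nuclei expressing the lineage probe
    (cspg4) with the target probe (c1ql1) in the given fraction, plus
    neuron-like nuclei with sparse target expression only.

    Finer 0.25 um pixels resolve individual diffraction-limited puncta so
    the per-nucleus half-peak surface quantizes reasonably.
    """
    return TissueSpec(
        region_name="cortex",
        extent_um=(150.0, 150.0, 10.2),
        voxel_size_um=(0.25, 0.25, 0.68),
        classes=(
            CellClassSpec(
                "opc",
                30e4,
                probe_probs={"cspg4": 0.9, "c1ql1": coexpression_fraction},
            ),
            CellClassSpec("neuron", 10e4, probe_probs={"cspg4": 0.0, "c1ql1": 0.3}),
        ),
        psf_sigma_um=0.2,
        seed=seed,
    )


def band_scene_spec(
    thickness_um: float, seed: int, noise: NoiseSpec | None = None
) -> TissueSpec:
    """Cell-free fiber-band scene (corpus-callosum-like) for morphometry."""
    return TissueSpec(
        region_name="cc_lateral",
        extent_um=(200.0, 500.0, 10.2),
        voxel_size_um=(1.0, 1.0, 0.68),
        classes=(),
        band=BandSpec(center_y_um=250.0, thickness_um=thickness_um, intensity=1000.0),
        noise=noise if noise is not None else NoiseSpec(),
        seed=seed,
    )


@dataclass
class DensityRecovery:
    control_densities: list[float]  # pipeline estimate per scene, cells/mm^3
    ablated_densities: list[float]
    estimated_reduction_pct: float
    true_reduction_pct: float


def density_reduction_recovery(
    seed: int,
    n_scenes: int = 5,
    control_density: float = CONTROL_DENSITY,
    ablated_density: float = ABLATED_DENSITY,
    params: AnalysisParams = AnalysisParams(),
) -> DensityRecovery:
    """Generate control/ablated cohorts, quantify GFP+ density per scene
    end-to-end, and compare the estimated percent reduction of group means
    with the generator's truth."""
    out: dict[str, list[float]] = {"control": [], "ablated": []}
    for group, density in (("control", control_density), ("ablated", ablated_density)):
        for i in range(n_scenes):
            scene_seed = int(seed) * 1000 + (0 if group == "control" else 500) + i
            spec = density_scene_spec(density, seed=scene_seed)
            truth = place_cells(spec)
            stack = render_stack(truth, spec, channels=["hoechst", "gfp"])
            res = analyze_scene(stack, params)
            out[group].append(res.gfp_density().density_per_mm3)
    est = percent_reduction(
        float(np.mean(out["control"])), float(np.mean(out["ablated"]))
    )
    true = percent_reduction(control_density, ablated_density)
    return DensityRecovery(
        control_densities=out["control"],
        ablated_densities=out["ablated"],
        estimated_reduction_pct=est,
        true_reduction_pct=true,
    )


@dataclass
class CoexpressionRecovery:
    true_fraction: float
    per_scene_pct: list[float]
    pooled_pct: float  # pooled over scenes: 100 * sum(a+b+) / sum(b+)


def coexpression_recovery(
    true_fraction: float,
    seed: int,
    n_scenes: int = 5,
    params: AnalysisParams = AnalysisParams(),
) -> CoexpressionRecovery:
    """Duplex smFISH recovery: percent of cspg4+ nuclei also c1ql1+, pooled
    over scenes, against the generator's true co-expression fraction."""
    from .smfish import coexpression_counts

    n_ab = n_b = 0
    per_scene: list[float] = []
    for i in range(n_scenes):
        spec = smfish_scene_spec(
            true_fraction, seed=int(seed) * 1000 + int(round(true_fraction * 100)) + i
        )
        truth = place_cells(spec)
        stack = render_stack(truth, spec, channels=["hoechst", "cspg4", "c1ql1"])
        res = analyze_scene(stack, params)
        ab, b = coexpression_counts(res.expression_calls, "c1ql1", "cspg4")
        n_ab += ab
        n_b += b
        if b:
            per_scene.append(100.0 * ab / b)
    if n_b == 0:
        raise RuntimeError("no lineage-probe-positive nuclei detected in any scene")
    return CoexpressionRecovery(
        true_fraction=true_fraction,
        per_scene_pct=per_scene,
        pooled_pct=100.0 * n_ab / n_b,
    )


@dataclass
class BandRecovery:
    control_thickness_um: list[float]
    ablated_thickness_um: list[float]
    estimated_reduction_pct: float
    true_reduction_pct: float


def band_reduction_recovery(
    seed: int,
    control_um: float = 144.6,
    ablated_um: float = 23.6,
    n_scenes: int = 3,
) -> BandRecovery:
    """Render paired fiber-band cohorts at the measured control/ablated
    band thicknesses and recover the percent reduction via the FWHM
    thickness pipeline."""
    measured: dict[str, list[float]] = {"control": [], "ablated": []}
    for group, thickness in (("control", control_um), ("ablated", ablated_um)):
        for i in range(n_scenes):
            scene_seed = int(seed) * 100 + (0 if group == "control" else 50) + i
            spec = band_scene_spec(thickness, seed=scene_seed)
            truth = place_cells(spec)
            stack = render_stack(truth, spec, channels=["fiber"])
            proj = project(stack, n_planes=stack.n_planes)
            m = band_thickness(proj.plane("fiber"), proj.pixel_size_um)
            measured[group].append(m.thickness_um)
    est = percent_reduction(
        float(np.mean(measured["control"])), float(np.mean(measured["ablated"]))
    )
    return BandRecovery(
        control_thickness_um=measured["control"],
        ablated_thickness_um=measured["ablated"],
        estimated_reduction_pct=est,
        true_reduction_pct=percent_reduction(control_um, ablated_um),
    )
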