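"""Shared fixtures: small noise-free scenes with ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliaquant.pipeline import AnalysisParams, analyze_scene
from gliaquant.segmentation import LabelMap
from gliaquant.synthetic_data import (
    CellClassSpec,
    GroundTruth,
    NoiseSpec,
    TissueSpec,
    place_cells,
    render_stack,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

NOISELESS = NoiseSpec(gaussian_sd=0.0, poisson_scale=0.0)


def clean_marker_spec(seed: int = 42) -> TissueSpec:
    """Noise-free, PSF-free field with well-separated nuclei and two
    marker channels (membrane-ring ng2, somatic cc1)."""
    return TissueSpec(
        region_name="test_field",
        extent_um=(120.0, 120.0, 10.2),
        voxel_size_um=(0.5, 0.5, 0.68),
        classes=(
            CellClassSpec(
                "oligolineage",
                15e4,
                gfp_prob=0.7,
                marker_probs={"ng2": 0.5, "cc1": 0.4},
            ),
        ),
        noise=NOISELESS,
        psf_sigma_um=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_scene():
    """(spec, truth, stack) for a noise-free non-touching marker scene."""
    spec = clean_marker_spec()
    truth = place_cells(spec, min_distance_um=12.0)
    stack = render_stack(truth, spec)
    return spec, truth, stack


@pytest.fixture(scope="session")
def clean_analysis(clean_scene):
    """The clean scene pushed through the full analysis chain."""
    _, _, stack = clean_scene
    return analyze_scene(stack, AnalysisParams())


def match_cells_to_labels(truth: GroundTruth, labelmap: LabelMap) -> dict[int, int]:
    """Map true cell id -> segmented label via centroid containment
    (0 when the centroid falls on background)."""
    dx, dy = labelmap.pixel_size_um
    ny, nx = labelmap.labels.shape
    out = {}
    for c in truth.cells:
        j = min(max(int(c.centroid_um[0] / dx), 0), nx - 1)
        i = min(max(int(c.centroid_um[1] / dy), 0), ny - 1)
        out[c.id] = int(labelmap.labels[i, j])
    return out


def soma_mask(truth: GroundTruth, shape, pixel_size, margin_um: float = 1.5,
              only_gfp: bool = True) -> np.ndarray:
    """Rasterize the true soma footprints (nucleus radius + margin)."""
    dx, dy = pixel_size
    ny, nx = shape
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    mask = np.zeros(shape, dtype=bool)
    for c in truth.cells:
        if only_gfp and not c.gfp:
            continue
        r = c.radii_um[0] + margin_um
        mask |= (ys[:, None] - c.centroid_um[1]) ** 2 + (
            xs[None, :] - c.centroid_um[0]
        ) ** 2 <= r**2
    return mask
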