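"""Puncta detection, per-nucleus surface accumulation and expression calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage as ndi
from scipy import stats as sps

from conftest import match_cells_to_labels
from gliaquant.pipeline import AnalysisParams, analyze_scene
from gliaquant.segmentation import LabelMap, ProjectedImage
from gliaquant.smfish import (
    Punctum,
    accumulate_per_nucleus,
    call_expression,
    coexpression_percentage,
    detect_puncta,
    make_expression_calls,
)
from gliaquant.synthetic_data import (
    CellClassSpec,
    NoiseSpec,
    TissueSpec,
    place_cells,
    render_stack,
)

PIXEL = 0.25


def probe_projection(plane) -> ProjectedImage:
    return ProjectedImage(
        planes={"c1ql1": np.asarray(plane, dtype=float)},
        pixel_size_um=(PIXEL, PIXEL),
        z_planes_used=15,
        z_step_um=0.68,
    )


def spot_plane(coords, shape=(120, 120), amp=1000.0, sigma_px=1.4, bg=20.0):
    plane = np.zeros(shape)
    for (y, x) in coords:
        plane[y, x] = amp
    plane = ndi.gaussian_filter(plane, sigma_px) * (sigma_px**2 * 2 * np.pi)
    return plane + bg


class TestDetectPuncta:
    def test_blank_channel_yields_nothing(self):
        assert detect_puncta(probe_projection(np.full((64, 64), 20.0)), "c1ql1") == []

    def test_separated_spots_all_found_with_subpixel_centroids(self):
        coords = [(20, 20), (20, 60), (60, 30), (80, 90), (40, 100)]
        proj = probe_projection(spot_plane(coords))
        puncta = detect_puncta(proj, "c1ql1")
        assert len(puncta) == len(coords)
        for (y, x) in coords:
            truth = np.array([(x + 0.5) * PIXEL, (y + 0.5) * PIXEL])
            d = min(
                np.hypot(*(np.array(p.centroid_um) - truth)) for p in puncta
            )
            assert d <= PIXEL  # within one pixel

    def test_detection_invariant_to_intensity_scale(self):
        coords = [(20, 20), (60, 80)]
        p1 = detect_puncta(probe_projection(spot_plane(coords)), "c1ql1")
        p5 = detect_puncta(probe_projection(5 * spot_plane(coords)), "c1ql1")
        assert len(p1) == len(p5) == 2
        for a, b in zip(p1, p5):
            assert a.area_um2 == pytest.approx(b.area_um2)

    def test_merged_pair_conserves_total_area(self):
        single = detect_puncta(probe_projection(spot_plane([(40, 40)])), "c1ql1")
        a1 = single[0].area_um2
        # pair at ~2 sigma separation: below the split resolution but the
        # elongated half-peak support still carries both spots' surface
        merged = detect_puncta(
            probe_projection(spot_plane([(40, 40), (40, 43)])), "c1ql1"
        )
        assert 1 <= len(merged) <= 2
        total = sum(p.area_um2 for p in merged)
        assert total == pytest.approx(2 * a1, rel=0.2)


class TestAccumulate:
    def nuclei(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:15, 5:15] = 1
        labels[25:35, 25:35] = 2
        return LabelMap(labels=labels, pixel_size_um=(PIXEL, PIXEL))

    def punctum(self, x_um, y_um, area=0.3):
        return Punctum("c1ql1", (x_um, y_um), area, 100.0)

    def test_centroid_inside_nucleus_credits_that_nucleus_only(self):
        surf = accumulate_per_nucleus([self.punctum(2.5, 2.5)], self.nuclei())
        by = surf.set_index(["label_id", "probe"])["total_surface_um2"]
        assert by[(1, "c1ql1")] == pytest.approx(0.3)
        assert by[(2, "c1ql1")] == 0.0

    def test_punctum_on_background_dropped_without_radius(self):
        surf = accumulate_per_nucleus([self.punctum(5.0, 5.0)], self.nuclei())
        assert surf["total_surface_um2"].sum() == 0.0

    def test_assign_radius_recovers_nearby_punctum(self):
        surf = accumulate_per_nucleus(
            [self.punctum(4.0, 2.5)], self.nuclei(), assign_radius_um=1.0
        )
        by = surf.set_index(["label_id", "probe"])["total_surface_um2"]
        assert by[(1, "c1ql1")] == pytest.approx(0.3)

    def test_assigned_surface_never_exceeds_detected(self):
        rng = np.random.default_rng(0)
        puncta = [
            self.punctum(rng.uniform(0, 10), rng.uniform(0, 10), rng.uniform(0.1, 0.5))
            for _ in range(50)
        ]
        surf = accumulate_per_nucleus(puncta, self.nuclei())
        assert surf["total_surface_um2"].sum() <= sum(p.area_um2 for p in puncta) + 1e-9


class TestExpressionCall:
    def test_strict_boundary_behavior(self):
        assert not call_expression(1.5)
        assert call_expression(1.6)
        assert not call_expression(0.0)
        with pytest.raises(ValueError):
            call_expression(-0.1)

    @given(st.floats(min_value=0.0, max_value=10.0))
    def test_raising_threshold_never_adds_positives(self, thr):
        surfaces = pd.DataFrame(
            {
                "label_id": range(1, 8),
                "probe": ["c1ql1"] * 7,
                "total_surface_um2": [0.0, 0.4, 1.5, 1.6, 2.0, 5.0, 9.9],
            }
        )
        lo = make_expression_calls(surfaces, thr)["positive"]
        hi = make_expression_calls(surfaces, thr + 0.7)["positive"]
        assert not (hi & ~lo).any()


class TestCoexpression:
    def calls(self, rows):
        return pd.DataFrame(
            [
                {"label_id": k, "probe": pr, "positive": v, "total_surface_um2": 2.0 * v}
                for k, (a, b) in enumerate(rows, start=1)
                for pr, v in (("c1ql1", a), ("cspg4", b))
            ]
        )

    def test_all_b_positive_also_a_positive_gives_100(self):
        calls = self.calls([(True, True), (True, True), (False, False)])
        assert coexpression_percentage(calls, "c1ql1", "cspg4") == 100.0

    def test_no_b_positive_reported_missing(self):
        calls = self.calls([(True, False), (False, False)])
        assert coexpression_percentage(calls, "c1ql1", "cspg4") is None

    def test_simple_fraction(self):
        calls = self.calls([(True, True), (False, True), (False, True), (True, False)])
        assert coexpression_percentage(calls, "c1ql1", "cspg4") == pytest.approx(100 / 3)

    def test_within_filter_restricts_denominator(self):
        calls = self.calls([(True, True), (False, True), (True, True)])
        assert coexpression_percentage(calls, "c1ql1", "cspg4", within=[1, 2]) == 50.0


@pytest.fixture(scope="module")
def duplex_scene():
    spec = TissueSpec(
        extent_um=(100.0, 100.0, 10.2),
        voxel_size_um=(0.25, 0.25, 0.68),
        classes=(
            CellClassSpec("opc", 25e4, probe_probs={"cspg4": 0.9, "c1ql1": 0.5}),
        ),
        noise=NoiseSpec(0.0, 0.0),
        psf_sigma_um=0.2,
        seed=77,
    )
    truth = place_cells(spec)
    stack = render_stack(truth, spec, channels=["hoechst", "cspg4", "c1ql1"])
    return spec, truth, analyze_scene(stack, AnalysisParams())

class TestSceneRecovery:
    def test_per_nucleus_surface_tracks_true_puncta_count(self, duplex_scene):
        _, truth, res = duplex_scene
        matches = match_cells_to_labels(truth, res.nuclei)
        surf = res.expression_calls.query("probe == 'c1ql1'").set_index("label_id")[
            "total_surface_um2"
        ]
        pairs = [
            (c.puncta["c1ql1"], surf[matches[c.id]])
            for c in truth.cells
            if matches[c.id] in surf.index
        ]
        counts, surfaces = zip(*pairs)
        rho = sps.spearmanr(counts, surfaces).statistic
        assert rho >= 0.95

    def test_noise_free_calls_match_truth(self, duplex_scene):
        _, truth, res = duplex_scene
        matches = match_cells_to_labels(truth, res.nuclei)
        pos = res.expression_calls.pivot_table(
            index="label_id", columns="probe", values="positive", aggfunc="any"
        )
        agree = total = 0
        for c in truth.cells:
            k = matches[c.id]
            if k not in pos.index:
                continue
            for probe in ("cspg4", "c1ql1"):
                total += 1
                agree += bool(pos.loc[k, probe]) == c.probes[probe]
        assert total > 0
        assert agree / total >= 0.95
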