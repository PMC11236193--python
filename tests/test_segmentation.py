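"""Projection, nucleus segmentation, reporter mask and colocalization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import match_cells_to_labels, soma_mask
from gliaquant.segmentation import (
    LabelMap,
    ProjectedImage,
    SizeFilter,
    apply_size_filter,
    colocalize,
    project,
    segment_nuclei,
    segment_reporter,
)
from gliaquant.synthetic_data import ImageStack


def make_stack(arrays: dict[str, np.ndarray]) -> ImageStack:
    return ImageStack(
        channels=arrays,
        voxel_size_um=(0.5, 0.5, 0.68),
        channel_roles={k: "nuclear" for k in arrays},
    )


def flat_projection(plane, pixel=1.0, channel="img") -> ProjectedImage:
    return ProjectedImage(
        planes={channel: np.asarray(plane, dtype=float)},
        pixel_size_um=(pixel, pixel),
        z_planes_used=1,
        z_step_um=0.68,
    )


class TestProject:
    @pytest.mark.parametrize("method", ["max", "mean", "sum"])
    def test_matches_elementwise_bruteforce(self, method):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 100, size=(15, 9, 7))
        proj = project(make_stack({"a": arr}), n_planes=15, method=method)
        expected = np.zeros((9, 7))
        for i in range(9):
            for j in range(7):
                col = [arr[k, i, j] for k in range(15)]
                expected[i, j] = {
                    "max": max(col),
                    "mean": sum(col) / 15,
                    "sum": sum(col),
                }[method]
        np.testing.assert_allclose(proj.planes["a"], expected)

    def test_constant_stack_projects_to_single_plane(self):
        plane = np.random.default_rng(1).uniform(size=(6, 6))
        arr = np.repeat(plane[None], 10, axis=0)
        for method in ("max", "mean"):
            proj = project(make_stack({"a": arr}), n_planes=10, method=method)
            np.testing.assert_allclose(proj.planes["a"], plane)

    def test_single_plane_is_identity(self):
        arr = np.random.default_rng(2).uniform(size=(4, 5, 5))
        proj = project(make_stack({"a": arr}), n_planes=1)
        np.testing.assert_array_equal(proj.planes["a"], arr[0])

    def test_too_few_planes_error_states_available(self):
        arr = np.zeros((5, 4, 4))
        with pytest.raises(ValueError, match="only 5"):
            project(make_stack({"a": arr}), n_planes=15)

    def test_depth_is_planes_times_step(self):
        arr = np.zeros((15, 4, 4))
        proj = project(make_stack({"a": arr}), n_planes=15)
        assert proj.depth_um == pytest.approx(15 * 0.68)


class TestSegmentNuclei:
    def test_recovers_all_nuclei_in_clean_scene(self, clean_scene):
        _, truth, stack = clean_scene
        proj = project(stack, n_planes=15)
        lm = segment_nuclei(proj)
        matches = match_cells_to_labels(truth, lm)
        hit = [v for v in matches.values() if v > 0]
        # recall and precision >= 0.95; here the clean scene is exact
        assert len(hit) / len(truth) >= 0.95
        assert len(set(hit)) == len(hit)  # no two cells share a label
        assert lm.n_labels <= len(truth) + max(1, int(0.05 * len(truth)))

    def test_blank_image_yields_empty_labelmap(self):
        lm = segment_nuclei(flat_projection(np.full((32, 32), 7.0)), "img")
        assert lm.n_labels == 0

    def test_single_small_nucleus_removed_by_filter(self):
        plane = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        plane[(yy - 20) ** 2 + (xx - 20) ** 2 <= 2**2] = 100.0
        lm = segment_nuclei(
            flat_projection(plane),
            "img",
            size_filter=SizeFilter(50.0, 500.0),
            smooth_sigma_um=0.0,
        )
        assert lm.n_labels == 0

    def test_touching_pair_split_by_watershed(self):
        plane = np.zeros((60, 80))
        yy, xx = np.mgrid[:60, :80]
        for cx in (30, 44):  # 14 px apart, radius 9: overlapping blobs
            plane[(yy - 30) ** 2 + (xx - cx) ** 2 <= 9**2] = 100.0
        lm = segment_nuclei(
            flat_projection(plane),
            "img",
            size_filter=SizeFilter(5.0, 1000.0),
            smooth_sigma_um=1.0,
            min_peak_distance_um=5.0,
        )
        assert lm.n_labels == 2

    def test_labels_invariant_to_intensity_scale(self, clean_scene):
        _, _, stack = clean_scene
        proj = project(stack, n_planes=15)
        scaled = ProjectedImage(
            planes={k: 2.0 * v for k, v in proj.planes.items()},
            pixel_size_um=proj.pixel_size_um,
            z_planes_used=proj.z_planes_used,
            z_step_um=proj.z_step_um,
        )
        np.testing.assert_array_equal(
            segment_nuclei(proj).labels, segment_nuclei(scaled).labels
        )


class TestSizeFilter:
    def test_bounds_are_exact_to_one_pixel(self):
        # component of exactly 100 px at 1 um/px; min_area 100 keeps it,
        # one pixel less is removed
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[:10, :10] = 1
        lm = LabelMap(labels=labels, pixel_size_um=(1.0, 1.0))
        kept = apply_size_filter(lm, SizeFilter(100.0, 1000.0))
        assert kept.n_labels == 1
        labels99 = labels.copy()
        labels99[0, 0] = 0
        lm99 = LabelMap(labels=labels99, pixel_size_um=(1.0, 1.0))
        assert apply_size_filter(lm99, SizeFilter(100.0, 1000.0)).n_labels == 0
        # and symmetrically at the upper bound
        assert apply_size_filter(lm, SizeFilter(1.0, 99.0)).n_labels == 0
        assert apply_size_filter(lm99, SizeFilter(1.0, 99.0)).n_labels == 1

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SizeFilter(10.0, 10.0)
        with pytest.raises(ValueError):
            SizeFilter(0.0, 10.0)


class TestSegmentReporter:
    def test_zero_threshold_gives_full_mask(self):
        proj = flat_projection(np.random.default_rng(0).uniform(1, 9, (16, 16)))
        assert segment_reporter(proj, "img", min_intensity=0.0).all()

    def test_threshold_above_max_gives_empty_mask(self):
        proj = flat_projection(np.random.default_rng(0).uniform(1, 9, (16, 16)))
        assert not segment_reporter(proj, "img", min_intensity=1e6).any()

    def test_mask_area_monotone_in_threshold(self):
        proj = flat_projection(np.random.default_rng(3).uniform(0, 100, (32, 32)))
        areas = [
            segment_reporter(proj, "img", min_intensity=t).sum()
            for t in (0.0, 20.0, 50.0, 80.0, 200.0)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_default_threshold_covers_true_somata(self, clean_scene):
        _, truth, stack = clean_scene
        proj = project(stack, n_planes=15)
        mask = segment_reporter(proj)
        true_soma = soma_mask(truth, mask.shape, proj.pixel_size_um)
        coverage = mask[true_soma].mean()
        false_rate = mask[~true_soma].mean()
        assert coverage >= 0.90
        assert false_rate <= 0.01


class TestColocalize:
    def test_full_mask_flags_all_and_empty_mask_none(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 2
        lm = LabelMap(labels=labels, pixel_size_um=(1.0, 1.0))
        assert colocalize(lm, np.ones((20, 20), bool)) == {1: True, 2: True}
        assert colocalize(lm, np.zeros((20, 20), bool)) == {1: False, 2: False}

    def test_shape_mismatch_rejected(self):
        lm = LabelMap(labels=np.ones((4, 4), dtype=np.int32), pixel_size_um=(1, 1))
        with pytest.raises(ValueError, match="shape"):
            colocalize(lm, np.ones((5, 5), bool))

    @given(st.floats(min_value=0.05, max_value=1.0))
    def test_flags_monotone_in_overlap_fraction(self, frac):
        rng = np.random.default_rng(7)
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[5:15, 5:15] = 1
        labels[18:28, 18:28] = 2
        lm = LabelMap(labels=labels, pixel_size_um=(1.0, 1.0))
        mask = rng.random((30, 30)) < 0.5
        strict = colocalize(lm, mask, overlap_fraction=min(1.0, frac + 0.2))
        loose = colocalize(lm, mask, overlap_fraction=frac)
        for k in strict:
            assert loose[k] or not strict[k]

    def test_recovers_reporter_state_in_clean_scene(self, clean_scene, clean_analysis):
        _, truth, _ = clean_scene
        res = clean_analysis
        matches = match_cells_to_labels(truth, res.nuclei)
        for cell in truth.cells:
            label = matches[cell.id]
            if label:
                assert res.gfp_flags[label] == cell.gfp
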