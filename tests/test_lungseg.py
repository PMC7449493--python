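"""Lung segmentation pipeline: per-stage oracles and end-to-end phantom
checks."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from conftest import small_spec
from helpers import brute_force_otsu, flood_fill_components
from pulmocad.lungseg import (
    DegenerateVolumeError,
    SegmentationConfig,
    TracheaNotFoundError,
    binarize_adaptive,
    detect_fusion,
    dice,
    extract_main_trachea,
    fill_body,
    reconstruct_bronchi,
    remove_background,
    repair_boundary,
    segment_lungs,
    separate_lungs,
)
from pulmocad.phantom import generate_phantom
from pulmocad.volume_io import CTVolume

S3 = np.ones((3, 3, 3), dtype=bool)


class TestBinarize:
    def test_two_level_volume_separates_exactly(self, rng):
        vox = np.where(rng.random((10, 10, 10)) < 0.4, -800.0, 40.0)
        mask = binarize_adaptive(CTVolume(vox))
        assert np.array_equal(mask, vox == -800.0)

    def test_matches_brute_force_otsu(self, rng):
        vox = np.concatenate(
            [rng.normal(-700, 80, 4000), rng.normal(30, 60, 6000)]
        ).reshape(10, 10, 100)
        mask = binarize_adaptive(CTVolume(vox))
        thr = brute_force_otsu(vox)
        assert np.array_equal(mask, vox < thr)

    def test_constant_volume_errors(self):
        with pytest.raises(DegenerateVolumeError):
            binarize_adaptive(CTVolume(np.zeros((4, 4, 4))))


class TestRemoveBackground:
    def test_phantom_keeps_three_interior_structures(self, default_phantom):
        vol, _ = default_phantom
        cleaned = remove_background(binarize_adaptive(vol))
        assert ndimage.label(cleaned, structure=S3)[1] == 3

    def test_flood_fill_oracle_on_tiny_fixture(self):
        mask = np.zeros((6, 8, 8), dtype=bool)
        mask[:, :, 0] = True  # touches lateral face -> removed
        mask[2:4, 2:4, 3:5] = True
        mask[1, 6, 6] = True
        out = remove_background(mask)
        assert flood_fill_components(out) == 2
        assert not out[:, :, 0].any()

    def test_fully_border_connected_becomes_empty(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        assert remove_background(mask).sum() == 0

    def test_interior_blob_unchanged(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        assert np.array_equal(remove_background(mask), mask)

    def test_empty_mask_returns_empty(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        assert remove_background(m).sum() == 0


class TestFillBody:
    def test_cavity_filled_solid_unchanged(self):
        comp = np.zeros((3, 9, 9), dtype=bool)
        comp[:, 2:7, 2:7] = True
        solid = comp.copy()
        comp[:, 4, 4] = False  # internal cavity
        assert np.array_equal(fill_body(comp), solid)
        assert np.array_equal(fill_body(solid), solid)

    def test_rough_mask_dice_against_truth(self, default_phantom):
        vol, truth = default_phantom
        rough = fill_body(remove_background(binarize_adaptive(vol)), vol)
        reference = truth.lung_mask | truth.trachea_mask
        assert dice(rough, reference) >= 0.95


class TestTrachea:
    def test_phantom_trachea_recovered(self, default_phantom):
        vol, truth = default_phantom
        rough = fill_body(remove_background(binarize_adaptive(vol)), vol)
        grown = extract_main_trachea(vol, rough)
        overlap = (grown & truth.trachea_mask).sum() / truth.trachea_mask.sum()
        leak = (grown & truth.lung_mask).sum() / max(grown.sum(), 1)
        assert overlap >= 0.90
        assert leak <= 0.05

    def test_no_tube_signals_not_found(self):
        vox = np.full((20, 30, 30), 40.0)
        vox[10:15, 10:20, 10:20] = -800.0  # dark blob far from the top slices
        mask = vox < -400
        with pytest.raises(TracheaNotFoundError):
            extract_main_trachea(CTVolume(vox), mask)

    def test_explosion_rule_stops_before_leak_threshold(self):
        """Tube joined to a large cavity through a neck at -700: the
        returned growth must stop below that level (exhaustive-sweep oracle
        confirms the volume jump there)."""
        vox = np.full((30, 40, 40), 40.0)
        vox[0:20, 18:23, 18:23] = -1000.0  # tube from the top
        vox[22:29, 5:35, 5:35] = -1000.0  # large cavity
        vox[20:22, 19:22, 19:22] = -700.0  # narrow neck at theta*
        vol = CTVolume(vox)
        rough = vox < -400
        config = SegmentationConfig(growth_max_threshold=-300.0)
        grown = extract_main_trachea(vol, rough, config)
        cavity = np.zeros_like(rough)
        cavity[22:29, 5:35, 5:35] = True
        assert (grown & cavity).sum() == 0  # stopped before flooding
        assert grown[5, 20, 20]  # but did grow the tube
        # oracle: sweeping thresholds shows the volume explodes past -700
        def region_volume(theta):
            labels, _ = ndimage.label(vox < theta, structure=S3)
            return (labels == labels[0, 20, 20]).sum()
        assert region_volume(-680.0) > 1.5 * region_volume(-720.0)


class TestBronchi:
    def test_no_thin_structures_gives_empty_mask(self):
        vox = np.full((10, 20, 20), -800.0)
        mask = np.zeros((10, 20, 20), dtype=bool)
        mask[2:8, 4:16, 4:16] = True
        out = reconstruct_bronchi(CTVolume(vox), mask)
        assert out.sum() == 0

    def test_reconstruction_ordering(self, default_phantom):
        vol, truth = default_phantom
        rough = fill_body(remove_background(binarize_adaptive(vol)), vol)
        parenchyma = rough & ~truth.trachea_mask
        _, recon, marker, img = reconstruct_bronchi(
            vol, parenchyma, return_internals=True
        )
        assert (recon >= img - 1e-9).all()
        assert (recon <= marker + 1e-9).all()

    def test_bronchi_recovered_from_parenchyma(self, default_phantom):
        vol, truth = default_phantom
        rough = fill_body(remove_background(binarize_adaptive(vol)), vol)
        parenchyma = rough & ~truth.trachea_mask
        bronchi = reconstruct_bronchi(vol, parenchyma)
        frac = (bronchi & truth.bronchi_mask).sum() / truth.bronchi_mask.sum()
        assert frac >= 0.80


class TestFusionDetection:
    def make_mask(self, areas):
        mask = np.zeros((1, 20, sum(areas) + 10 * len(areas)), dtype=bool)
        x = 2
        for a in areas:
            mask[0, 5, x : x + a] = True
            x += a + 5
        return mask

    def test_ratio_rule_cases(self):
        assert detect_fusion(self.make_mask([100, 20])) is True  # 5 > 4
        assert detect_fusion(self.make_mask([100, 90])) is False  # 1.11
        assert detect_fusion(self.make_mask([100])) is True  # A2 = 0 limit

    def test_absolute_mode(self):
        cfg = SegmentationConfig(fusion_mode="absolute", fusion_threshold=15)
        assert detect_fusion(self.make_mask([100, 80]), cfg) is True
        assert detect_fusion(self.make_mask([100, 90]), cfg) is False

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            detect_fusion(np.zeros((2, 2, 2), dtype=bool))


class TestSeparation:
    def test_bridge_fixture_line_at_known_column(self):
        """Two tall blocks joined by a thin bridge at column 30: the
        projection minimum sits on the bridge (hand oracle)."""
        mask = np.zeros((5, 40, 60), dtype=bool)
        mask[:, 2:38, 10:30] = True
        mask[:, 2:38, 31:50] = True
        mask[:, 18:21, 30] = True  # 1-wide bridge at column 30
        out, line = separate_lungs(mask)
        assert set(line.values()) == {30}
        assert ndimage.label(out, structure=S3)[1] == 2

    def test_fused_phantom_separates_into_matching_lungs(
        self, fused_phantom, fused_segmentation
    ):
        _, truth = fused_phantom
        res = fused_segmentation
        assert ndimage.label(res.lung_mask, structure=S3)[1] == 2
        assert dice(res.left_mask, truth.left_lung_mask) >= 0.9
        assert dice(res.right_mask, truth.right_lung_mask) >= 0.9

    def test_not_fused_identity(self):
        mask = np.zeros((3, 20, 40), dtype=bool)
        mask[:, 5:15, 5:15] = True
        mask[:, 5:15, 25:35] = True
        out, line = separate_lungs(mask)
        assert np.array_equal(out, mask)
        assert line == {}


class TestRepairBoundary:
    @staticmethod
    def disc_with_notch(R, r_notch):
        n = 2 * R + 30
        c = n // 2
        yy, xx = np.ogrid[:n, :n]
        disc = (yy - c) ** 2 + (xx - c) ** 2 <= R * R
        notch = (yy - c) ** 2 + (xx - (c - R)) ** 2 <= r_notch * r_notch
        return (disc & ~notch)[None], (disc & notch)[None]

    def test_convex_component_unchanged(self):
        mask, _ = self.disc_with_notch(30, 0)
        assert np.array_equal(repair_boundary(mask), mask)

    def test_small_notch_filled_large_not(self):
        small_mask, small_notch = self.disc_with_notch(50, 5)
        big_mask, big_notch = self.disc_with_notch(50, 30)
        rep_small = repair_boundary(small_mask)
        rep_big = repair_boundary(big_mask)
        frac_small = (rep_small & small_notch).sum() / small_notch.sum()
        frac_big = (rep_big & big_notch).sum() / big_notch.sum()
        assert frac_small >= 0.6
        assert frac_big <= 0.05

    def test_agrees_with_independent_closing(self):
        """Per-slice repair equals skimage's own binary closing (padded)."""
        mask, _ = self.disc_with_notch(40, 8)
        rep = repair_boundary(mask)
        disk = morphology.disk(13)
        pad = 14
        padded = np.pad(mask[0], pad)
        oracle = morphology.closing(padded, disk)[pad:-pad, pad:-pad]
        assert np.array_equal(rep[0], oracle | mask[0])

    def test_output_superset_of_input(self, notch_segmentation):
        res = notch_segmentation
        assert (res.stages.repaired & ~res.stages.separated).sum() >= 0
        assert not (res.stages.separated & ~res.stages.repaired).any()

    def test_phantom_notch_restored(self, notch_phantom, notch_segmentation):
        _, truth = notch_phantom
        res = notch_segmentation
        frac = (res.lung_mask & truth.notch_mask).sum() / truth.notch_mask.sum()
        assert frac >= 0.90

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            repair_boundary(
                np.ones((1, 4, 4), bool), (1, 1, 1), SegmentationConfig(ball_radius_mm=0)
            )


class TestPipeline:
    def test_default_phantom_end_to_end(self, default_phantom, default_segmentation):
        _, truth = default_phantom
        res = default_segmentation
        assert dice(res.lung_mask, truth.lung_mask) >= 0.90
        overlap = (res.lung_mask & truth.trachea_mask).sum() / truth.trachea_mask.sum()
        assert overlap <= 0.05
        assert res.fused_detected is False

    def test_fused_phantom_detected_and_split(self, fused_segmentation):
        res = fused_segmentation
        assert res.fused_detected is True
        assert ndimage.label(res.lung_mask, structure=S3)[1] == 2

    def test_left_right_partition_exact(self, default_segmentation):
        res = default_segmentation
        assert not (res.left_mask & res.right_mask).any()
        assert np.array_equal(res.left_mask | res.right_mask, res.lung_mask)

    def test_stage_monotonicity(self, default_segmentation):
        st = default_segmentation.stages
        # subtractions only remove voxels; repair only adds
        assert not (st.fused_check_input & ~st.body_filled).any()
        assert not (st.separated & ~st.repaired).any()

    def test_all_air_volume_errors(self):
        with pytest.raises(DegenerateVolumeError):
            segment_lungs(CTVolume(np.full((8, 8, 8), -1000.0)))

    def test_pipeline_deterministic(self):
        vol, _ = generate_phantom(small_spec())
        r1 = segment_lungs(vol)
        r2 = segment_lungs(vol)
        assert np.array_equal(r1.lung_mask, r2.lung_mask)
        assert r1.separation_line == r2.separation_line
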