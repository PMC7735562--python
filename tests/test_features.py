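import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from npcscreen.features import (FeatureConfig, FieldFeatures, QC_NO_OBJECTS,
                                QC_OK, aggregate_well, circularity,
                                compute_field_features, gfp_int,
                                small_obj_ratio)
from npcscreen.io_plate import Channel, ImageField, ValidationError
from npcscreen.segmentation import LabelMap
from npcscreen.synthetic_plate import PhenotypeParams, render_field

from conftest import as_field


def _label_map(mask):
    from scipy import ndimage as ndi
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    return LabelMap(labels)


class TestCircularity:
    def test_disc_scores_near_one(self):
        img = np.zeros((128, 128), dtype=bool)
        rr, cc = draw_disk((64, 64), 50)
        img[rr, cc] = True
        assert 0.95 <= circularity(_label_map(img)) <= 1.0

    def test_square_scores_near_pi_over_four(self):
        img = np.zeros((128, 128), dtype=bool)
        img[10:110, 10:110] = True
        assert circularity(_label_map(img)) == pytest.approx(math.pi / 4, abs=0.05)

    def test_thin_line_scores_low(self):
        img = np.zeros((220, 16), dtype=bool)
        img[10:210, 8] = True
        assert circularity(_label_map(img)) < 0.1

    def test_empty_map_gives_nan(self):
        assert math.isnan(circularity(LabelMap(np.zeros((16, 16), dtype=np.int32))))

    def test_mean_over_objects(self):
        # disc (~1) and long line (<0.1) in one map: mean strictly between
        img = np.zeros((300, 300), dtype=bool)
        rr, cc = draw_disk((80, 80), 30)
        img[rr, cc] = True
        img[200, 20:280] = True
        score = circularity(_label_map(img))
        assert 0.4 < score < 0.6

    def test_area_oracle_on_small_shapes(self):
        """Per-object pixel counts match a brute-force enumeration on a
        library of small shapes."""
        rng = np.random.default_rng(1)
        img = rng.random((20, 20)) < 0.3
        lm = _label_map(img)
        for lbl in range(1, lm.n_objects + 1):
            brute = sum(1 for r in range(20) for c in range(20)
                        if lm.labels[r, c] == lbl)
            assert lm.areas_px[lbl - 1] == brute
        # the reported score is exactly 4*pi*A/P^2, clamped, averaged
        scores = np.minimum(1.0, 4 * math.pi * lm.areas_px / lm.perimeters_px**2)
        assert circularity(lm) == pytest.approx(scores.mean())


class TestSmallObjRatio:
    def _two_objects(self, a1, a2):
        img = np.zeros((200, 400), dtype=bool)
        img[10:10 + a1 // 10, 10:20] = True          # area a1
        img[100:100 + a2 // 20, 100:120] = True      # area a2
        lm = _label_map(img)
        assert sorted(lm.areas_px) == sorted([a1, a2])
        return lm

    def test_worked_value(self):
        lm = self._two_objects(100, 900)
        assert small_obj_ratio(lm, FeatureConfig(small_obj_area_px=500)) == \
            pytest.approx(0.1)

    def test_all_small_gives_one(self):
        lm = self._two_objects(100, 200)
        assert small_obj_ratio(lm, FeatureConfig(small_obj_area_px=500)) == 1.0

    def test_all_large_gives_zero(self):
        lm = self._two_objects(600, 900)
        assert small_obj_ratio(lm, FeatureConfig(small_obj_area_px=500)) == 0.0

    def test_strict_at_threshold(self):
        lm = self._two_objects(500, 900)
        assert small_obj_ratio(lm, FeatureConfig(small_obj_area_px=500)) == 0.0

    def test_empty_map_gives_nan(self):
        assert math.isnan(small_obj_ratio(
            LabelMap(np.zeros((16, 16), dtype=np.int32)), FeatureConfig()))


class TestGfpInt:
    def test_arithmetic(self):
        px = np.zeros((64, 64))
        px[0:10, 0:5] = 1.0                           # 50 intensity units
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[0:10, 0:5] = 1
        cells = np.zeros((64, 64), dtype=bool)
        cells[:25, :40] = True                        # 1000 px
        value = gfp_int(as_field(px), LabelMap(labels), cells)
        assert value == pytest.approx(0.05)

    def test_empty_pattern_gives_zero(self):
        px = np.full((64, 64), 0.5)
        cells = np.ones((64, 64), dtype=bool)
        assert gfp_int(as_field(px), LabelMap(np.zeros((64, 64), dtype=np.int32)),
                       cells) == 0.0

    def test_linearity_in_intensity(self):
        rng = np.random.default_rng(0)
        px = rng.random((64, 64)) * 0.5
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[10:30, 10:30] = 1
        cells = np.ones((64, 64), dtype=bool)
        v1 = gfp_int(as_field(px), LabelMap(labels), cells)
        v2 = gfp_int(as_field(2 * px), LabelMap(labels), cells)
        assert v2 == pytest.approx(2 * v1)

    def test_empty_cell_mask_gives_nan(self):
        px = np.full((64, 64), 0.5)
        labels = np.zeros((64, 64), dtype=np.int32)
        assert math.isnan(gfp_int(as_field(px), LabelMap(labels),
                                  np.zeros((64, 64), dtype=bool)))


class TestComputeFieldFeatures:
    def test_blank_field_flagged(self, screen_cfg, feat_cfg):
        gfp = ImageField(np.zeros((256, 256)), Channel.GFP)
        hoechst = ImageField(np.zeros((256, 256)), Channel.HOECHST)
        f = compute_field_features(gfp, hoechst, screen_cfg, feat_cfg)
        assert f.n_objects == 0
        assert f.qc == QC_NO_OBJECTS
        assert math.isnan(f.circularity)

    def test_punctate_scores_above_reticular(self, screen_cfg, feat_cfg):
        """Paired over seeds, the punctate phenotype scores strictly higher
        in circularity and small-object ratio than the reticular one."""
        lo_c, hi_c, lo_s, hi_s = [], [], [], []
        for seed in range(8):
            g, h, _ = render_field(PhenotypeParams(theta=0.1), 512, 512,
                                   seed=1000 + seed)
            f = compute_field_features(g, h, screen_cfg, feat_cfg)
            lo_c.append(f.circularity)
            lo_s.append(f.small_obj_ratio)
            g, h, _ = render_field(PhenotypeParams(theta=0.9), 512, 512,
                                   seed=1000 + seed)
            f = compute_field_features(g, h, screen_cfg, feat_cfg)
            hi_c.append(f.circularity)
            hi_s.append(f.small_obj_ratio)
        assert np.median(hi_c) > np.median(lo_c)
        assert np.median(hi_s) > np.median(lo_s)

    def test_rotation_invariance(self, screen_cfg, feat_cfg):
        gfp, hoechst, _ = render_field(
            PhenotypeParams(theta=0.8, n_cells=3), 360, 360, seed=11,
            margin_px=80)
        g90 = ImageField(np.rot90(gfp.pixels).copy(), Channel.GFP)
        h90 = ImageField(np.rot90(hoechst.pixels).copy(), Channel.HOECHST)
        a = compute_field_features(gfp, hoechst, screen_cfg, feat_cfg)
        b = compute_field_features(g90, h90, screen_cfg, feat_cfg)
        assert a.n_objects == b.n_objects
        assert a.npc1_area_px == b.npc1_area_px
        assert a.circularity == pytest.approx(b.circularity, abs=1e-6)
        assert a.small_obj_ratio == pytest.approx(b.small_obj_ratio, abs=1e-6)
        assert a.gfp_int == pytest.approx(b.gfp_int, abs=1e-6)

    def test_shape_features_stable_under_gain(self, screen_cfg, feat_cfg):
        """Circularity and small-object ratio barely move under a uniform
        intensity gain of 0.8x / 1.2x (threshold-stable fixtures)."""
        gfp, hoechst, _ = render_field(
            PhenotypeParams(theta=0.9, noise_sd=0.001), 512, 512, seed=21)
        ref = compute_field_features(gfp, hoechst, screen_cfg, feat_cfg)
        for gain in (0.8, 1.2):
            g = ImageField(np.clip(gfp.pixels * gain, 0, 1), Channel.GFP)
            f = compute_field_features(g, hoechst, screen_cfg, feat_cfg)
            assert f.circularity == pytest.approx(ref.circularity, abs=0.05)
            assert f.small_obj_ratio == pytest.approx(ref.small_obj_ratio, abs=0.1)

    def test_shape_mismatch_rejected(self, screen_cfg, feat_cfg):
        gfp = ImageField(np.zeros((256, 256)), Channel.GFP)
        hoechst = ImageField(np.zeros((256, 320)), Channel.HOECHST)
        with pytest.raises(ValidationError):
            compute_field_features(gfp, hoechst, screen_cfg, feat_cfg)


def _field(circ=0.5, sor=0.2, qc=QC_OK):
    return FieldFeatures(circularity=circ, small_obj_ratio=sor, gfp_int=0.05,
                         npc1_area_px=1000, cell_area_px=50000, n_nuclei=30,
                         mean_nuc_area_px=3000.0, n_objects=40, qc=qc)


class TestAggregateWell:
    def _agg(self, fields, **kw):
        return aggregate_well(fields, "P1", "A01", "DMSO", 0.0, "vehicle", **kw)

    def test_identical_fields_reproduce_field(self):
        rec = self._agg([_field()] * 6)
        assert rec.circularity == pytest.approx(0.5)
        assert rec.n_valid_fields == 6
        assert rec.qc_flag == QC_OK

    def test_mean_of_two(self):
        rec = self._agg([_field(circ=0.2), _field(circ=0.4)],
                        fcfg=FeatureConfig(min_fields_for_valid_well=2))
        assert rec.circularity == pytest.approx(0.3)

    def test_mostly_invalid_well_flagged(self):
        nan = float("nan")
        fields = [_field()] + [
            FieldFeatures(nan, nan, nan, 0, 0, 0, nan, 0, qc=QC_NO_OBJECTS)
        ] * 5
        rec = self._agg(fields)
        assert rec.n_valid_fields == 1
        assert rec.qc_flag == QC_NO_OBJECTS

    def test_zero_fields_rejected(self):
        with pytest.raises(ValidationError):
            self._agg([])
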