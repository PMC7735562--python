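import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from npcscreen.downstream_quant import (DegenerateClusteringError,
                                        FilipinThresholds, coloc_correlation,
                                        compare_groups,
                                        filipin_cluster_thresholds,
                                        relative_filipin_intensity)
from npcscreen.io_plate import Channel, ImageField, ValidationError
from npcscreen.synthetic_plate import render_filipin_field

from conftest import as_field


def _field_from_values(values, shape=(64, 64), channel=Channel.FILIPIN):
    px = np.resize(np.asarray(values, dtype=float), shape)
    return ImageField(np.clip(px, 0, 1), channel)


def _dp_kmeans_1d(x, k):
    """Exhaustive optimal 1-D k-means by dynamic programming over sorted
    breakpoints; independent oracle for the clustering."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def cost(i, j):           # sse of x[i:j]
        s, s2, m = pref[j] - pref[i], pref2[j] - pref2[i], j - i
        return s2 - s * s / m

    dp = np.full((k + 1, n + 1), np.inf)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                c = dp[kk - 1, i] + cost(i, j)
                if c < dp[kk, j]:
                    dp[kk, j], arg[kk, j] = c, i
    bounds = [n]
    for kk in range(k, 0, -1):
        bounds.append(arg[kk, bounds[-1]])
    bounds = bounds[::-1]
    return [x[bounds[i]:bounds[i + 1]].mean() for i in range(k)]


class TestFilipinClusterThresholds:
    def _three_population_images(self, means=(0.05, 0.30, 0.80), sd=0.02,
                                 seed=0):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(m, sd, 3000) for m in means])
        rng.shuffle(vals)
        return [_field_from_values(vals, shape=(95, 95))]

    def test_recovers_generating_means_and_midpoints(self):
        t = filipin_cluster_thresholds(self._three_population_images(),
                                       subsample=6000, seed=1)
        for got, want in zip(t.cluster_means, (0.05, 0.30, 0.80)):
            assert got == pytest.approx(want, abs=0.02)
        assert t.lower_threshold == pytest.approx(0.175, abs=0.02)
        assert t.higher_threshold == pytest.approx(0.55, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_small_sample(self, seed):
        # a duck-typed stub keeps the sample small enough for the O(k n^2)
        # dynamic-programming oracle; subsample == pixel count makes the
        # clustered multiset identical to the oracle's input
        class _Stub:
            def __init__(self, px):
                self.pixels = px

        rng = np.random.default_rng(seed)
        vals = np.clip(np.concatenate([rng.normal(m, 0.02, 60)
                                       for m in (0.1, 0.4, 0.8)]), 0, 1)
        t = filipin_cluster_thresholds([_Stub(vals.reshape(18, 10))],
                                       subsample=180, seed=0)
        oracle = _dp_kmeans_1d(vals, 3)
        for got, want in zip(t.cluster_means, oracle):
            assert got == pytest.approx(want, abs=1e-6)

    def test_constant_images_degenerate(self):
        img = _field_from_values(np.full(4096, 0.5))
        with pytest.raises(DegenerateClusteringError):
            filipin_cluster_thresholds([img], subsample=1000, seed=0)

    def test_deterministic_under_seed(self):
        imgs = self._three_population_images()
        a = filipin_cluster_thresholds(imgs, subsample=5000, seed=3)
        b = filipin_cluster_thresholds(imgs, subsample=5000, seed=3)
        assert a == b

    def test_mean_recovery_across_seeds(self):
        """Cluster means recovered within +-0.02 on well-separated mixtures
        over 20 seeds."""
        for seed in range(20):
            t = filipin_cluster_thresholds(
                self._three_population_images(seed=seed), subsample=6000,
                seed=seed)
            for got, want in zip(t.cluster_means, (0.05, 0.30, 0.80)):
                assert got == pytest.approx(want, abs=0.02)


THRESHOLDS = FilipinThresholds((0.02, 0.3, 0.9), 0.15, 0.6)


class TestRelativeFilipinIntensity:
    def test_all_signal_in_puncta_gives_one(self):
        # thresholds placed so the mean-filter transition ring around the
        # bright block falls below the cell threshold: every cell pixel is
        # then also a puncta pixel
        px = np.zeros((64, 64))
        px[20:40, 20:40] = 0.95
        t = FilipinThresholds((0.5, 0.87, 0.95), 0.86, 0.93)
        res = relative_filipin_intensity(as_field(px, Channel.FILIPIN), t)
        assert res.relative_filipin == pytest.approx(1.0, abs=1e-6)
        assert res.puncta_area_px == res.cell_area_px > 0

    def test_no_pixel_above_higher_threshold_gives_zero(self):
        px = np.zeros((64, 64))
        px[10:40, 10:40] = 0.3
        res = relative_filipin_intensity(as_field(px, Channel.FILIPIN),
                                         THRESHOLDS)
        assert res.relative_filipin == 0.0
        assert res.puncta_area_px == 0

    def test_empty_cell_region_flagged(self):
        res = relative_filipin_intensity(as_field(np.zeros((64, 64)),
                                                  Channel.FILIPIN), THRESHOLDS)
        assert math.isnan(res.relative_filipin)
        assert res.qc == "no_cells"

    def test_invariant_under_joint_gain(self):
        rng = np.random.default_rng(0)
        px = np.clip(rng.random((64, 64)), 0, 1)
        base = relative_filipin_intensity(as_field(px, Channel.FILIPIN),
                                          THRESHOLDS)
        gained = relative_filipin_intensity(
            as_field(0.5 * px, Channel.FILIPIN),
            FilipinThresholds((0.01, 0.15, 0.45), 0.075, 0.3))
        assert gained.relative_filipin == pytest.approx(base.relative_filipin)
        assert gained.cell_area_px == base.cell_area_px

    def test_monotone_in_generated_accumulation(self):
        """Median readout increases strictly across generated accumulation
        levels, with thresholds derived once from the pooled set."""
        levels = (0.1, 0.5, 0.9)
        imgs = {af: [render_filipin_field(af, 12, seed=s)[0]
                     for s in range(10)] for af in levels}
        pooled = [im for af in levels for im in imgs[af][:4]]
        t = filipin_cluster_thresholds(pooled, seed=0)
        medians = [np.median([relative_filipin_intensity(im, t).relative_filipin
                              for im in imgs[af]]) for af in levels]
        assert medians[0] < medians[1] < medians[2]


class TestColocCorrelation:
    def _mask(self, shape=(64, 64)):
        return np.ones(shape, dtype=bool)

    def _noise_pair(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.random((100, 100))
        b = rng.random((100, 100))
        return (ImageField(a, Channel.GFP), ImageField(b, Channel.MARKER))

    def test_self_correlation_is_one(self):
        g, _ = self._noise_pair()
        m = ImageField(g.pixels.copy(), Channel.MARKER)
        assert coloc_correlation(g, m, self._mask((100, 100))) == \
            pytest.approx(1.0)

    def test_complement_is_minus_one(self):
        g, _ = self._noise_pair()
        m = ImageField(1.0 - g.pixels, Channel.MARKER)
        assert coloc_correlation(g, m, self._mask((100, 100))) == \
            pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        g, m = self._noise_pair(seed=5)
        assert abs(coloc_correlation(g, m, self._mask((100, 100)))) < 0.05

    def test_symmetric_and_affine_invariant(self):
        g, m = self._noise_pair(seed=7)
        mask = self._mask((100, 100))
        r = coloc_correlation(g, m, mask)
        assert coloc_correlation(
            ImageField(m.pixels, Channel.GFP),
            ImageField(g.pixels, Channel.MARKER), mask) == pytest.approx(r)
        scaled = ImageField(np.clip(0.5 * g.pixels + 0.1, 0, 1), Channel.GFP)
        assert coloc_correlation(scaled, m, mask) == pytest.approx(r)

    def test_zero_variance_gives_nan(self):
        g = ImageField(np.full((64, 64), 0.5), Channel.GFP)
        m = ImageField(np.random.default_rng(0).random((64, 64)), Channel.MARKER)
        assert math.isnan(coloc_correlation(g, m, self._mask()))

    def test_tiny_mask_rejected(self):
        g, m = self._noise_pair()
        mask = np.zeros((100, 100), dtype=bool)
        mask[:5, :5] = True
        with pytest.raises(ValidationError):
            coloc_correlation(g, m, mask)


class TestCompareGroups:
    def test_null_type_one_error_rate(self):
        """Three same-distribution groups: omnibus p > 0.05 in >= 18 of 20
        seeded replicates."""
        calm = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = {g: rng.normal(0, 1, 20) for g in "abc"}
            res = compare_groups(groups, method="kruskal_dunn_bh")
            calm += res.omnibus_p > 0.05
        assert calm >= 18

    def test_dunnett_detects_large_effect(self):
        rng = np.random.default_rng(1)
        groups = {"control": rng.normal(0, 1, 10),
                  "treated": rng.normal(3, 1, 10)}
        res = compare_groups(groups, method="dunnett", control="control")
        assert res.pairwise["p_adj"].iloc[0] < 0.01
        assert set(res.preconditions["test"]) == {"shapiro_wilk", "bartlett"}

    def test_identical_constant_groups_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups({"a": [1.0] * 5, "b": [1.0] * 5})

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})

    def test_dunn_pairwise_covers_all_pairs_with_bh(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(i, 1, 8) for i, g in enumerate("abcd")}
        res = compare_groups(groups, method="kruskal_dunn_bh")
        assert len(res.pairwise) == len(list(itertools.combinations("abcd", 2)))
        assert (res.pairwise["p_adj"] >= res.pairwise["p"] - 1e-12).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(2, 12))
    def test_bh_adjustment_monotone_and_order_preserving(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.random(n)
        adj = multipletests(p, method="fdr_bh")[1]
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
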