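"""Regional averaging, windowed AUC, exact U test and effect sizes."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import ufd_hemo as u
from ufd_hemo.regional_stats import RegionSet, RegionTimeSeries


def series(times, values, artifact=None):
    return RegionTimeSeries(region="r", times=np.asarray(times, float),
                            values=np.asarray(values, float),
                            artifact=artifact)


def brute_force_exact_p(a, b, alternative):
    """Independent oracle: enumerate labelings, count U by pair comparison."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group1, group2):
        u_val = 0.0
        for x in group1:
            for y in group2:
                if x > y:
                    u_val += 1.0
                elif x == y:
                    u_val += 0.5
        return u_val

    u_obs = u_stat(a, b)
    mu = n1 * len(b) / 2.0
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(g1, g2))
    us = np.asarray(us)
    if alternative == "greater":
        count = np.sum(us >= u_obs - 1e-9)
    elif alternative == "less":
        count = np.sum(us <= u_obs + 1e-9)
    else:
        count = np.sum(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9)
    return u_obs, count / us.size


class TestRegionSet:
    def test_default_regions_nested_in_whole_slice(self):
        rs = u.default_region_set((64, 64))
        for name in ("cortex", "hippocampus", "thalamus"):
            assert rs[name].sum() > 0
            assert np.all(rs["whole_slice"] | ~rs[name])

    def test_depth_layers_partition_cortex_band(self):
        rs = u.default_region_set((64, 64), n_depth_layers=3)
        layers = sum(rs[f"cortex_layer_{i}"].sum() for i in range(3))
        assert layers == rs["cortex"].sum()

    def test_missing_whole_slice_rejected(self):
        with pytest.raises(ValueError):
            RegionSet({"cortex": np.ones((4, 4), bool)})

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            RegionSet({"whole_slice": np.ones((4, 4), bool),
                       "cortex": np.zeros((4, 4), bool)})


class TestSpatialAverage:
    def test_uniform_map(self):
        vals = np.full((8, 8), 150.0)
        assert u.spatial_average(vals, np.ones((8, 8), bool)) == 150.0

    def test_half_and_half(self):
        vals = np.zeros((2, 2))
        vals[:, 1] = 100.0
        assert u.spatial_average(vals, np.ones((2, 2), bool)) == 50.0

    def test_undefined_pixels_excluded(self):
        vals = np.array([[np.nan, 30.0], [60.0, np.nan]])
        assert u.spatial_average(vals, np.ones((2, 2), bool)) == 45.0

    def test_fully_undefined_region_warns_nan(self):
        vals = np.full((2, 2), np.nan)
        with pytest.warns(UserWarning):
            assert np.isnan(u.spatial_average(vals, np.ones((2, 2), bool)))


class TestNormalizedAuc:
    def test_constant_series(self):
        s = series([0, 10, 20, 40], [50.0] * 4)
        assert u.normalized_auc(s, 7, 37) == pytest.approx(50.0)

    def test_linear_ramp(self):
        s = series([7, 37], [0.0, 100.0])
        assert u.normalized_auc(s, 7, 37) == pytest.approx(50.0)

    def test_zero_series(self):
        s = series([0, 40], [0.0, 0.0])
        assert u.normalized_auc(s, 7, 37) == 0.0

    def test_resampling_invariance_at_knots(self):
        t = np.array([0.0, 5.0, 12.0, 40.0])
        v = np.array([0.0, 80.0, 20.0, -10.0])
        dense_t = np.union1d(t, np.linspace(0, 40, 161))
        dense_v = np.interp(dense_t, t, v)
        a1 = u.normalized_auc(series(t, v), 2, 38)
        a2 = u.normalized_auc(series(dense_t, dense_v), 2, 38)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_artifact_points_excluded(self):
        t = np.arange(0, 41, 1.0)
        v = np.zeros_like(t)
        art = (t >= 23) & (t <= 26)
        v[art] = 1000.0     # artefactual spikes must not contribute
        a = u.normalized_auc(series(t, v, art), 7, 37)
        assert a == pytest.approx(0.0, abs=1e-9)

    def test_window_outside_support_rejected(self):
        with pytest.raises(ValueError):
            u.normalized_auc(series([0, 30], [0, 0]), 7, 37)


class TestMannWhitneyExact:
    def test_fully_separated_groups(self):
        u_stat, p = u.mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert u_stat == 0.0
        assert p == pytest.approx(2 / 252)

    def test_u_equal_two_two_sided(self):
        # exactly two (a, b) pairs with a > b
        a, b = [1, 2, 3, 4, 7], [5, 6, 8, 9, 10]
        u_stat, p = u.mann_whitney_exact(a, b)
        assert u_stat == 2.0
        assert p == pytest.approx(8 / 252)   # the n=5 per group p = 0.032

    def test_identical_groups_give_p_one(self):
        _, p = u.mann_whitney_exact([3, 3, 3], [3, 3, 3])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_matches_independent_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        a = np.round(rng.standard_normal(5), 1)    # rounding induces ties
        b = np.round(rng.standard_normal(4), 1)
        u_stat, p = u.mann_whitney_exact(a, b, alternative=alternative)
        u_ref, p_ref = brute_force_exact_p(a, b, alternative)
        assert u_stat == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        u_stat, p = u.mann_whitney_exact(a, b)
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u_stat == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_symmetry_relations(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(5), rng.standard_normal(6)
        ua, pg = u.mann_whitney_exact(a, b, alternative="greater")
        ub, pl = u.mann_whitney_exact(b, a, alternative="less")
        assert pg == pytest.approx(pl)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            u.mann_whitney_exact([], [1, 2])


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert u.cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_one_pooled_sd_difference(self):
        a = np.array([9.0, 10.0, 11.0])
        b = a - np.std(a, ddof=1)
        assert u.cohens_d(a, b) == pytest.approx(1.0)

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(u.cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestGroupPipeline:
    def test_control_exceeds_tlv(self):
        ctrl = u.simulate_region_series(u.HemodynamicTemplate.control(),
                                        n_subjects=5, seed=1,
                                        interval_s=60.0)
        tlv = u.simulate_region_series(u.HemodynamicTemplate.tlv(),
                                       n_subjects=5, seed=2, interval_s=60.0)
        cmp = u.group_pipeline(
            {"control": [s.series["whole_slice"] for s in ctrl],
             "tlv": [s.series["whole_slice"] for s in tlv]},
            window=(7.0, 37.0))
        assert cmp.summary["control"]["median"] > cmp.summary["tlv"]["median"]
        assert cmp.cohens_d > 0

    def test_duplicated_groups_give_zero_effect(self):
        # per-subject values differ, but both groups share the same set
        s = [series([0, 10, 20, 40], [0, 50 + 10 * k, 30, 10], None)
             for k in range(3)]
        cmp = u.group_pipeline({"a": s, "b": s}, window=(5, 35))
        assert cmp.cohens_d == pytest.approx(0.0)
        assert cmp.p_value == 1.0
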