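"""Evaluation statistics against hand-computed and brute-force oracles."""

import numpy as np
import pytest

from harmonet import evaluation as ev
from harmonet import synthetic
from harmonet.metric_io import MetricVolume, SiteDataset


def _cohort(site, stacks, ages=None, sexes=None):
    n = len(stacks)
    ages = ages if ages is not None else np.full(n, 41.0)
    sexes = sexes if sexes is not None else ["male"] * n
    vols = [MetricVolume(np.asarray(s, dtype=float), subject_id=f"{site}_{i}",
                         site=site, age_weeks=float(ages[i]), sex=sexes[i])
            for i, s in enumerate(stacks)]
    return SiteDataset(site, vols)


class TestErrorMaps:
    def test_identical_cohorts_zero_map(self):
        rng = np.random.default_rng(0)
        stacks = rng.uniform(0, 1, (4, 5, 5, 3))
        mask = np.ones((5, 5, 3), bool)
        amap = ev.absolute_error_map(_cohort("a", stacks), _cohort("b", stacks),
                                     mask)
        assert np.all(amap == 0)

    def test_constant_offset(self):
        mask = np.ones((4, 4, 2), bool)
        a = _cohort("a", [np.full((4, 4, 2), 0.45)] * 3)
        b = _cohort("b", [np.full((4, 4, 2), 0.40)] * 3)
        amap = ev.absolute_error_map(a, b, mask)
        assert np.allclose(amap[mask], 0.05)

    def test_matches_explicit_voxel_loop(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, (3, 8, 8, 4))
        B = rng.uniform(0, 1, (5, 8, 8, 4))
        mask = rng.random((8, 8, 4)) > 0.4
        amap = ev.absolute_error_map(_cohort("a", A), _cohort("b", B), mask)
        for i in range(8):
            for j in range(8):
                for k in range(4):
                    expected = abs(A[:, i, j, k].mean() - B[:, i, j, k].mean()) \
                        if mask[i, j, k] else 0.0
                    assert amap[i, j, k] == pytest.approx(expected)


class TestRmse:
    def test_subject_equal_to_reference_mean_is_zero(self):
        mask = np.ones((4, 4, 2), bool)
        ref = _cohort("r", [np.full((4, 4, 2), 0.3), np.full((4, 4, 2), 0.5)])
        subj = MetricVolume(np.full((4, 4, 2), 0.4), subject_id="s", site="t")
        assert ev.rmse(subj, ref, mask) == 0.0

    def test_constant_offset_closed_form(self):
        mask = np.ones((4, 4, 2), bool)
        ref = _cohort("r", [np.full((4, 4, 2), 0.3)] * 3)
        subj = MetricVolume(np.full((4, 4, 2), 0.35), subject_id="s", site="t")
        assert ev.rmse(subj, ref, mask) == pytest.approx(0.05)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        ref_stacks = rng.uniform(0, 1, (4, 6, 6, 3))
        subj_data = rng.uniform(0, 1, (6, 6, 3))
        mask = rng.random((6, 6, 3)) > 0.3
        got = ev.rmse(MetricVolume(subj_data, subject_id="s", site="t"),
                      _cohort("r", ref_stacks), mask)
        acc = [(subj_data[i, j, k] - ref_stacks[:, i, j, k].mean()) ** 2
               for i in range(6) for j in range(6) for k in range(3)
               if mask[i, j, k]]
        assert got == pytest.approx(np.sqrt(np.mean(acc)))

    def test_empty_mask_raises(self):
        ref = _cohort("r", [np.zeros((4, 4, 2))] * 2)
        with pytest.raises(ValueError, match="mask"):
            ev.rmse(ref.volumes[0], ref, np.zeros((4, 4, 2), bool))


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert ev.cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]).d == 0.0

    def test_hand_computed_example(self):
        res = ev.cohens_d([2.0, 4.0], [1.0, 3.0])
        assert res.M_f == 3.0 and res.M_m == 2.0
        assert res.S_pooled == pytest.approx(np.sqrt(2.0))
        assert res.d == pytest.approx(1.0 / np.sqrt(2.0))

    def test_antisymmetry_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = rng.normal(size=rng.integers(2, 10))
            m = rng.normal(size=rng.integers(2, 10))
            assert ev.cohens_d(f, m).d == pytest.approx(-ev.cohens_d(m, f).d)

    def test_matches_stepwise_formula(self):
        rng = np.random.default_rng(4)
        f = rng.normal(0.5, 0.1, 12)
        m = rng.normal(0.4, 0.2, 9)
        res = ev.cohens_d(f, m)
        sp = np.sqrt((11 * f.std(ddof=1) ** 2 + 8 * m.std(ddof=1) ** 2) / 19)
        assert res.d == pytest.approx((f.mean() - m.mean()) / sp)

    def test_zero_pooled_sd_unequal_means_raises(self):
        with pytest.raises(ValueError, match="pooled"):
            ev.cohens_d([1.0, 1.0], [2.0, 2.0])


class TestTractProfile:
    def test_constant_volume_gives_constant_profile(self):
        mask = np.zeros((20, 8, 8), bool)
        mask[2:18, 3:5, 3:5] = True
        prof = ev.tract_profile(np.full((20, 8, 8), 0.37), mask,
                                axis_direction=(1, 0, 0), n_levels=10)
        assert np.allclose(prof.values, 0.37)

    def test_projected_coordinate_volume_increases(self):
        mask = np.zeros((30, 8, 8), bool)
        mask[1:29, 3:5, 3:5] = True
        coord = np.broadcast_to(np.arange(30)[:, None, None],
                                (30, 8, 8)).astype(float)
        prof = ev.tract_profile(coord, mask, axis_direction=(1, 0, 0),
                                n_levels=14)
        assert np.all(np.diff(prof.values) > 0)

    def test_100_levels_on_long_synthetic_tract(self):
        template = synthetic.make_template((32, 160, 8), 1, seed=0)
        name = next(iter(template.tract_masks))
        tract = template.tract_masks[name]
        coords = np.argwhere(tract)
        assert coords[:, 1].max() - coords[:, 1].min() >= 100
        prof = ev.tract_profile(template.base_map, tract,
                                template.tract_directions[name], n_levels=100)
        assert len(prof.values) == 100

    def test_empty_bin_names_the_bin(self):
        mask = np.zeros((10, 4, 4), bool)
        mask[0, 1, 1] = mask[9, 1, 1] = True  # two voxels, huge gap
        with pytest.raises(ValueError, match="bin"):
            ev.tract_profile(np.zeros((10, 4, 4)), mask,
                             axis_direction=(1, 0, 0), n_levels=5)


class TestProfileAgeCorrelation:
    @staticmethod
    def _profiles(values):
        return [ev.TractProfile("t", np.asarray(v, dtype=float), len(v))
                for v in values]

    def test_perfectly_linear_in_age_gives_r_one(self):
        ages = np.array([38.0, 40.0, 42.0, 44.0])
        profs = self._profiles([[a * 0.01, 0.5] for a in ages])
        res = ev.profile_age_correlation(profs, ages)
        assert res.r[0] == pytest.approx(1.0)
        assert res.undefined[1]  # constant location is flagged, not significant
        assert not res.significant[1]

    def test_null_calibration_false_positive_rate(self):
        rng = np.random.default_rng(5)
        n_sub, n_loc, reps = 12, 20, 60
        flags = []
        for _ in range(reps):
            ages = rng.uniform(38, 44, n_sub)
            profs = self._profiles(rng.normal(0.3, 0.05, (n_sub, n_loc)))
            res = ev.profile_age_correlation(profs, ages)
            flags.append(res.significant.mean())
        assert abs(np.mean(flags) - 0.05) < 0.03

    def test_planted_age_effect_gives_positive_median_r(self, small_template):
        cov = synthetic.CovariateModel(beta_age=0.01, beta_sex=0.0,
                                       subject_sd=0.002, noise_sd=0.002)
        ds = synthetic.generate_cohort(small_template, 12, cov, seed=6)
        name = next(iter(small_template.tract_masks))
        profs = [ev.tract_profile(v.data, small_template.tract_masks[name],
                                  small_template.tract_directions[name],
                                  n_levels=8) for v in ds.volumes]
        res = ev.profile_age_correlation(profs, ds.ages())
        assert np.nanmedian(res.r) > 0


class TestHistogram:
    def test_counts_sum_to_mask_size(self):
        rng = np.random.default_rng(7)
        stacks = rng.uniform(0, 1, (3, 6, 6, 3))
        mask = rng.random((6, 6, 3)) > 0.5
        h = ev.wm_histogram(_cohort("a", stacks), mask, bins=10)
        for counts in h["per_subject"].values():
            assert counts.sum() == mask.sum()
        assert h["pooled"].sum() == 3 * mask.sum()

    def test_gain_shifts_pooled_histogram_right(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0.2, 0.4, (4, 6, 6, 3))
        mask = np.ones((6, 6, 3), bool)
        h1 = ev.wm_histogram(_cohort("a", base), mask, bins=20)
        h2 = ev.wm_histogram(_cohort("b", base * 1.2), mask, bins=20)
        centers = 0.5 * (h1["edges"][:-1] + h1["edges"][1:])
        m1 = (h1["pooled"] * centers).sum() / h1["pooled"].sum()
        m2 = (h2["pooled"] * centers).sum() / h2["pooled"].sum()
        assert m2 > m1

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            ev.wm_histogram(_cohort("a", [np.zeros((4, 4, 2))] * 2),
                            np.ones((4, 4, 2), bool), bins=1)


class TestMannWhitney:
    def test_identical_groups_p_near_one(self):
        u, p = ev.mannwhitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.95

    def test_exact_enumeration_example(self):
        u, p = ev.mannwhitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_swapping_groups_reflects_u(self):
        rng = np.random.default_rng(9)
        a = list(rng.normal(size=6))
        b = list(rng.normal(size=8))
        ua, _ = ev.mannwhitney_u(a, b)
        ub, _ = ev.mannwhitney_u(b, a)
        assert ua + ub == pytest.approx(6 * 8)


class TestGroupTest:
    def test_identical_cohorts_empty_significance(self):
        rng = np.random.default_rng(10)
        stacks = rng.uniform(0.2, 0.5, (6, 6, 6, 3))
        mask = np.ones((6, 6, 3), bool)
        res = ev.voxelwise_group_test(_cohort("a", stacks), _cohort("b", stacks),
                                      mask, n_permutations=200, seed=0)
        assert res.n_significant() == 0

    def test_planted_effect_detected_with_direction(self):
        rng = np.random.default_rng(11)
        mask = np.ones((8, 8, 4), bool)
        A = rng.normal(0.4, 0.02, (20, 8, 8, 4))
        B = rng.normal(0.4, 0.02, (20, 8, 8, 4))
        B[:, 2:4, 2:4, 1] += 0.1
        res = ev.voxelwise_group_test(_cohort("a", A), _cohort("b", B), mask,
                                      n_permutations=300, seed=1)
        planted = np.zeros((8, 8, 4), bool)
        planted[2:4, 2:4, 1] = True
        assert res.significance[planted].all()
        assert np.all(res.direction[planted] == 1.0)  # site B higher
        assert res.significance[~planted].sum() <= 2

    def test_mannwhitney_fdr_method(self):
        rng = np.random.default_rng(12)
        mask = np.ones((6, 6, 2), bool)
        A = rng.normal(0.4, 0.02, (15, 6, 6, 2))
        B = A + 0.08
        res = ev.voxelwise_group_test(_cohort("a", A), _cohort("b", B), mask,
                                      method="mannwhitney_fdr")
        assert res.n_significant() > 0.9 * mask.sum()

    def test_too_few_permutations_rejected(self):
        stacks = np.random.default_rng(13).uniform(0, 1, (4, 4, 4, 2))
        mask = np.ones((4, 4, 2), bool)
        with pytest.raises(ValueError, match="100"):
            ev.voxelwise_group_test(_cohort("a", stacks), _cohort("b", stacks),
                                    mask, n_permutations=50)


class TestUnionOverFolds:
    @staticmethod
    def _result(p_map, mask, method="permutation_maxstat"):
        return ev.GroupTestResult(p_map, p_map <= 0.05,
                                  np.sign(p_map - 0.5), method, mask, 0.05)

    def test_single_input_is_identity(self):
        mask = np.ones((4, 4, 2), bool)
        p = np.random.default_rng(14).uniform(0, 1, (4, 4, 2))
        r = self._result(p, mask)
        u = ev.union_over_folds([r])
        assert np.array_equal(u.p_map, r.p_map)
        assert np.array_equal(u.significance, r.significance)

    def test_disjoint_masks_sum(self):
        mask = np.ones((4, 4, 2), bool)
        p1 = np.ones((4, 4, 2))
        p2 = np.ones((4, 4, 2))
        p1[0, 0, 0] = 0.01
        p2[1, 1, 1] = 0.02
        u = ev.union_over_folds([self._result(p1, mask), self._result(p2, mask)])
        assert u.n_significant() == 2

    def test_min_p_matches_brute_force(self):
        rng = np.random.default_rng(15)
        mask = np.ones((5, 5, 2), bool)
        ps = [rng.uniform(0, 1, (5, 5, 2)) for _ in range(4)]
        u = ev.union_over_folds([self._result(p, mask) for p in ps])
        for i in range(5):
            for j in range(5):
                for k in range(2):
                    assert u.p_map[i, j, k] == min(p[i, j, k] for p in ps)

    def test_mixed_methods_rejected(self):
        mask = np.ones((4, 4, 2), bool)
        p = np.ones((4, 4, 2))
        with pytest.raises(ValueError, match="method"):
            ev.union_over_folds([self._result(p, mask),
                                 self._result(p, mask, method="mannwhitney_fdr")])
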