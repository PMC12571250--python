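import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import figground as fg


class TestCircularVariance:
    @pytest.mark.parametrize(
        "dirs,expected",
        [
            ([37.0] * 10, 0.0),
            ([0.0, 90.0, 180.0, 270.0], 1.0),
            ([0.0, 90.0], 1.0 - np.sqrt(2) / 2),
        ],
    )
    def test_analytic_cases(self, dirs, expected):
        assert fg.circular_variance(dirs) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 360), min_size=1, max_size=50))
    def test_bounded_and_matches_vector_sum(self, dirs):
        v = fg.circular_variance(dirs)
        assert 0.0 <= v <= 1.0 + 1e-12
        rad = np.deg2rad(dirs)
        rbar = np.hypot(np.cos(rad).mean(), np.sin(rad).mean())
        assert v == pytest.approx(1 - rbar, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fg.circular_variance([])


class TestRayleigh:
    def test_identical_directions_reject_uniformity(self):
        assert fg.rayleigh_test([45.0] * 50).p_value < 1e-10

    def test_uniform_grid_accepts_uniformity(self):
        assert fg.rayleigh_test(np.linspace(0, 360, 100, endpoint=False)).p_value > 0.99

    def test_von_mises_power(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            fg.rayleigh_test(np.rad2deg(rng.vonmises(0, 2.0, 100))).p_value < 0.05
            for _ in range(50)
        )
        assert rejections == 50

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        d = np.rad2deg(rng.vonmises(1.0, 0.8, 40)) % 360
        z, p = pingouin.circ_rayleigh(np.deg2rad(d))
        ours = fg.rayleigh_test(d)
        assert ours.statistic == pytest.approx(z, rel=1e-6)
        # the two implementations use different standard approximations of
        # the Rayleigh p-value; they agree to ~1e-4 at this n
        assert ours.p_value == pytest.approx(p, rel=1e-3)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fg.rayleigh_test([1.0, 2.0])


class TestKuiper:
    def test_identical_samples_do_not_differ(self):
        a = np.linspace(0, 360, 30, endpoint=False)
        res = fg.kuiper_two(a, a)
        assert res.p_value > 0.99
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        a = np.rad2deg(rng.vonmises(0, 1.0, 40)) % 360
        b = np.rad2deg(rng.vonmises(1.0, 2.0, 55)) % 360
        base = fg.kuiper_two(a, b)
        for rot in (37.0, 180.0, 299.5):
            r = fg.kuiper_two((a + rot) % 360, (b + rot) % 360)
            assert r.statistic == pytest.approx(base.statistic, abs=1e-12)
            assert r.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_statistic_matches_cdf_scan_oracle(self):
        a = np.array([10.0, 50.0, 200.0, 300.0, 355.0])
        b = np.array([20.0, 60.0, 90.0, 250.0, 340.0, 350.0])
        res = fg.kuiper_two(a, b)
        # brute force: evaluate EDF difference on a fine grid of angles
        grid = np.linspace(0, 360, 100_000)
        fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
        fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
        v = (fa - fb).max() + (fb - fa).max()
        assert res.statistic == pytest.approx(v, abs=1e-9)

    def test_detects_shifted_distributions(self):
        rng = np.random.default_rng(3)
        a = np.rad2deg(rng.vonmises(0, 4.0, 200)) % 360
        b = np.rad2deg(rng.vonmises(np.pi, 4.0, 200)) % 360
        assert fg.kuiper_two(a, b).p_value < 0.001


class TestClassicalTests:
    def test_symmetric_values_give_zero_t(self):
        res = fg.one_sample_t([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_textbook_one_sample_t(self):
        # mean 3, sd sqrt(2.5): t = 3 / (sqrt(2.5)/sqrt(5)) = 4.2426,
        # p (two-sided, df=4) = 0.01324, D = 3/sqrt(2.5) = 1.8974
        res = fg.one_sample_t([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.statistic == pytest.approx(4.242640687, abs=1e-6)
        assert res.p_value == pytest.approx(0.013237, abs=1e-5)
        assert res.effect_size == pytest.approx(1.897366596, abs=1e-6)

    def test_t_scale_invariance(self):
        x = np.array([0.3, -0.2, 0.9, 1.4, -0.6])
        a, b = fg.one_sample_t(x), fg.one_sample_t(17.0 * x)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.effect_size == pytest.approx(b.effect_size)

    def test_anova_identical_groups(self):
        x = [1.0, 2.0, 3.0] * 3
        g = [0] * 3 + [1] * 3 + [2] * 3
        res = fg.anova_eta(x, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_anova_all_variance_between(self):
        res = fg.anova_eta([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        assert res.effect_size == pytest.approx(1.0)

    def test_anova_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        g = np.repeat([0, 1, 2, 3], 5)
        res = fg.anova_eta(x, g)
        grand = x.mean()
        ssb = sum(5 * (x[g == k].mean() - grand) ** 2 for k in range(4))
        ssw = sum(((x[g == k] - x[g == k].mean()) ** 2).sum() for k in range(4))
        f = (ssb / 3) / (ssw / 16)
        assert res.statistic == pytest.approx(f)
        assert res.effect_size == pytest.approx(ssb / (ssb + ssw))

    def test_tukey_two_groups_equals_t_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        table = fg.tukey_pairs(np.concatenate([a, b]), [0] * 12 + [1] * 12)
        t = sps.ttest_ind(a, b)
        assert table.loc[0, "p_value"] == pytest.approx(t.pvalue, abs=1e-6)

    def test_tukey_ci_excludes_zero_iff_significant(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(m, 1, 15) for m in (0, 0.2, 2.0, 2.1)])
        g = np.repeat([0, 1, 2, 3], 15)
        table = fg.tukey_pairs(x, g)
        for _, row in table.iterrows():
            excludes = row.ci_lo > 0 or row.ci_hi < 0
            assert excludes == (row.p_value < 0.05)

    def test_ranksum_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = fg.ranksum_r(x, x)
        assert res.p_value > 0.9
        assert res.effect_size == pytest.approx(0.0, abs=0.05)

    def test_ranksum_fully_separated_matches_enumeration(self):
        res = fg.ranksum_r([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        # z for complete separation of two n=3 samples: W = 6 (min),
        # E[W] = 10.5, sd = sqrt(3*3*7/12) = 2.2913 -> z = -1.9640
        assert res.statistic == pytest.approx(-4.5 / np.sqrt(5.25), abs=1e-6)
        assert 0.0 <= res.effect_size <= 1.0

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            fg.ranksum_r([1.0, 1.0], [1.0, 1.0])


class TestBinomialCI:
    def test_paper_scale_proportion(self):
        lo, hi = fg.binomial_ci(544, 800)
        assert round(100 * lo) == 65
        assert round(100 * hi) == 71

    def test_zero_successes_lower_bound(self):
        lo, hi = fg.binomial_ci(0, 100)
        assert lo == 0.0 and hi < 0.05

    def test_symmetric_about_half(self):
        lo, hi = fg.binomial_ci(50, 100)
        assert lo + hi == pytest.approx(1.0, abs=1e-9)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            fg.binomial_ci(0, 0)


class TestRegionSummary:
    def _uniform_srf(self):
        from figground.srf_sampler import SRFSample
        from figground.gaze_sim import GazeState

        rows = np.arange(4)
        gaze = GazeState((0, 0), (0.0, 0.0), False, 10.0)
        return SRFSample(
            scene_id="t", scene_index=0, center=(2, 2), diameter_deg=5.0,
            eccentricity_deg=5.0, gaze=gaze,
            figure_pixels=(rows, np.zeros(4, int)),
            ground_pixels=(rows, np.ones(4, int)),
            figure_fraction=0.5, ground_fraction=0.5, invalid_fraction=0.0,
        )

    def test_uniform_region_summary(self):
        srf = self._uniform_srf()
        shape = (4, 2)
        summ = fg.region_summary(
            srf,
            np.full(shape, 10.0),
            np.zeros(shape),
            np.full(shape, 0.2),
            np.ones(shape, bool),
        )
        assert summ.s_f == pytest.approx(1.0)
        assert summ.v_f == pytest.approx(0.0, abs=1e-12)
        assert summ.d_f == pytest.approx(0.2)

    def test_log_averaging_of_speeds(self):
        srf = self._uniform_srf()
        speeds = np.array([[1.0, 5.0], [100.0, 5.0], [1.0, 5.0], [100.0, 5.0]])
        summ = fg.region_summary(
            srf, speeds, np.zeros((4, 2)), np.full((4, 2), np.nan), np.ones((4, 2), bool)
        )
        assert summ.s_f == pytest.approx(1.0)  # mean of log10 {1,100,1,100}
        assert np.isnan(summ.d_f)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(7)
        srf = self._uniform_srf()
        sp = rng.uniform(0.6, 30, (4, 2))
        di = rng.uniform(0, 360, (4, 2))
        dm = rng.normal(0, 1, (4, 2))
        valid = rng.random((4, 2)) > 0.3
        summ = fg.region_summary(srf, sp, di, dm, valid)
        col = 0
        v = valid[:, col]
        if v.any():
            assert summ.s_f == pytest.approx(np.mean(np.log10(sp[v, col])))
            assert summ.v_f == pytest.approx(fg.circular_variance(di[v, col]))
        assert summ.d_f == pytest.approx(dm[:, col].mean())

    def test_empty_region_is_undefined(self):
        srf = self._uniform_srf()
        summ = fg.region_summary(
            srf, np.full((4, 2), 1.0), np.zeros((4, 2)), np.zeros((4, 2)),
            np.zeros((4, 2), bool),
        )
        assert np.isnan(summ.s_f) and np.isnan(summ.v_g)
        assert summ.n_f == 0


class TestNormalization:
    def test_even_spacing_rescaled_to_unit_interval(self):
        vals, keep = fg.normalized_speed_values(np.linspace(1, 100, 100))
        assert vals.min() == 0.0 and vals.max() == 1.0

    def test_outlier_removed_by_quantile_trim(self):
        v = np.concatenate([np.linspace(1, 2, 200), [1000.0]])
        vals, keep = fg.normalized_speed_values(v)
        assert not keep[-1]
        assert vals.max() == 1.0

    def test_constant_speeds_map_to_half(self):
        with pytest.warns(UserWarning, match="degenerate"):
            vals, _ = fg.normalized_speed_values(np.full(10, 3.0))
        assert np.all(vals == 0.5)


class TestAlignment:
    def test_single_direction_aligns_to_zero(self):
        out = fg.aligned_directions(np.full(20, 90.0))
        assert np.allclose(np.abs(out), np.abs(out[0]))
        assert abs(out[0]) <= 3.6  # within half a 7.2 deg bin of zero

    def test_majority_lobe_wins(self):
        d = np.array([30.0] * 60 + [210.0] * 40)
        out = fg.aligned_directions(d)
        # the 60% lobe sits at ~0, the 40% lobe at ~180
        assert np.abs(out[:60]).max() <= 3.6
        assert np.abs(np.abs(out[60:]) - 180).max() <= 3.6

    def test_equivariant_under_bin_multiple_rotation(self):
        rng = np.random.default_rng(8)
        d = rng.vonmises(1.0, 2.0, 200)
        d = np.rad2deg(d) % 360
        base = fg.aligned_directions(d)
        rotated = fg.aligned_directions((d + 5 * 7.2) % 360)
        np.testing.assert_allclose(np.sort(base), np.sort(rotated), atol=1e-9)


class TestRatioCurve:
    def test_null_case_ratio_near_one(self):
        # bins within one dataset are correlated, so bin coverage of a single
        # realization fluctuates; average over independent null datasets
        coverages, ratios = [], []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            figs = [rng.random(300) for _ in range(30)]
            gnds = [rng.random(300) for _ in range(30)]
            curve = fg.ratio_curve(figs, gnds, np.linspace(0, 1, 51), n_boot=300, rng=seed)
            ok = np.isfinite(curve.ratio)
            covered = (curve.ci_lo[ok] <= 1.0) & (1.0 <= curve.ci_hi[ok])
            coverages.append(covered.mean())
            ratios.append(np.nanmean(curve.ratio))
        assert np.mean(coverages) >= 0.9
        assert min(coverages) >= 0.8
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_constructed_shift_gives_increasing_trend(self):
        rng = np.random.default_rng(10)
        figs = [np.clip(rng.normal(0.65, 0.15, 300), 0, 1) for _ in range(30)]
        gnds = [np.clip(rng.normal(0.35, 0.15, 300), 0, 1) for _ in range(30)]
        curve = fg.ratio_curve(figs, gnds, np.linspace(0, 1, 51), n_boot=100, rng=1)
        ok = np.isfinite(curve.ratio)
        rho = sps.spearmanr(np.arange(50)[ok], curve.ratio[ok]).statistic
        assert rho > 0.5

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(11)
        figs = [rng.random(100) for _ in range(12)]
        gnds = [rng.random(100) for _ in range(12)]
        edges = np.linspace(0, 1, 51)
        curve = fg.ratio_curve(figs, gnds, edges, n_boot=10, rng=0)
        width = edges[1] - edges[0]
        assert curve.figure_density.sum() * width == pytest.approx(1.0)
        assert curve.ground_density.sum() * width == pytest.approx(1.0)

    def test_too_few_srfs_rejected(self):
        with pytest.raises(ValueError):
            fg.ratio_curve([np.ones(3)] * 5, [np.ones(3)] * 5, np.linspace(0, 1, 51))


class TestGlobalDistributions:
    def test_histogram_mass_equals_pixel_counts(self, small_dataset):
        out = fg.global_distributions(small_dataset[0])
        for feat in ("speed", "direction", "distance"):
            tbl = out["tables"][feat]
            for cls in ("all", "figure", "ground"):
                assert tbl[f"count_{cls}"].sum() == out["counts"][f"{feat}_{cls}"]

    def test_single_class_scene_has_empty_figure_table(self):
        from figground.scene_model import GROUND, SceneBundle, SceneMetadata

        meta = SceneMetadata(deg_per_pixel=0.2, frame_rate=120.0, height=40, width=40)
        bundle = SceneBundle(
            speed_map=np.full((40, 40), 3.0),
            direction_map=np.zeros((40, 40)),
            distance_map=np.full((40, 40), 8.0),
            label_map=np.full((40, 40), GROUND, dtype=np.uint8),
            metadata=meta,
        )
        out = fg.global_distributions([bundle])
        assert out["counts"]["speed_figure"] == 0
        assert out["counts"]["speed_ground"] > 0

    def test_configured_medians_recovered(self):
        p = fg.SceneGenParams(figure_static_fraction=0.0, ground_fast_fraction=0.0)
        bundles, _ = fg.generate_dataset(40, p, seed=13)
        out = fg.global_distributions(bundles)
        # truncation shifts the ground median slightly above the configured 1.0
        assert out["medians"]["speed_figure"] == pytest.approx(
            p.figure_speed_median, rel=0.10
        )
        assert out["medians"]["distance_figure"] < out["medians"]["distance_ground"]
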