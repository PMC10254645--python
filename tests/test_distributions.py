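"""Lognormal fitting, mixture selection, ANOVA and classification rules."""

import numpy as np
import pytest
from scipy import stats as sstats

from spicpms import (
    SampleResult,
    classify_transformation,
    compare_groups,
    fit_lognormal,
    fit_mixture,
    recovery_after_filtration,
)


def sample_result(n_events=400, median=59.0, dissolved=0.0, particulate=0.01):
    return SampleResult(
        n_events=n_events,
        number_concentration=1e7,
        number_per_gram=1e9,
        particulate_mass_ug_l=particulate,
        particulate_mass_ng_per_gram=1.0,
        dissolved_ug_l=dissolved,
        lod_size=20.0,
        median_diameter=median,
    )


class TestFitLognormal:
    def test_point_mass(self):
        d = fit_lognormal([59.0] * 20)
        assert d.lognormal_median == pytest.approx(59.0)
        assert d.lognormal_gsd == pytest.approx(1.0)

    def test_median_recovery_from_known_draws(self, rng):
        draws = np.exp(rng.normal(np.log(59.0), np.log(1.4), 5000))
        d = fit_lognormal(draws)
        assert d.lognormal_median == pytest.approx(59.0, rel=0.02)
        assert d.lognormal_gsd == pytest.approx(1.4, rel=0.02)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal([])
        with pytest.raises(ValueError):
            fit_lognormal([50.0, -1.0])

    @pytest.mark.parametrize("n", [300, 1000, 5000])
    def test_estimator_bias_and_spread_scale_with_n(self, n, rng):
        """Median MLE: bias < 2% and spread consistent with ln(gsd)/√n."""
        medians = [
            fit_lognormal(np.exp(rng.normal(np.log(59.0), np.log(1.3), n))).lognormal_median
            for _ in range(100)
        ]
        medians = np.array(medians)
        assert abs(medians.mean() / 59.0 - 1) < 0.02
        theory_sd = 59.0 * np.log(1.3) / np.sqrt(n)
        assert medians.std() == pytest.approx(theory_sd, rel=0.35)


class TestFitMixture:
    def test_unimodal_selects_one_component(self, rng):
        draws = np.exp(rng.normal(np.log(59.0), np.log(1.3), 1000))
        assert fit_mixture(draws, seed=0).k == 1

    def test_bimodal_selects_two_components(self, rng):
        n = 1000
        heavy = rng.random(n) < 0.3
        draws = np.where(
            heavy,
            np.exp(rng.normal(np.log(140.0), np.log(1.3), n)),
            np.exp(rng.normal(np.log(55.0), np.log(1.3), n)),
        )
        mix = fit_mixture(draws, seed=0)
        assert mix.k == 2
        meds = sorted(c.median for c in mix.components)
        assert meds[0] == pytest.approx(55.0, rel=0.10)
        assert meds[1] == pytest.approx(140.0, rel=0.10)
        assert mix.heavy_mode.weight == pytest.approx(0.3, abs=0.06)

    def test_small_sample_guard(self):
        mix = fit_mixture([55.0, 60.0, 57.0] * 7, seed=0)  # n = 21
        assert mix.k == 1
        assert "skipped" in mix.note

    def test_selection_reliability_over_seeds(self, rng):
        """k = 1 on ≥95% of unimodal samples, k = 2 on ≥95% of
        well-separated bimodal samples."""
        uni_correct = bi_correct = 0
        n_rep, n = 100, 400
        for _ in range(n_rep):
            uni = np.exp(rng.normal(np.log(59.0), np.log(1.3), n))
            uni_correct += fit_mixture(uni, seed=0).k == 1
            heavy = rng.random(n) < 0.3
            bi = np.where(
                heavy,
                np.exp(rng.normal(np.log(140.0), np.log(1.3), n)),
                np.exp(rng.normal(np.log(55.0), np.log(1.3), n)),
            )
            bi_correct += fit_mixture(bi, seed=0).k == 2
        assert uni_correct >= 95
        assert bi_correct >= 95


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        cmp = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert cmp.f_statistic == 0.0
        assert not cmp.significant

    def test_two_groups_f_equals_t_squared(self):
        a, b = [59.0, 61.0, 60.0], [62.0, 64.0, 63.0]
        cmp = compare_groups({"a": a, "b": b})
        t, p = sstats.ttest_ind(a, b)
        assert cmp.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert cmp.p_value == pytest.approx(p, rel=1e-10)

    def test_extreme_separation_significant(self):
        cmp = compare_groups({"a": [0.0, 0.1, -0.1], "b": [10.0, 10.1, 9.9]})
        assert cmp.significant

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0]})

    def test_null_rejection_rate_is_calibrated(self, rng):
        """Under H0 the 0.05-level rejection rate is 0.05 ± 0.02."""
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {k: rng.normal(0, 1, 5) for k in "abc"}
            rejections += compare_groups(groups).significant
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


class TestRecovery:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(2.5e7, 1.1e7, 44.0), (2.1e7, 1.1e7, 52.38), (5.0, 5.0, 100.0)],
    )
    def test_percentages(self, before, after, expected):
        assert recovery_after_filtration(before, after) == pytest.approx(
            expected, rel=1e-3
        )

    def test_zero_before_rejected(self):
        with pytest.raises(ValueError):
            recovery_after_filtration(0.0, 1.0)


class TestClassifier:
    def test_identical_runs_are_stable(self):
        r = sample_result()
        v = classify_transformation(r, r)
        assert v.flags == {"stable"}

    def test_median_shift_flags_agglomeration(self):
        fresh = sample_result(median=55.0)
        aged = sample_result(median=81.0)
        v = classify_transformation(fresh, aged)
        assert "agglomeration" in v.flags

    def test_dissolved_rise_flags_partial_dissolution(self):
        fresh = sample_result(dissolved=0.0002, particulate=0.01)
        aged = sample_result(dissolved=0.004, particulate=0.009)
        v = classify_transformation(fresh, aged)
        assert "partial_dissolution" in v.flags

    def test_event_collapse_with_high_dissolved_is_fast_dissolution(self):
        fresh = sample_result(n_events=400, dissolved=0.0)
        aged = sample_result(n_events=10, dissolved=0.05, particulate=0.0002)
        v = classify_transformation(fresh, aged)
        assert "fast_dissolution" in v.flags
        assert any("events" in n for n in v.notes)  # size rules skipped

    def test_evidence_fields_always_populated(self):
        v = classify_transformation(sample_result(), sample_result(median=61.0))
        assert v.median_shift_nm == pytest.approx(2.0)
        assert np.isfinite(v.event_count_ratio)
        assert np.isfinite(v.dissolved_fraction_change)
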