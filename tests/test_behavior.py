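import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wheelwiggle import behavior as bh
from wheelwiggle.behavior import ClassificationResult, PsychometricParams


def make_trials(rt, go_cue_offset=0.0):
    n = len(rt)
    return pd.DataFrame({
        "rt_s": rt,
        "stim_on_s": np.arange(n, dtype=float),
        "go_cue_s": np.arange(n, dtype=float) + go_cue_offset,
    })


class TestFilterTrials:
    def test_counts(self):
        rt = [0.5, 1.5, 0.08, 0.05, 0.3, 1.20, 1.21, 0.9, 0.15, 0.2]
        kept, counts = bh.filter_trials(make_trials(rt))
        assert counts == {"kept": 7, "dropped": 3}
        assert list(kept.index) == [0, 2, 4, 5, 7, 8, 9]

    def test_boundaries_inclusive(self):
        kept, _ = bh.filter_trials(make_trials([0.08, 1.20]))
        assert len(kept) == 2

    def test_go_cue_tolerance(self):
        kept, _ = bh.filter_trials(make_trials([0.5, 0.5], go_cue_offset=0.06))
        assert len(kept) == 0

    def test_missing_column(self):
        with pytest.raises(KeyError):
            bh.filter_trials(pd.DataFrame({"rt_s": [0.5]}))


@pytest.mark.parametrize("rt, expected", [(0.08, True), (0.16, False), (-0.1, True)])
def test_classify_false_start(rt, expected):
    assert bh.classify_false_start(rt) is expected


class TestPredictPsychometric:
    def test_symmetry_at_bias(self):
        p = PsychometricParams(gamma=0.1, lambda_=0.1, mu=5.0, sigma=10.0)
        assert bh.predict_psychometric(p, 5.0) == pytest.approx(0.5)

    def test_asymptotes(self):
        p = PsychometricParams(gamma=0.05, lambda_=0.12, mu=0.0, sigma=10.0)
        assert bh.predict_psychometric(p, 1e6) == pytest.approx(1 - 0.12, abs=1e-9)
        assert bh.predict_psychometric(p, -1e6) == pytest.approx(0.05, abs=1e-9)

    def test_gaussian_cdf_identity(self):
        p = PsychometricParams(gamma=0.0, lambda_=0.0, mu=0.0, sigma=10.0)
        assert bh.predict_psychometric(p, 10.0) == pytest.approx(0.8413, abs=1e-4)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.0, 0.4), st.floats(0.0, 0.4),
        st.floats(-50.0, 50.0), st.floats(0.5, 100.0),
    )
    def test_monotone_and_bounded(self, gamma, lam, mu, sigma):
        p = PsychometricParams(gamma=gamma, lambda_=lam, mu=mu, sigma=sigma)
        c = np.linspace(-100, 100, 41)
        vals = bh.predict_psychometric(p, c)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all(vals >= gamma - 1e-12) and np.all(vals <= 1 - lam + 1e-12)


class TestFitPsychometric:
    levels = np.array([-100, -25, -12.5, -6.25, 0, 6.25, 12.5, 25, 100])

    def _simulate(self, params, n, seed):
        rng = np.random.default_rng(seed)
        c = rng.choice(self.levels, n)
        p = bh.predict_psychometric(params, c)
        return pd.DataFrame({
            "contrast_signed_pct": c,
            "choice": np.where(rng.random(n) < p, 1, -1),
        })

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parameter_recovery(self, seed):
        true = PsychometricParams(gamma=0.05, lambda_=0.1, mu=5.0, sigma=15.0)
        est = bh.fit_psychometric(self._simulate(true, 10000, seed))
        assert abs(est.gamma - true.gamma) <= 0.02
        assert abs(est.lambda_ - true.lambda_) <= 0.02
        assert abs(est.mu - true.mu) <= 2.0
        assert abs(est.sigma - true.sigma) <= 3.0

    def test_deterministic_refit(self):
        df = self._simulate(PsychometricParams(), 2000, 3)
        a, b = bh.fit_psychometric(df), bh.fit_psychometric(df)
        assert (a.gamma, a.lambda_, a.mu, a.sigma) == (b.gamma, b.lambda_, b.mu, b.sigma)

    def test_all_rightward_hits_lapse_bound(self):
        df = pd.DataFrame({
            "contrast_signed_pct": np.tile(self.levels, 50),
            "choice": np.ones(450, dtype=int),
        })
        est = bh.fit_psychometric(df)
        assert est.gamma >= 0.45  # left-lapse driven to its bound

    def test_single_contrast_rejected(self):
        df = pd.DataFrame({"contrast_signed_pct": [6.25] * 100, "choice": [1] * 100})
        with pytest.raises(ValueError):
            bh.fit_psychometric(df)


class TestOctileBin:
    def test_equal_counts(self, rng):
        idx, excluded, degenerate = bh.octile_bin(rng.normal(size=16))
        assert np.all(np.bincount(idx, minlength=8) == 2)
        assert excluded  # 2 < 3 trials per bin fails the session rule
        assert not degenerate

    def test_sufficient_counts_not_excluded(self, rng):
        idx, excluded, _ = bh.octile_bin(rng.normal(size=24))
        assert np.all(np.bincount(idx, minlength=8) == 3)
        assert not excluded

    def test_short_bins_trigger_exclusion(self, rng):
        idx, excluded, _ = bh.octile_bin(rng.normal(size=20))
        assert excluded  # 20 values over 8 bins leaves bins of 2 < 3

    def test_too_few_values(self):
        idx, excluded, _ = bh.octile_bin(np.arange(5))
        assert idx is None and excluded

    def test_all_identical_degenerate(self):
        idx, _, degenerate = bh.octile_bin(np.zeros(32))
        assert degenerate
        assert np.all(np.bincount(idx, minlength=8) == 4)  # stable tie handling


class TestAccuracyVsSpeed:
    def _simulate(self, b, n, seed):
        rng = np.random.default_rng(seed)
        speed = rng.gamma(2.0, 30.0, n)
        octile = bh.octile_bin(speed)[0]
        p = 1.0 / (1.0 + np.exp(-(0.1 + b * octile)))
        return pd.DataFrame({
            "speed_deg_s": speed,
            "correct": (rng.random(n) < p).astype(int),
        })

    def test_slope_recovery(self):
        res = bh.accuracy_vs_speed(self._simulate(0.1, 8000, 0))
        assert abs(res["beta"] - 0.1) < 3 * res["se"]

    def test_null_slope(self):
        res = bh.accuracy_vs_speed(self._simulate(0.0, 8000, 1))
        assert abs(res["beta"]) < 3 * res["se"]

    def test_monotone_accuracy_positive_beta(self):
        res = bh.accuracy_vs_speed(self._simulate(0.3, 4000, 2))
        assert res["beta"] > 0
        assert res["accuracy"][-1] > res["accuracy"][0]

    def test_separation_flagged(self):
        df = self._simulate(0.1, 100, 3)
        df["correct"] = 1
        assert bh.accuracy_vs_speed(df)["separation"]


class TestNormalizedGain:
    def test_basic(self):
        np.testing.assert_allclose(bh.normalized_gain([0.5, 0.6]), [0.2])

    def test_flat(self):
        np.testing.assert_allclose(bh.normalized_gain([0.7, 0.7, 0.7]), [0.0, 0.0])

    def test_zero_baseline_flagged(self):
        assert np.all(np.isnan(bh.normalized_gain([0.0, 0.5])))


class TestAccuracyGLM:
    def _simulate(self, bk, bd, n, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(0, 6, n)
        dur = rng.gamma(2.0, 0.3, n)
        p = 1.0 / (1.0 + np.exp(-(0.2 + bk * k + bd * dur)))
        return pd.DataFrame({
            "k": k, "response_duration_s": dur,
            "correct": (rng.random(n) < p).astype(int),
        })

    def test_k_only_effect(self):
        res = bh.accuracy_glm(self._simulate(0.3, 0.0, 5000, 0))
        assert res["beta_k"] - 3 * res["se_k"] > 0
        assert abs(res["beta_dur"]) < 3 * res["se_dur"]

    def test_no_effects(self):
        res = bh.accuracy_glm(self._simulate(0.0, 0.0, 5000, 1))
        assert abs(res["beta_k"]) < 3 * res["se_k"]
        assert abs(res["beta_dur"]) < 3 * res["se_dur"]

    def test_collinearity_flag(self):
        df = self._simulate(0.2, 0.0, 500, 2)
        df["response_duration_s"] = df["k"] + 1e-9
        assert bh.accuracy_glm(df)["collinear"]


class TestKRegression:
    def test_closed_form_three_bins(self):
        """acc = (0.5, 0.6, 0.7) at k = 0, 1, 2 with equal weights -> slope 0.1."""
        rows = []
        for k, acc in [(0, 0.5), (1, 0.6), (2, 0.7)]:
            rows += [{"k": k, "correct": 1}] * int(acc * 10)
            rows += [{"k": k, "correct": 0}] * (10 - int(acc * 10))
        res = bh.k_regression(pd.DataFrame(rows))
        assert res.slope == pytest.approx(0.1, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_flat_accuracy_zero_slope(self):
        rows = []
        for k in range(5):
            rows += [{"k": k, "correct": 1}] * 6 + [{"k": k, "correct": 0}] * 6
        res = bh.k_regression(pd.DataFrame(rows))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_k_cap_at_four(self):
        rows = [{"k": 9, "correct": 1}] * 5 + [{"k": 0, "correct": 0}] * 5
        res = bh.k_regression(pd.DataFrame(rows))
        assert res.slope == pytest.approx(0.25)  # (1 - 0) / (4 - 0)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            bh.k_regression(pd.DataFrame([{"k": 1, "correct": 1}] * 10))


class TestClassification:
    @pytest.mark.parametrize("slope, r2, expected, strong", [
        (0.03, 0.5, "positive", False),
        (0.1, 0.75, "positive", True),
        (-0.02, 0.5, "negative", False),
        (-0.02, 0.05, "unclassified", False),
        (0.02, 0.09, "unclassified", False),
        (0.0, 0.9, "unclassified", True),
        (0.05, 0.1, "positive", False),   # boundary R2 = 0.1 included
        (0.05, 0.7, "positive", True),    # boundary R2 = 0.7 strong
    ])
    def test_mouse_labels(self, slope, r2, expected, strong):
        res = ClassificationResult(slope=slope, r2=r2, pearson_r=0.0)
        assert bh.classify_mouse(res) == (expected, strong)

    @pytest.mark.parametrize("r, expected", [
        (0.5, "benefiting"), (0.31, "benefiting"),
        (0.3, "neutral"), (0.0, "neutral"), (-0.3, "neutral"),
        (-0.31, "non_benefiting"), (-0.5, "non_benefiting"),
    ])
    def test_session_labels(self, r, expected):
        res = ClassificationResult(slope=0.0, r2=0.0, pearson_r=r)
        assert bh.classify_session(res) == expected


class TestWiggleFractionTrend:
    def _table(self, p_of_t, n, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 3600, n))
        return pd.DataFrame({
            "stim_on_s": t,
            "is_wiggle": (rng.random(n) < p_of_t(t)).astype(int),
        })

    def test_constant_probability_null_slope(self):
        res = bh.wiggle_fraction_trend(self._table(lambda t: 0.4 + 0 * t, 3000, 0))
        assert abs(res["slope"]) < 3 * res["se"]

    def test_decaying_probability_negative_slope(self):
        res = bh.wiggle_fraction_trend(
            self._table(lambda t: 0.6 - 0.4 * t / 3600.0, 3000, 1))
        assert res["slope"] < 0 and res["p_value"] < 0.05

    def test_single_bin_rejected(self):
        df = pd.DataFrame({"stim_on_s": [1.0, 2.0], "is_wiggle": [0, 1]})
        with pytest.raises(ValueError):
            bh.wiggle_fraction_trend(df)


class TestSideAsymmetry:
    def _cohort(self, frac_nonpref, n_mice, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for m in range(n_mice):
            # preferred side = right (higher accuracy on +6.25)
            for c, acc in [(6.25, 0.9), (-6.25, 0.6)]:
                for _ in range(50):
                    rows.append({"mouse": m, "contrast_signed_pct": c,
                                 "correct": int(rng.random() < acc),
                                 "is_wiggle": 0, "choice": 1})
            for _ in range(40):
                nonpref = rng.random() < frac_nonpref
                rows.append({"mouse": m, "contrast_signed_pct": 6.25,
                             "correct": 1, "is_wiggle": 1,
                             "choice": -1 if nonpref else 1})
        return pd.DataFrame(rows)

    def test_symmetric_cohort(self):
        res = bh.side_asymmetry(self._cohort(0.5, 12, 0))
        assert abs(res["median"] - 0.5) < 0.15

    def test_all_preferred(self):
        res = bh.side_asymmetry(self._cohort(0.0, 5, 1))
        assert res["median"] == 0.0

    def test_biased_cohort_detected(self):
        res = bh.side_asymmetry(self._cohort(0.35, 20, 2))
        assert res["median"] < 0.5 and res["wilcoxon_p"] < 0.05


class TestDprime:
    def test_equal_rates(self):
        assert bh.dprime(0.5, 0.5, 100, 100) == pytest.approx(0.0, abs=1e-12)

    def test_unit_z_scores(self):
        assert bh.dprime(0.8413, 0.1587, 10000, 10000) == pytest.approx(2.0, abs=1e-3)

    def test_clipping_extreme_rates(self):
        from scipy.special import ndtri
        d = bh.dprime(1.0, 0.2, 50, 50)
        assert d == pytest.approx(ndtri(0.99) - ndtri(0.2))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            bh.dprime(0.5, 0.5, 0, 10)


def test_wilson_interval_contains_point_estimate():
    lo, hi = bh.wilson_interval(30, 100)
    assert lo < 0.3 < hi and 0 <= lo and hi <= 1


def test_bonferroni_default_matches_three_way():
    assert bh.bonferroni_alpha() == pytest.approx(0.05 / 3)
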