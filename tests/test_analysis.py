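"""Tests for the behavioral analyses: normalization, psychometric fits,
response curves, slopes, bootstrap intervals, accuracy and correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from contraction_bias import (
    DegenerateDataError,
    DegenerateFitError,
    InsufficientTrialsError,
    OutOfRangeError,
    ParamDistribution,
    ResponseCurve,
    SubjectMismatchError,
    TaskConfig,
    TooFewReplicatesError,
    accuracy_by_difficulty,
    basic_interval,
    bootstrap_slope_ci,
    bootstrap_slope_difference,
    compute_response_curve,
    fit_psychometric,
    fit_response_slope,
    generate_cohort,
    normalize_log_lengths,
    slope_sigma_correlation,
    windowed_slope_comparison,
)
from contraction_bias.analysis import denormalize_log_lengths


def _table(l1, l2, response, subject="s00", interfered=False):
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    return pd.DataFrame({
        "subject_id": subject,
        "trial_index": np.arange(l1.size),
        "l1_px": l1,
        "l2_px": l2,
        "is_impossible": l1 == l2,
        "interfered": interfered,
        "response": pd.array(response, dtype="Int64"),
    })


class TestNormalize:
    def test_endpoints_and_geometric_midpoint(self):
        out = normalize_log_lengths([150.0, 300.0, 600.0], (150.0, 600.0))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(0.5)
        assert out[2] == 1.0

    def test_round_trip(self):
        x = np.array([160.0, 233.3, 410.0, 599.0])
        back = denormalize_log_lengths(normalize_log_lengths(x, (150, 600)), (150, 600))
        assert np.allclose(back, x, rtol=1e-10)

    def test_out_of_range_raises(self):
        with pytest.raises(OutOfRangeError):
            normalize_log_lengths([149.0], (150.0, 600.0))


class TestPsychometric:
    DELTAS = (-0.30, -0.15, -0.075, 0.075, 0.15, 0.30)

    def _noiseless_table(self, mu, sigma, n_per=400):
        rows_l1, rows_l2, resp = [], [], []
        for d in self.DELTAS:
            frac_first = ndtr((mu - d) / sigma)
            k = int(round(frac_first * n_per))
            for i in range(n_per):
                rows_l1.append(200.0)
                rows_l2.append(200.0 * (1 + d))
                resp.append(1 if i < k else 2)
        return _table(rows_l1, rows_l2, resp)

    def test_recovers_generating_curve(self):
        # fractions generated exactly from the model: recovery is near-exact
        # up to the 1/n_per rounding of counts
        t = self._noiseless_table(mu=0.0, sigma=0.1, n_per=10_000)
        fit = fit_psychometric(t)
        assert fit.mu == pytest.approx(0.0, abs=1e-3)
        assert fit.sigma_psych == pytest.approx(0.1, rel=1e-2)
        assert fit.rss < 1e-6

    def test_constant_responses_degenerate(self):
        t = _table([200] * 6, [200 * (1 + d) for d in self.DELTAS], [1] * 6)
        with pytest.raises(DegenerateFitError):
            fit_psychometric(t)

    def test_symmetric_responses_give_zero_pse(self):
        t = self._noiseless_table(mu=0.0, sigma=0.15, n_per=1000)
        assert fit_psychometric(t).mu == pytest.approx(0.0, abs=1e-3)


class TestResponseCurve:
    def test_all_first_longer(self):
        l = np.linspace(160, 590, 100)
        t = _table(l, l, [1] * 100)
        c = compute_response_curve(t, (150, 600), n_bins=5)
        assert np.all(c.fractions == 1.0)

    def test_equal_count_binning_exact(self):
        l = np.linspace(160, 590, 210)
        t = _table(l, l, [1] * 210)
        c = compute_response_curve(t, (150, 600), trials_per_bin=21)
        assert len(c) == 10
        assert np.all(c.counts == 21)

    def test_unbiased_observer_near_half(self):
        cfg = TaskConfig(impossible_fraction=1.0, n_trials=10_000)
        trials, _ = generate_cohort(1, cfg, ParamDistribution(0.25, 0.25), seed=3)
        c = compute_response_curve(trials, cfg.range_px, n_bins=10)
        se = np.sqrt(0.25 / c.counts.astype(float))
        assert np.all(np.abs(c.fractions - 0.5) < 3 * se + 0.01)

    def test_no_impossible_trials_raises(self):
        t = _table([200.0], [260.0], [1])
        with pytest.raises(InsufficientTrialsError):
            compute_response_curve(t, (150, 600), n_bins=2)

    def test_subject_average_has_sem(self, standard_cohort):
        cfg, trials, _ = standard_cohort
        c = compute_response_curve(trials, cfg.range_px, n_bins=10)
        assert c.sem is not None and np.all(c.sem >= 0)


class TestSlope:
    def test_flat_curve_zero_slope(self):
        c = ResponseCurve(np.linspace(0, 1, 10), np.full(10, 0.5))
        assert fit_response_slope(c) == pytest.approx(0.0)

    def test_exact_line(self):
        x = np.linspace(0, 1, 10)
        c = ResponseCurve(x, 1.0 - x)
        assert fit_response_slope(c) == pytest.approx(-1.0)

    def test_step_curve_slope_at_most_minus_one(self):
        """Step response sampled at equal-count bins: OLS slope <= -1,
        checked against the closed-form OLS on the step values."""
        x = np.linspace(0.05, 0.95, 10)
        y = np.where(x < 0.5, 1.0, 0.0)
        slope = fit_response_slope(ResponseCurve(x, y))
        xc = x - x.mean()
        closed_form = float(np.sum(xc * y) / np.sum(xc ** 2))
        assert slope == pytest.approx(closed_form, rel=1e-12)
        assert slope <= -1.0

    def test_invariant_to_additive_constant(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.random(8))
        y = rng.random(8)
        s0 = fit_response_slope(ResponseCurve(x, y))
        s1 = fit_response_slope(ResponseCurve(x, y + 0.17))
        assert s1 == pytest.approx(s0, abs=1e-12)


class TestBootstrap:
    def test_identical_responses_zero_width(self):
        l = np.linspace(160, 590, 120)
        t = _table(l, l, [1] * 120)
        est = bootstrap_slope_ci(t, (150, 600), n_boot=500, seed=0, n_bins=5)
        assert est.slope == pytest.approx(0.0)
        assert est.ci_lo == pytest.approx(est.ci_hi)

    def test_reproducible_under_seed(self, standard_cohort):
        cfg, trials, _ = standard_cohort
        a = bootstrap_slope_ci(trials, cfg.range_px, n_boot=300, seed=7)
        b = bootstrap_slope_ci(trials, cfg.range_px, n_boot=300, seed=7)
        assert (a.slope, a.ci_lo, a.ci_hi) == (b.slope, b.ci_lo, b.ci_hi)

    def test_too_few_replicates(self, standard_cohort):
        cfg, trials, _ = standard_cohort
        with pytest.raises(TooFewReplicatesError):
            bootstrap_slope_ci(trials, cfg.range_px, n_boot=50)

    def test_basic_interval_formula(self):
        boots = np.array([-0.40, -0.35, -0.30, -0.25, -0.20, -0.15])
        lo, hi = basic_interval(-0.28, boots, level=0.90)
        q_lo, q_hi = np.quantile(boots, [0.05, 0.95])
        assert lo == pytest.approx(2 * -0.28 - q_hi)
        assert hi == pytest.approx(2 * -0.28 - q_lo)

    def test_interval_width_shrinks_with_trials(self):
        widths = []
        for n in (50, 200, 800):
            cfg = TaskConfig(impossible_fraction=1.0, n_trials=n)
            trials, _ = generate_cohort(5, cfg, ParamDistribution(0.3, 0.2), seed=21)
            est = bootstrap_slope_ci(trials, cfg.range_px, n_boot=400, seed=2, n_bins=5)
            widths.append(est.ci_hi - est.ci_lo)
        assert widths[0] > widths[1] > widths[2]

    def test_contraction_bias_detected(self, standard_cohort):
        """sigma1 > sigma2 cohort: negative slope, CI excluding zero."""
        cfg, trials, _ = standard_cohort
        est = bootstrap_slope_ci(trials, cfg.range_px, n_boot=1000, seed=3)
        assert est.slope < 0
        assert est.ci_hi < 0


class TestSlopeDifference:
    def test_same_table_difference_covers_zero(self, standard_cohort):
        cfg, trials, _ = standard_cohort
        est = bootstrap_slope_difference(
            trials, trials, range_px_a=cfg.range_px, range_px_b=cfg.range_px,
            n_boot=400, seed=5)
        assert est.slope == pytest.approx(0.0)
        assert est.contains_zero()

    def test_paired_requires_matching_subjects(self, standard_cohort):
        cfg, trials, _ = standard_cohort
        other = trials.copy()
        other["subject_id"] = other["subject_id"] + "_x"
        with pytest.raises(SubjectMismatchError):
            bootstrap_slope_difference(
                trials, other, paired=True,
                range_px_a=cfg.range_px, range_px_b=cfg.range_px,
                n_boot=200, seed=0)

    def test_shifted_prior_null(self):
        """Two ranges, same normalized observer: no slope difference
        (the translational-invariance prediction)."""
        dist = ParamDistribution(0.3, 0.2)
        cfg_a = TaskConfig(range_px=(150.0, 600.0), n_trials=400)
        cfg_b = TaskConfig(range_px=(50.0, 200.0), n_trials=400)
        ta, _ = generate_cohort(6, cfg_a, dist, seed=31)
        tb, _ = generate_cohort(6, cfg_b, dist, seed=32)
        est = bootstrap_slope_difference(
            ta, tb, range_px_a=cfg_a.range_px, range_px_b=cfg_b.range_px,
            n_boot=500, seed=1)
        assert est.contains_zero()

    def test_noise_contrast_detected(self):
        """sigma1 = 2*sigma2 vs sigma1 = sigma2: more negative slope."""
        cfg = TaskConfig(n_trials=500)
        ta, _ = generate_cohort(6, cfg, ParamDistribution(0.40, 0.20), seed=41)
        tb, _ = generate_cohort(6, cfg, ParamDistribution(0.20, 0.20), seed=42)
        est = bootstrap_slope_difference(
            ta, tb, range_px_a=cfg.range_px, range_px_b=cfg.range_px,
            n_boot=500, seed=2)
        assert est.slope < 0
        assert est.ci_hi < 0


class TestWindowedComparison:
    def test_stationary_observer_covers_zero(self):
        cfg = TaskConfig(impossible_fraction=1.0, n_trials=200)
        trials, _ = generate_cohort(6, cfg, ParamDistribution(0.3, 0.2), seed=17)
        est = windowed_slope_comparison(trials, cfg.range_px, n_boot=400, seed=4)
        assert est.contains_zero()

    def test_time_reversal_negates_point_estimate(self):
        cfg = TaskConfig(impossible_fraction=1.0, n_trials=120)
        trials, _ = generate_cohort(4, cfg, ParamDistribution(0.35, 0.2), seed=19)
        fwd = windowed_slope_comparison(trials, cfg.range_px, n_boot=200, seed=6)
        rev = trials.copy()
        rev["trial_index"] = -rev["trial_index"]
        bwd = windowed_slope_comparison(rev, cfg.range_px, n_boot=200, seed=6)
        assert bwd.slope == pytest.approx(-fwd.slope, abs=1e-12)

    def test_insufficient_trials(self):
        cfg = TaskConfig(impossible_fraction=1.0, n_trials=30)
        trials, _ = generate_cohort(2, cfg, ParamDistribution(0.3, 0.2), seed=23)
        with pytest.raises(InsufficientTrialsError):
            windowed_slope_comparison(trials, cfg.range_px, first_k=20, last_k=20,
                                      n_boot=200, seed=0)


class TestAccuracy:
    def test_noiseless_observer_perfect(self):
        cfg = TaskConfig(impossible_fraction=0.0, n_trials=600)
        trials, _ = generate_cohort(3, cfg, ParamDistribution(0.0, 0.0), seed=2)
        acc = accuracy_by_difficulty(trials)
        assert np.allclose(acc["percent_correct"], 100.0)

    def test_accuracy_decreases_with_difficulty(self, standard_cohort):
        _, trials, _ = standard_cohort
        acc = accuracy_by_difficulty(trials).sort_values("abs_delta")
        pc = acc["percent_correct"].to_numpy()
        assert np.all(np.diff(pc) >= 0)  # easier |delta| -> more correct

    def test_interference_lowers_accuracy_at_all_levels(self):
        cfg = TaskConfig(impossible_fraction=0.0, interference_fraction=0.5,
                         n_trials=2500)
        dist = ParamDistribution(0.26, 0.20, interference_multiplier=3.0)
        trials, _ = generate_cohort(4, cfg, dist, seed=13)
        acc = accuracy_by_difficulty(trials)
        wide = acc.pivot(index="abs_delta", columns="condition",
                         values="percent_correct")
        assert (wide[True] < wide[False]).all()


class TestCorrelation:
    def test_perfect_negative(self):
        r, p = slope_sigma_correlation([0.1, 0.2, 0.3, 0.4], [-0.1, -0.2, -0.3, -0.4])
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_constant_variable_degenerate(self):
        with pytest.raises(DegenerateDataError):
            slope_sigma_correlation([0.2, 0.2, 0.2], [-0.1, -0.2, -0.3])

    def test_noisier_subjects_show_stronger_bias(self):
        """Across subjects with spread sigma1, psychometric width correlates
        negatively with the (negative) response-curve slope."""
        cfg = TaskConfig(n_trials=600)
        dist = ParamDistribution(sigma1=(0.15, 0.55), sigma2=0.18)
        trials, truth = generate_cohort(10, cfg, dist, seed=29)
        sigmas, slopes = [], []
        for sid, g in trials.groupby("subject_id"):
            sigmas.append(fit_psychometric(g).sigma_psych)
            curve = compute_response_curve(g, cfg.range_px, n_bins=6)
            slopes.append(fit_response_slope(curve))
        r, _ = slope_sigma_correlation(sigmas, slopes)
        assert r < 0
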