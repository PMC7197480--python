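"""Association models against closed-form and independent numerical oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from enuscreen.association import (
    DegenerateOutcomeError,
    ddct_fold_change,
    fit_linear,
    fit_proportional_odds,
    fit_survival,
    fit_survival_best,
    km_median,
    logrank_test,
    scan_line,
    select_by_aic,
    two_sample_t,
)
from enuscreen.scoring import InvalidInputError
from enuscreen.simulate import (
    ScreenConfig,
    simulate_line,
    single_locus_model,
    two_locus_model,
)


def logistic_irls(y, x, iters=60):
    """Hand-rolled IRLS for binary logistic regression (test oracle)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(iters):
        mu = 1 / (1 + np.exp(-X @ beta))
        w = mu * (1 - mu)
        beta = beta + np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - mu))
    return beta


class TestProportionalOdds:
    def test_intercept_only_matches_empirical_frequencies(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 400)
        fit = fit_proportional_odds(y)
        probs = fit.category_probabilities(np.zeros((1, 0)))[0]
        empirical = np.bincount(y, minlength=3) / len(y)
        assert probs == pytest.approx(empirical, abs=1e-5)

    def test_binary_outcome_equals_logistic_mle(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(1, 0.5, 600).astype(float)
        eta = -0.4 + 1.1 * x
        y = (rng.random(600) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_proportional_odds(y, pd.DataFrame({"g": x}))
        beta_oracle = logistic_irls(y, x)[1]
        assert fit.coefficients["g"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_parameter_recovery_at_n2000(self):
        """beta-hat lands within 3 SE of the generating beta = 1."""
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        latent = 1.0 * x + rng.logistic(size=n)
        y = np.digitize(latent, [0.0, 1.5])
        fit = fit_proportional_odds(y, pd.DataFrame({"g": x}))
        assert fit.converged
        # generating model has P(Y<=j) = logistic(theta_j - beta x), beta = -1
        # on the severity convention used here: x shifts latent upward
        assert abs(fit.coefficients["g"] - 1.0) < 3 * fit.standard_errors["g"]

    def test_fitted_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        x = rng.binomial(1, 0.5, 300).astype(float)
        y = np.digitize(0.8 * x + rng.logistic(size=300), [0.0, 1.2])
        fit = fit_proportional_odds(y, pd.DataFrame({"g": x}))
        probs = fit.category_probabilities(np.array([[0.0], [1.0]]))
        assert probs.sum(axis=1) == pytest.approx([1.0, 1.0])
        assert np.all(np.diff(fit.cutpoints) > 0)

    def test_single_level_outcome_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_proportional_odds(np.zeros(50, dtype=int))

    def test_mle_beats_truth_likelihood(self):
        """The optimized likelihood is >= the generating parameters'."""
        rng = np.random.default_rng(5)
        n = 400
        x = rng.binomial(1, 0.5, n).astype(float)
        y = np.digitize(1.0 * x + rng.logistic(size=n), [0.0, 1.5])
        fit = fit_proportional_odds(y, pd.DataFrame({"g": x}))

        def loglik(beta, cuts):
            theta = np.concatenate([[-np.inf], cuts, [np.inf]])
            cum = 1 / (1 + np.exp(-(theta[None, :] - (beta * x)[:, None])))
            probs = np.diff(cum, axis=1)
            return float(np.log(probs[np.arange(n), y]).sum())

        assert fit.log_likelihood >= loglik(1.0, np.array([0.0, 1.5])) - 1e-6


class TestLinear:
    def test_exact_fit(self):
        x = np.arange(10, dtype=float)
        fit = fit_linear(2 * x, pd.DataFrame({"x": x}))
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=80)
        y = 1.5 * x + rng.normal(size=80)
        perm = rng.permutation(80)
        a = fit_linear(y, pd.DataFrame({"x": x}))
        b = fit_linear(y[perm], pd.DataFrame({"x": x[perm]}))
        assert a.coefficients["x"] == pytest.approx(b.coefficients["x"])
        assert a.p_values["x"] == pytest.approx(b.p_values["x"])

    def test_weight_effect_recovery(self):
        """+3 g genotype effect recovered within 3 SE at n = 500."""
        rng = np.random.default_rng(7)
        g = rng.binomial(1, 0.5, 500).astype(float)
        y = 30 + 3.0 * g + rng.normal(0, 3, 500)
        fit = fit_linear(y, pd.DataFrame({"g": g}))
        assert abs(fit.coefficients["g"] - 3.0) < 3 * fit.standard_errors["g"]

    def test_aliased_column_named(self):
        x = np.arange(20, dtype=float)
        with pytest.raises(InvalidInputError, match="x2"):
            fit_linear(x, pd.DataFrame({"x1": x, "x2": 2 * x}))


class TestSurvival:
    def test_exponential_rate_closed_form(self):
        """No-covariate exponential MLE: rate = events / total exposure."""
        times = np.array([3.0, 5.0, 7.0, 2.0, 10.0])
        events = np.array([1, 0, 1, 1, 0])
        fit = fit_survival(times, events, family="exponential")
        rate = math.exp(-fit.baseline_params["log_scale"])
        assert rate == pytest.approx(events.sum() / times.sum(), rel=1e-6)
        # log-likelihood at the MLE: d log(rate) - rate * T
        d, t = events.sum(), times.sum()
        assert fit.log_likelihood == pytest.approx(
            d * math.log(d / t) - d, rel=1e-9
        )

    def test_weibull_beats_exponential_when_shape_is_2(self):
        rng = np.random.default_rng(8)
        wins = 0
        for rep in range(10):
            t = 80 * rng.weibull(2.0, 2000)
            e = np.ones(2000, dtype=int)
            aic_w = fit_survival(t, e, family="weibull").aic
            aic_e = fit_survival(t, e, family="exponential").aic
            wins += aic_w < aic_e
        assert wins >= 10 * 0.95

    def test_noise_covariate_worsens_aic_on_average(self):
        rng = np.random.default_rng(9)
        deltas = []
        for rep in range(20):
            t = 80 * rng.weibull(2.0, 300)
            e = np.ones(300, dtype=int)
            z = rng.normal(size=300)
            base = fit_survival(t, e, family="weibull").aic
            noisy = fit_survival(t, e, pd.DataFrame({"z": z}), family="weibull").aic
            deltas.append(noisy - base)
        assert np.mean(deltas) > 0  # +2 penalty vs ~chi2_1/2 expected gain

    def test_aft_coefficient_recovery(self):
        """Weibull AFT recovers log-acceleration log(112/77) within 3 SE."""
        rng = np.random.default_rng(10)
        n = 2000
        g = rng.binomial(1, 0.5, n).astype(float)
        beta = math.log(112 / 77)
        t = 80 * np.exp(beta * g) * rng.weibull(4.0, n)
        e = np.ones(n, dtype=int)
        fit = fit_survival(t, e, pd.DataFrame({"g": g}), family="weibull")
        assert abs(fit.coefficients["g"] - beta) < 3 * fit.standard_errors["g"]

    def test_family_selection_consistency_at_line_scale(self):
        """At n = 50 per line, the true family wins more than any wrong one."""
        rng = np.random.default_rng(11)
        chosen = []
        for rep in range(40):
            t = 80 * rng.weibull(4.0, 50)
            e = np.ones(50, dtype=int)
            chosen.append(fit_survival_best(t, e).family)
        counts = pd.Series(chosen).value_counts()
        assert counts.idxmax() == "weibull"

    def test_aic_tie_prefers_fewer_parameters(self):
        from enuscreen.association import SurvivalFit

        a = SurvivalFit("weibull", {}, {}, {}, {}, log_likelihood=-10.0,
                        n_params=2, converged=True, n_obs=10)
        b = SurvivalFit("exponential", {}, {}, {}, {}, log_likelihood=-11.0,
                        n_params=1, converged=True, n_obs=10)
        assert select_by_aic([a, b]).family == "exponential"  # equal AIC = 24

    def test_zero_events_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_survival([1.0, 2.0], [0, 0], family="weibull")


class TestLogrankAndUtilities:
    def test_identical_groups_null(self):
        t = np.array([5.0, 8.0, 13.0, 21.0] * 2)
        e = np.ones(8, dtype=int)
        g = np.repeat([0, 1], 4)
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_animal_worked_example(self):
        """O-E by hand: E_A = 1/2 + 1/3 + 1/2, V = 1/4 + 2/9 + 1/4."""
        stat, p = logrank_test([10, 20, 15, 25], [1, 1, 1, 1], [0, 0, 1, 1])
        expected = (2 - 4 / 3) ** 2 / (1 / 4 + 2 / 9 + 1 / 4)
        assert stat == pytest.approx(expected, rel=1e-9)  # 0.61538...

    def test_uniform_p_under_equal_hazards(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(12)
        pvals = []
        for rep in range(300):
            t = rng.exponential(80, 40)
            e = np.ones(40, dtype=int)
            g = np.repeat([0, 1], 20)
            pvals.append(logrank_test(t, e, g)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_km_median_and_censoring(self):
        assert km_median([2, 4, 6, 8], [1, 1, 1, 1]) == pytest.approx(4.0)
        assert km_median([10, 10, 10], [0, 0, 0]) is None

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])

    @pytest.mark.parametrize(
        "cts,expected",
        [((20, 15, 22, 18), 0.5), ((20, 15, 20, 15), 1.0), ((19, 15, 20, 15), 2.0)],
    )
    def test_ddct_fold_change(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)

    def test_two_sample_t_matches_pooled_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        t, p = two_sample_t(a, b)
        sp2 = (3 * np.var(a, ddof=1) + 2 * np.var(b, ddof=1)) / 5
        expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 3))
        assert t == pytest.approx(expected, rel=1e-12)
        with pytest.raises(InvalidInputError):
            two_sample_t([1.0], [2.0, 3.0])


def line_to_frame(line):
    """Per-animal analysis table for the scan, built from a simulated line."""
    from enuscreen.scoring import assessment_nearest_age, total_health_score

    rows = []
    for a in line.n3_animals:
        if not a.mecp2_null:
            continue
        chosen = assessment_nearest_age(a.assessments, 56)
        if chosen is None:
            continue
        rows.append(
            {
                "score_total": total_health_score(chosen).total,
                "clasping": chosen.clasping,
                "weight_g": chosen.body_weight_g,
                "survival_days": float(a.survival_days),
                "event": int(not a.censored),
                **{l: float(a.carrier_flags[l]) for l in line.truth.loci},
            }
        )
    return pd.DataFrame(rows)


class TestScanLine:
    def test_independent_architecture_marginals_fire(self):
        """Two independent suppressors: both marginal p small on the score."""
        config = ScreenConfig(n2_families_per_line=30, n3_per_family=10)
        line = simulate_line(config, two_locus_model("additive"), rng_seed=13)
        df = line_to_frame(line)
        result = scan_line(
            df, loci=["SupA", "SupB"], ordinal_traits=["score_total"],
            linear_traits=["weight_g"],
        )
        score = result.marginal.query("trait == 'score_total'").set_index("locus")
        assert score.loc["SupA", "p_value"] < 0.01
        assert score.loc["SupB", "p_value"] < 0.01
        assert score.loc["SupA", "effect"] < 0  # carriers healthier

    def test_both_required_architecture_needs_interaction(self):
        """Strict epistasis: the product term captures the improvement."""
        config = ScreenConfig(n2_families_per_line=40, n3_per_family=10,
                              censor_age_days=400)
        line = simulate_line(config, two_locus_model("epistatic"), rng_seed=14)
        df = line_to_frame(line)
        result = scan_line(
            df, loci=["SupA", "SupB"], ordinal_traits=["score_total"],
        )
        inter = result.interactions.query("trait == 'score_total'")
        surv_inter = result.interactions.query("trait == 'survival_days'")
        assert (inter["p_value"] < 0.01).any()
        assert (surv_inter["p_value"] < 0.05).any()

    def test_all_zero_genotype_column_skipped(self, small_line):
        _, line = small_line
        df = line_to_frame(line)
        df["dead_locus"] = 0.0
        result = scan_line(
            df, loci=["SupA", "dead_locus"], ordinal_traits=["score_total"],
            survival_cols=None,
        )
        assert result.skipped and result.skipped[0][0] == "dead_locus"
        assert set(result.marginal["locus"]) == {"SupA"}

    def test_bh_adjustment_flag(self, small_line):
        _, line = small_line
        df = line_to_frame(line)
        result = scan_line(
            df, loci=["SupA"], ordinal_traits=["score_total", "clasping"],
            linear_traits=["weight_g"], bh=True,
        )
        assert "q_value" in result.marginal.columns
        ok = result.marginal["p_value"].notna()
        assert (result.marginal.loc[ok, "q_value"]
                >= result.marginal.loc[ok, "p_value"] - 1e-12).all()

    def test_no_loci_rejected(self, small_line):
        _, line = small_line
        with pytest.raises(InvalidInputError):
            scan_line(line_to_frame(line), loci=[])


class TestScanCalibration:
    def test_marginal_type_i_error_near_nominal(self):
        """Null-effect generator: ordinal marginal p <= 0.05 at ~5% rate.

        Scaled to 250 replicates of n = 60 animals (a per-line cohort);
        the rejection rate must sit within 3 binomial SE of 0.05.
        """
        rng = np.random.default_rng(15)
        rejections = 0
        reps = 250
        for rep in range(reps):
            g = rng.binomial(1, 0.5, 60).astype(float)
            y = np.digitize(rng.logistic(size=60), [-1.0, 1.0])
            if len(np.unique(y)) < 2:
                continue
            fit = fit_proportional_odds(y, pd.DataFrame({"g": g}))
            if fit.converged and fit.wald_p_values["g"] <= 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)
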