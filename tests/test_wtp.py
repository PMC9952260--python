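import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cvwtp
from cvwtp.survey_io import Certainty
from cvwtp.wtp import (
    DEFINITELY_YES_SCHEME,
    MeanUndefinedError,
    NOT_SURE_SCHEME,
    NonIdentifiableError,
    PROBABLY_YES_SCHEME,
    WtpInterval,
    aggregate_wtp,
    bootstrap_ci,
    build_interval,
    build_intervals,
    fit_interval_model,
    interval_loglik,
    loglogistic_cdf,
    mean_wtp,
    recode_certainty,
)

DY, PY, NS, PN, DN = (
    Certainty.DEFINITELY_YES,
    Certainty.PROBABLY_YES,
    Certainty.NOT_SURE,
    Certainty.PROBABLY_NO,
    Certainty.DEFINITELY_NO,
)
GRID = [DY, DY, PY, NS, PN, DN, DN, DN, DN]


class TestRecoding:
    def test_probably_yes_scheme(self):
        out = recode_certainty(GRID, PROBABLY_YES_SCHEME)
        assert list(out) == [True] * 3 + [False] * 6

    def test_definitely_yes_scheme(self):
        out = recode_certainty(GRID, DEFINITELY_YES_SCHEME)
        assert list(out) == [True] * 2 + [False] * 7

    def test_all_definitely_yes_is_yes_under_every_scheme(self):
        for scheme in cvwtp.SCHEMES.values():
            assert recode_certainty([DY] * 9, scheme).all()

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            recode_certainty([7], PROBABLY_YES_SCHEME)

    def test_non_prefix_yes_set_rejected(self):
        with pytest.raises(ValueError):
            cvwtp.RecodingScheme("bad", frozenset({NS}))


def brute_force_interval(answers, amounts):
    """Literal reading of the bracketing rule, for cross-checking."""
    yes = [a for a, ok in zip(amounts, answers) if ok]
    lower = max(yes) if yes else 0.0
    refused_above = [a for a, ok in zip(amounts, answers) if not ok and a > lower]
    upper = min(refused_above) if refused_above else np.inf
    monotone = all(
        not (ai < aj and (not yi) and yj)
        for (ai, yi), (aj, yj) in itertools.product(
            zip(amounts, answers), repeat=2
        )
    )
    return lower, upper, monotone


class TestBuildInterval:
    def test_clean_monotone_pattern(self):
        iv = build_interval([True] * 5 + [False] * 4)
        assert (iv.lower, iv.upper) == (40.0, 80.0)
        assert iv.monotone and not iv.left_censored and not iv.right_censored

    def test_all_no_is_left_censored_below_first_bid(self):
        iv = build_interval([False] * 9)
        assert (iv.lower, iv.upper) == (0.0, 1.0)
        assert iv.left_censored and not iv.right_censored

    def test_all_yes_is_right_censored_above_top_bid(self):
        iv = build_interval([True] * 9)
        assert iv.lower == 500.0 and np.isinf(iv.upper)
        assert iv.right_censored

    def test_non_monotone_envelope(self):
        iv = build_interval([True, False, True] + [False] * 6)
        assert (iv.lower, iv.upper) == (10.0, 20.0)
        assert not iv.monotone

    def test_exhaustive_all_patterns_match_brute_force(self):
        amounts = cvwtp.DEFAULT_BIDS.amounts
        for bits in itertools.product([False, True], repeat=9):
            iv = build_interval(bits)
            lower, upper, monotone = brute_force_interval(bits, amounts)
            assert (iv.lower, iv.upper, iv.monotone) == (lower, upper, monotone)
            assert iv.lower < iv.upper
            assert (iv.lower == 0) == iv.left_censored
            assert np.isinf(iv.upper) == iv.right_censored

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_interval([])

    def test_drop_policy_removes_flagged_respondents(self):
        grids = [[DY] * 9, [DN, DY] + [DN] * 7]
        intervals, kept = build_intervals(grids, nonmonotone="drop")
        assert len(intervals) == 1 and list(kept) == [True, False]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lower=5.0, upper=5.0),
            dict(lower=0.0, upper=1.0, left_censored=False),
            dict(lower=5.0, upper=np.inf, right_censored=False),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        kwargs.setdefault("left_censored", kwargs.get("lower") == 0.0)
        kwargs.setdefault("right_censored", np.isinf(kwargs.get("upper", 1.0)))
        with pytest.raises(ValueError):
            WtpInterval(**kwargs)


class TestLogLogisticCdf:
    def test_unit_amount_at_zero_predictor(self):
        assert loglogistic_cdf(1.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_amount_e_value(self):
        assert loglogistic_cdf(np.e, 0.0, 1.0) == pytest.approx(np.e / (1 + np.e), abs=1e-10)

    def test_strictly_increasing_over_bid_grid(self, rng):
        for _ in range(10):
            dx, alpha = rng.normal(0, 3), rng.uniform(0.2, 4.0)
            values = loglogistic_cdf(np.array(cvwtp.DEFAULT_BIDS.amounts), dx, alpha)
            assert np.all(np.diff(values) > 0)
            assert np.all((values > 0) & (values < 1))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            loglogistic_cdf(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            loglogistic_cdf(1.0, 0.0, -1.0)


def random_intervals(rng, n, amounts=cvwtp.DEFAULT_BIDS.amounts):
    """Random mix of bounded and censored brackets off the bid ladder."""
    intervals = []
    for _ in range(n):
        kind = rng.integers(0, 3)
        if kind == 0:
            intervals.append(WtpInterval(0.0, amounts[0], left_censored=True))
        elif kind == 1:
            intervals.append(WtpInterval(amounts[-1], np.inf, right_censored=True))
        else:
            i = rng.integers(0, len(amounts) - 1)
            intervals.append(WtpInterval(amounts[i], amounts[i + 1]))
    return intervals


class TestIntervalLoglik:
    def test_uninformative_interval_contributes_zero(self):
        iv = WtpInterval(0.0, np.inf, left_censored=True, right_censored=True)
        X = pd.DataFrame({"const": [1.0]})
        assert interval_loglik([0.7], 1.3, [iv], X) == pytest.approx(0.0)

    def test_unit_to_e_bracket_value(self):
        iv = WtpInterval(1.0, np.e)
        X = pd.DataFrame({"const": [1.0]})
        expected = np.log(np.e / (1 + np.e) - 0.5)
        assert interval_loglik([0.0], 1.0, [iv], X) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-1.4650, abs=1e-4)

    def test_matches_generic_loglogistic_cdf_differences(self, rng):
        # independent oracle: scipy's fisk distribution, c = α, scale = exp(δX/α)
        n = 100
        intervals = random_intervals(rng, n)
        X = pd.DataFrame({"const": np.ones(n), "z": rng.normal(0, 0.5, n)})
        delta, alpha = np.array([5.5, 0.4]), 1.6
        ours = interval_loglik(delta, alpha, intervals, X)
        scale = np.exp((X.to_numpy() @ delta) / alpha)
        oracle = sum(
            np.log(
                stats.fisk.cdf(iv.upper, c=alpha, scale=s)
                - stats.fisk.cdf(iv.lower, c=alpha, scale=s)
            )
            for iv, s in zip(intervals, scale)
        )
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_every_summand_nonpositive(self, rng):
        intervals = random_intervals(rng, 50)
        X = pd.DataFrame({"const": np.ones(50)})
        assert interval_loglik([4.0], 1.2, intervals, X) <= 0.0


@pytest.fixture(scope="module")
def synthetic_intervals():
    """n = 2000 intercept-only draw from (δ0 = 2.0, α = 1.5)."""
    config = cvwtp.SimulationConfig(n=2000, seed=77, wtp_delta={"const": 2.0}, wtp_alpha=1.5)
    covariates = pd.DataFrame(index=range(config.n))
    grids, latent = cvwtp.simulate_payment_card(
        covariates, config.wtp_delta, config.wtp_alpha, seed=config.seed
    )
    intervals, _ = build_intervals(list(grids))
    return intervals, latent


class TestFitIntervalModel:
    def test_parameter_recovery_within_3se(self, synthetic_intervals):
        intervals, _ = synthetic_intervals
        fit = fit_interval_model(intervals)
        assert fit.converged
        assert abs(fit.delta["const"] - 2.0) < 3 * fit.se["const"]
        assert abs(fit.alpha - 1.5) < 3 * fit.se["alpha"]

    def test_matches_grid_search_of_likelihood(self, synthetic_intervals):
        intervals, _ = synthetic_intervals
        subset = intervals[:150]
        X = pd.DataFrame({"const": np.ones(len(subset))})
        fit = fit_interval_model(subset)

        def negll(d0, a):
            return -interval_loglik([d0], a, subset, X)

        d_grid = np.linspace(fit.delta["const"] - 0.5, fit.delta["const"] + 0.5, 41)
        a_grid = np.linspace(max(fit.alpha - 0.4, 0.1), fit.alpha + 0.4, 41)
        for _ in range(3):  # successive refinement to ~1e-3 resolution
            values = np.array([[negll(d, a) for a in a_grid] for d in d_grid])
            i, j = np.unravel_index(values.argmin(), values.shape)
            d_best, a_best = d_grid[i], a_grid[j]
            d_half = (d_grid[1] - d_grid[0]) * 2
            a_half = (a_grid[1] - a_grid[0]) * 2
            d_grid = np.linspace(d_best - d_half, d_best + d_half, 41)
            a_grid = np.linspace(a_best - a_half, a_best + a_half, 41)
        assert d_best == pytest.approx(fit.delta["const"], abs=1e-3)
        assert a_best == pytest.approx(fit.alpha, abs=1e-3)

    def test_replication_invariance(self, synthetic_intervals):
        intervals, _ = synthetic_intervals
        subset = intervals[:300]
        fit1 = fit_interval_model(subset)
        fit2 = fit_interval_model(subset * 2)
        assert fit2.delta["const"] == pytest.approx(fit1.delta["const"], abs=1e-5)
        assert fit2.alpha == pytest.approx(fit1.alpha, abs=1e-5)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-8)

    def test_all_uninformative_intervals_rejected(self):
        ivs = [WtpInterval(0.0, np.inf, left_censored=True, right_censored=True)] * 5
        with pytest.raises(NonIdentifiableError):
            fit_interval_model(ivs)

    def test_vcov_symmetric_psd(self, synthetic_intervals):
        intervals, _ = synthetic_intervals
        fit = fit_interval_model(intervals[:500])
        v = fit.vcov.to_numpy()
        assert np.allclose(v, v.T)
        assert np.linalg.eigvalsh(v).min() > 0

    def test_refining_ladder_approaches_exact_mle(self, synthetic_intervals):
        # with a dense bid ladder the interval MLE nears the MLE on the
        # latent draws themselves (fitted by scipy on exact observations)
        _, latent = synthetic_intervals
        dense = cvwtp.BidSchedule(tuple(np.geomspace(0.05, 4000, 120)))
        answers = [list(latent[i] >= np.array(dense.amounts)) for i in range(800)]
        intervals = [build_interval(a, dense) for a in answers]
        fit = fit_interval_model(intervals)
        c_hat, _, scale_hat = stats.fisk.fit(latent[:800], floc=0)
        assert fit.alpha == pytest.approx(c_hat, rel=0.05)
        assert np.exp(fit.delta["const"] / fit.alpha) == pytest.approx(scale_hat, rel=0.05)


class TestMeanWtp:
    @staticmethod
    def unit_fit(alpha, delta0=0.0):
        names = ["const", "alpha"]
        return cvwtp.IntervalFit(
            delta=pd.Series({"const": delta0}),
            alpha=alpha,
            vcov=pd.DataFrame(np.eye(2), index=names, columns=names),
            loglik=-1.0,
            n=10,
            converged=True,
            iterations=1,
            covariate_means=pd.Series({"const": 1.0}),
        )

    def test_closed_form_example(self):
        est = mean_wtp(self.unit_fit(2.0))
        assert est.median == pytest.approx(1.0)
        assert est.mean == pytest.approx(np.pi / 2)

    def test_printed_variant_value(self):
        est = mean_wtp(self.unit_fit(2.0), method="printed_eq4")
        assert est.mean == pytest.approx(np.exp(1 / 8.0))

    def test_closed_form_diverges_for_small_alpha(self):
        with pytest.raises(MeanUndefinedError, match="truncated"):
            mean_wtp(self.unit_fit(0.9))

    def test_truncated_mean_below_closed_form(self, synthetic_intervals):
        intervals, _ = synthetic_intervals
        fit = fit_interval_model(intervals[:800])
        full = mean_wtp(fit, method="closed_form")
        truncated = mean_wtp(fit, method="truncated_at_max_bid")
        assert truncated.mean < full.mean
        assert truncated.median == full.median

    def test_mean_exceeds_median_for_alpha_above_one(self, synthetic_intervals):
        intervals, _ = synthetic_intervals
        est = mean_wtp(fit_interval_model(intervals[:800]))
        assert est.mean > est.median


class TestRecodingMonotonicity:
    def test_larger_yes_sets_never_shrink_brackets_or_median(self, survey500):
        _, records, _, _ = survey500
        grids = [r.certainty_grid for r in records if r.participates == 1]
        lowers, medians = [], []
        for scheme in (DEFINITELY_YES_SCHEME, PROBABLY_YES_SCHEME, NOT_SURE_SCHEME):
            intervals, _ = build_intervals(grids, scheme=scheme)
            lowers.append(np.array([iv.lower for iv in intervals]))
            medians.append(mean_wtp(fit_interval_model(intervals)).median)
        assert (lowers[0] <= lowers[1]).all() and (lowers[1] <= lowers[2]).all()
        assert medians[0] <= medians[1] <= medians[2]


class TestBootstrap:
    def test_same_seed_reproduces_ci_exactly(self, survey500):
        _, records, _, _ = survey500
        grids = [r.certainty_grid for r in records if r.participates == 1]
        intervals, _ = build_intervals(grids)
        b1 = bootstrap_ci(intervals, B=150, seed=4)
        b2 = bootstrap_ci(intervals, B=150, seed=4)
        b3 = bootstrap_ci(intervals, B=150, seed=5)
        assert (b1.ci_low, b1.ci_high) == (b2.ci_low, b2.ci_high)
        assert (b1.ci_low, b1.ci_high) != (b3.ci_low, b3.ci_high)
        # different seeds agree within Monte-Carlo noise
        assert b3.ci_low == pytest.approx(b1.ci_low, rel=0.15)
        assert b3.ci_high == pytest.approx(b1.ci_high, rel=0.15)
        assert b1.ci_low < b1.ci_high

    def test_minimum_replicate_count_enforced(self, survey500):
        _, records, _, _ = survey500
        grids = [r.certainty_grid for r in records if r.participates == 1]
        intervals, _ = build_intervals(grids[:50])
        with pytest.raises(ValueError):
            bootstrap_ci(intervals, B=50, seed=1)

    def test_near_degenerate_data_gives_near_zero_width(self):
        # two balanced patterns pinning both parameters: replicate
        # estimates vary only through resample counts, so the CI is tight
        ivs = [WtpInterval(40.0, 80.0)] * 400 + [
            WtpInterval(0.0, 1.0, left_censored=True)
        ] * 8
        boot = bootstrap_ci(ivs, B=120, seed=2, method="truncated_at_max_bid")
        width = boot.ci_high - boot.ci_low
        assert width / boot.ci_high < 0.25


class TestAggregation:
    def test_reported_total_and_bounds(self):
        result = aggregate_wtp(41.595, 0.616, 235_349, ci=(33.347, 49.862))
        assert result.total / 1e6 == pytest.approx(6.03, abs=0.005)
        assert result.total_low / 1e6 == pytest.approx(4.83, abs=0.005)
        assert result.total_high / 1e6 == pytest.approx(7.23, abs=0.005)

    def test_product_invariant_and_zero_proportion(self):
        result = aggregate_wtp(10.0, 0.0, 1000)
        assert result.total == 0.0
        result = aggregate_wtp(12.5, 0.4, 100)
        assert result.total == pytest.approx(12.5 * 0.4 * 100)

    def test_accepts_estimate_object(self):
        est = cvwtp.WtpEstimate(
            mean=41.595,
            median=30.0,
            method="closed_form",
            covariate_point=pd.Series({"const": 1.0}),
            ci_low=33.347,
            ci_high=49.862,
        )
        result = aggregate_wtp(est, 0.616, 235_349)
        assert result.total_low < result.total < result.total_high

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_wtp(10.0, 1.5, 100)
        with pytest.raises(ValueError):
            aggregate_wtp(10.0, 0.5, 0)
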