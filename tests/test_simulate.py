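import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cvwtp
from cvwtp.simulate import (
    ConfigError,
    SimulationConfig,
    sample_bounded,
    simulate_covariates,
    simulate_participation,
    simulate_payment_card,
)


class TestDeterminism:
    def test_same_seed_same_tables(self):
        config = SimulationConfig(n=200, seed=9)
        a = simulate_covariates(config)
        b = simulate_covariates(config)
        pd.testing.assert_frame_equal(a, b)

    def test_fixture_files_byte_identical(self, tmp_path):
        config = SimulationConfig(n=120, seed=5)
        p1, t1 = cvwtp.make_fixture(config, tmp_path / "a.csv", tmp_path / "a.json")
        p2, t2 = cvwtp.make_fixture(config, tmp_path / "b.csv", tmp_path / "b.json")
        assert p1.read_bytes() == p2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_covariates(SimulationConfig(n=200, seed=1))
        b = simulate_covariates(SimulationConfig(n=200, seed=2))
        assert not a.equals(b)


class TestCovariateMoments:
    def test_attitude_mean_matches_target(self):
        config = SimulationConfig(n=100_000, seed=3)
        frame = simulate_covariates(config)
        assert frame["attitude"].mean() == pytest.approx(3.30, abs=0.02)

    def test_all_composite_moments_match(self):
        config = SimulationConfig(n=100_000, seed=4)
        frame = simulate_covariates(config)
        for name, (mean, sd) in config.composite_moments.items():
            assert frame[name].mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(config.n) + 0.01)
            assert frame[name].std() == pytest.approx(sd, rel=0.05)
            assert frame[name].between(1, 5).all()

    def test_gender_proportion_within_3se(self):
        config = SimulationConfig(n=100_000, seed=5)
        frame = simulate_covariates(config)
        se = np.sqrt(0.51 * 0.49 / config.n)
        assert abs(frame["gender"].mean() - 0.51) < 3 * se

    def test_items_are_valid_likert_answers(self, survey500):
        _, _, covariates, _ = survey500
        from cvwtp.survey_io import ITEM_COLUMNS

        block = covariates[list(ITEM_COLUMNS)]
        assert block.isin([1, 2, 3, 4, 5]).all().all()

    def test_scored_items_track_latent_composites(self, survey500):
        # re-scored item means follow the latent composite used in the DGP
        _, _, covariates, _ = survey500
        scored = cvwtp.score_all(covariates)
        for name in ("attitude", "knowledge", "moralistic"):
            r = np.corrcoef(scored[name], covariates[name])[0, 1]
            assert r > 0.8

    def test_unreachable_moments_rejected(self, rng):
        with pytest.raises(ConfigError):
            sample_bounded(4.9, 2.0, 1, 5, 10, rng)  # sd beyond the support's cap


class TestParticipation:
    def test_zero_coefficients_give_half(self, rng):
        covariates = pd.DataFrame(index=range(50_000))
        y, prob = simulate_participation(covariates, {"const": 0.0}, rng=rng)
        assert prob == pytest.approx(0.5)
        assert y.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(y)))

    def test_default_intercept_gives_616(self, rng):
        covariates = pd.DataFrame(index=range(50_000))
        y, prob = simulate_participation(
            covariates, {"const": float(np.log(0.616 / 0.384))}, rng=rng
        )
        assert prob == pytest.approx(0.616, abs=1e-12)
        assert y.mean() == pytest.approx(0.616, abs=0.01)

    def test_logit_recovers_slope(self, rng):
        n = 2000
        covariates = pd.DataFrame({"knowledge": rng.normal(3.2, 1.0, n)})
        beta = {"const": 0.2, "knowledge": 0.4}
        y, _ = simulate_participation(covariates, beta, rng=rng)
        fit = cvwtp.fit_logit(y, covariates)
        for name, truth in beta.items():
            assert abs(fit.coefficients[name] - truth) < 3 * fit.se[name]

    def test_unknown_covariate_name_rejected(self, rng):
        with pytest.raises(ConfigError):
            simulate_participation(pd.DataFrame({"x": [1.0]}), {"ghost": 1.0}, rng=rng)


class TestPaymentCard:
    def test_grids_bracket_latent_wtp(self):
        n = 10_000
        covariates = pd.DataFrame(index=range(n))
        grids, latent = simulate_payment_card(
            covariates, {"const": 1.8 * np.log(40)}, 1.8, seed=11
        )
        intervals, _ = cvwtp.build_intervals(list(grids))
        for iv, w in zip(intervals, latent):
            assert iv.lower <= w < iv.upper
            assert iv.monotone

    def test_two_band_degenerate_case_reproduces_threshold(self):
        n = 5000
        covariates = pd.DataFrame(index=range(n))
        grids, latent = simulate_payment_card(
            covariates,
            {"const": 1.8 * np.log(40)},
            1.8,
            certainty_bands=(0.0, 0.0, 0.0, 0.0),
            seed=12,
            jitter_sd=0.0,
        )
        assert set(np.unique(grids)) <= {1, 5}
        amounts = np.array(cvwtp.DEFAULT_BIDS.amounts)
        expected = latent[:, None] >= amounts[None, :]
        for scheme in cvwtp.SCHEMES.values():
            recoded = np.array([cvwtp.recode_certainty(g, scheme) for g in grids])
            assert (recoded == expected).all()

    def test_median_of_latent_draws(self):
        n = 100_000
        covariates = pd.DataFrame(index=range(n))
        _, latent = simulate_payment_card(
            covariates, {"const": 1.8 * np.log(40)}, 1.8, seed=13
        )
        assert np.median(latent) == pytest.approx(40.0, rel=0.03)

    def test_latent_distribution_is_loglogistic(self):
        # KS distance below the 1% critical value in most seeds
        n = 10_000
        crit = 1.628 / np.sqrt(n)
        passes = 0
        for seed in range(10):
            covariates = pd.DataFrame(index=range(n))
            _, latent = simulate_payment_card(
                covariates, {"const": 1.8 * np.log(40)}, 1.8, seed=seed
            )
            d = stats.kstest(latent, stats.fisk(c=1.8, scale=40.0).cdf).statistic
            passes += d < crit
        assert passes >= 9

    def test_all_five_levels_occur(self, survey500):
        _, records, _, _ = survey500
        levels = {c for r in records if r.certainty_grid for c in r.certainty_grid}
        assert len(levels) == 5

    def test_bad_bands_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(certainty_bands=(0.0, 0.5, -0.5, -1.0))


class TestFixture:
    def test_fixture_reads_back_and_validates(self, tmp_path):
        config = SimulationConfig(n=150, seed=21)
        csv_path, truth_path = cvwtp.make_fixture(
            config, tmp_path / "f.csv", tmp_path / "f.json"
        )
        records = cvwtp.read_survey(csv_path)
        assert len(records) == 150
        truth = json.loads(truth_path.read_text())
        assert truth["wtp_alpha"] == config.wtp_alpha
        assert len(truth["latent_wtp"]) == 150
        participants = [r for r in records if r.participates == 1]
        assert all(r.certainty_grid is not None for r in participants)
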