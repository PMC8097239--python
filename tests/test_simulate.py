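"""Microsimulator contracts: internal consistency, determinism, regimes."""

import numpy as np
import pandas as pd
import pytest

import openinterval as oi
from openinterval.errors import ConfigurationError, DomainError
from openinterval.simulate import DESIRED_PARITIES, MARRIAGE_AGES, _make_config
from openinterval.survey_io import parse_birth_histories


def tiny_config(**overrides):
    kw = dict(
        monthly_fecundability=0.1,
        postpartum_infecundable_months=9,
        contraceptive_prevalence=0.5,
        contraceptive_effectiveness=0.9,
        desired_parity_distribution=np.eye(len(DESIRED_PARITIES))[3],
        marriage_age_distribution=np.full(len(MARRIAGE_AGES), 1 / len(MARRIAGE_AGES)),
        cohort_size=200,
        seed=1,
    )
    kw.update(overrides)
    return oi.SimulationConfig(**kw)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("monthly_fecundability", 1.5),
            ("contraceptive_prevalence", -0.1),
            ("contraceptive_effectiveness", 2.0),
            ("cohort_size", 0),
            ("postpartum_infecundable_months", -1),
            ("annual_growth_rate", -0.01),
        ],
    )
    def test_invalid_value_names_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            tiny_config(**{field: value})

    def test_probability_vector_must_normalize(self):
        bad = np.full(len(DESIRED_PARITIES), 0.1)
        with pytest.raises(ConfigurationError, match="desired_parity_distribution"):
            tiny_config(desired_parity_distribution=bad)


class TestSimulateSurvey:
    def test_no_conception_possible_yields_all_nulliparae(self):
        cfg = tiny_config(
            monthly_fecundability=0.0,
            desired_parity_distribution=np.eye(len(DESIRED_PARITIES))[0],
        )
        records = oi.simulate_survey(cfg)
        assert (records["parity"] == 0).all()
        assert not records["currently_pregnant"].any()
        assert records["last_birth_cmc"].isna().all()

    def test_same_seed_identical_output(self):
        a = oi.simulate_survey(tiny_config(cohort_size=500, seed=9))
        b = oi.simulate_survey(tiny_config(cohort_size=500, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_growing_cohort_preserves_earlier_women(self):
        small = oi.simulate_survey(tiny_config(cohort_size=150, seed=5))
        large = oi.simulate_survey(tiny_config(cohort_size=300, seed=5))
        pd.testing.assert_frame_equal(small, large.iloc[:150].reset_index(drop=True))

    def test_records_internally_consistent(self, high_survey):
        df = high_survey
        histories = parse_birth_histories(df)
        lengths = np.array([len(h) for h in histories])
        assert (lengths == df["parity"].to_numpy()).all()
        mothers = df["parity"] > 0
        last = np.array([h[-1] if len(h) else -1 for h in histories])
        assert (last[mothers] == df.loc[mothers, "last_birth_cmc"]).all()
        months_since = (df.loc[mothers, "interview_cmc"]
                        - df.loc[mothers, "last_birth_cmc"])
        assert (months_since >= 0).all()
        assert df.loc[~mothers, "last_birth_cmc"].isna().all()
        assert df["age_years"].between(15, 49).all()

    def test_pregnancies_resolve_within_gestation(self, high_survey):
        # a currently pregnant woman's next birth is within gestation months,
        # so her state never contradicts the recorded history
        cfg = oi.high_fertility_preset(cohort_size=8000, seed=42).config
        pregnant = high_survey["currently_pregnant"]
        assert 0.05 < pregnant.mean() < 0.35

    def test_survey_instant_invariance(self):
        """Under fixed rates the census date is exchangeable (stable state)."""
        base = oi.high_fertility_preset(cohort_size=6000, seed=3).config
        import dataclasses

        later = dataclasses.replace(base, survey_cmc=base.survey_cmc + 240)
        d0 = oi.tabulate_distribution(oi.simulate_survey(base)).percentages
        d1 = oi.tabulate_distribution(oi.simulate_survey(later)).percentages
        assert np.abs(d0 - d1).max() < 2.5  # multinomial noise at n~5k

    def test_high_fertility_distribution_non_increasing(self):
        cfg = oi.high_fertility_preset(cohort_size=20_000, seed=11).config
        dist = oi.tabulate_distribution(oi.simulate_survey(cfg))
        diffs = np.diff(dist.percentages)
        assert (diffs <= 0.2).all()  # monotone up to bin noise


class TestPowerLawSampler:
    def test_counts_sum_to_n(self):
        d = oi.sample_power_law_survey(0.5, 1.5, 1234, seed=0)
        assert d.n_eligible == 1234

    def test_single_trial_lands_in_one_bin(self):
        d = oi.sample_power_law_survey(0.5, 1.5, 1, seed=0)
        assert (d.counts == 1).sum() == 1 and d.counts.sum() == 1

    def test_flat_limit_near_uniform(self):
        n = 20_000
        d = oi.sample_power_law_survey(0.5, 1e-9, n, seed=2)
        expected = n / 20
        se = np.sqrt(n * (1 / 20) * (19 / 20))
        assert np.abs(d.counts - expected).max() < 5 * se

    @pytest.mark.parametrize("a,b,n", [(0, 1, 10), (1, -1, 10), (1, 1, 0)])
    def test_domain_errors(self, a, b, n):
        with pytest.raises(DomainError):
            oi.sample_power_law_survey(a, b, n)

    def test_refit_recovers_slope(self):
        d = oi.sample_power_law_survey(0.5, 1.5, 10_000, seed=3)
        assert abs(oi.fit_power(d).params["b"] - 1.5) < 0.1


class TestStationaryRenewalSampler:
    def test_exponential_backward_times_memoryless(self):
        from scipy import stats

        backward, _ = oi.sample_stationary_renewal(
            lambda size, rng: rng.exponential(24.0, size), 50_000, seed=4
        )
        ks = stats.ks_1samp(backward, stats.expon(scale=24.0).cdf)
        assert ks.statistic < 0.02

    def test_uniform_closed_density_at_zero(self):
        # f_B(0) = 1/mu = 1/12 per month for uniform(0, 24) closed intervals
        backward, _ = oi.sample_stationary_renewal(
            lambda size, rng: rng.uniform(0.0, 24.0, size), 50_000, seed=5
        )
        density_near_zero = np.mean(backward < 2.0) / 2.0
        assert density_near_zero == pytest.approx(1 / 12, rel=0.1)

    def test_degenerate_closed_gives_uniform_backward(self):
        backward, forward = oi.sample_stationary_renewal(
            lambda size, rng: np.full(size, 24.0), 20_000, seed=6
        )
        assert backward.max() < 24.0 and backward.min() >= 0.0
        # uniform on [0, 24): mean 12, variance 48
        assert backward.mean() == pytest.approx(12.0, rel=0.05)
        assert np.allclose(backward + forward, 24.0)

    def test_forward_backward_exchangeable(self):
        from scipy import stats

        backward, forward = oi.sample_stationary_renewal(
            lambda size, rng: rng.gamma(4.0, 7.5, size), 5_000, seed=7
        )
        assert stats.ks_2samp(backward, forward).pvalue > 0.01

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(DomainError):
            oi.sample_stationary_renewal(
                lambda size, rng: np.zeros(size), 100, seed=0
            )

    def test_deterministic_under_seed(self):
        sampler = lambda size, rng: rng.exponential(10.0, size)  # noqa: E731
        b1, f1 = oi.sample_stationary_renewal(sampler, 500, seed=8)
        b2, f2 = oi.sample_stationary_renewal(sampler, 500, seed=8)
        assert np.array_equal(b1, b2) and np.array_equal(f1, f2)


class TestPresets:
    def test_presets_include_both_regimes(self):
        assert {"niger", "colombia"} <= set(oi.PRESETS)

    def test_high_first_interval_exceeds_transitional(self, high_survey, trans_survey):
        hi = oi.tabulate_distribution(high_survey).percentages[0]
        lo = oi.tabulate_distribution(trans_survey).percentages[0]
        assert hi > lo
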