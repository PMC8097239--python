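"""Interval binning rules, decompositions, and printed-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import openinterval as oi
from openinterval.errors import DomainError, EmptyInputError

from conftest import make_records


class TestOpenIntervalYear:
    def test_pregnant_nullipara_in_first_interval(self):
        rec = dict(woman_id="x", interview_cmc=1200, age_years=22, parity=0,
                   last_birth_cmc=None, currently_pregnant=True,
                   currently_married=True)
        assert oi.open_interval_year(rec) == 1

    def test_pregnant_mother_forced_to_first_interval(self):
        # her last birth was 5 years ago but pregnancy overrides the bin
        rec = dict(woman_id="x", interview_cmc=1200, age_years=30, parity=2,
                   last_birth_cmc=1140, currently_pregnant=True,
                   currently_married=True)
        assert oi.open_interval_year(rec) == 1

    @pytest.mark.parametrize("months,expected", [(0, 1), (6, 1), (11, 1),
                                                 (12, 2), (30, 3), (239, 20)])
    def test_month_to_year_binning(self, months, expected):
        rec = dict(woman_id="x", interview_cmc=1200, age_years=40, parity=2,
                   last_birth_cmc=1200 - months, currently_pregnant=False,
                   currently_married=True)
        assert oi.open_interval_year(rec) == expected

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(last_birth_cmc=1200 - 240),                  # 20+ years
            dict(currently_married=False),
            dict(parity=0, last_birth_cmc=None),              # never gave birth
            dict(age_years=52),
        ],
    )
    def test_exclusions(self, overrides):
        rec = dict(woman_id="x", interview_cmc=1200, age_years=30, parity=2,
                   last_birth_cmc=1190, currently_pregnant=False,
                   currently_married=True)
        rec.update(overrides)
        assert oi.open_interval_year(rec) is None

    def test_negative_interval_is_data_error(self):
        rec = dict(woman_id="x", interview_cmc=1200, age_years=30, parity=1,
                   last_birth_cmc=1250, currently_pregnant=False,
                   currently_married=True)
        with pytest.raises(DomainError):
            oi.open_interval_year(rec)


class TestTabulateDistribution:
    def test_all_pregnant_concentrates_first_bin(self):
        records = make_records(currently_pregnant=[True] * 5)
        dist = oi.tabulate_distribution(records)
        assert dist.percentages[0] == 100.0

    def test_hand_built_counts_and_exclusion(self):
        records = make_records(
            last_birth_cmc=[1200 - 3, 1200 - 15, 1200 - 15, 1200 - 250],
            parity=[1, 1, 1, 1],
        )
        dist = oi.tabulate_distribution(records)
        assert dist.counts[:3].tolist() == [1, 2, 0]
        assert dist.n_eligible == 3
        assert dist.exclusions == {"interval_20plus_years": 1}

    def test_percentages_sum_to_100(self, high_survey):
        dist = oi.tabulate_distribution(high_survey)
        assert dist.percentages.sum() == pytest.approx(100.0, abs=1e-6)
        assert dist.counts.sum() == dist.n_eligible

    def test_empty_input_raises(self):
        records = make_records(currently_married=[False] * 3)
        with pytest.raises(EmptyInputError):
            oi.tabulate_distribution(records)

    def test_invariant_to_order_and_duplication(self, trans_survey):
        base = oi.tabulate_distribution(trans_survey).percentages
        shuffled = oi.tabulate_distribution(
            trans_survey.sample(frac=1, random_state=0)
        ).percentages
        doubled = oi.tabulate_distribution(
            pd.concat([trans_survey, trans_survey])
        ).percentages
        assert np.allclose(base, shuffled)
        assert np.allclose(base, doubled)

    def test_high_fertility_first_interval_exceeds_low(self, high_survey,
                                                       trans_survey):
        hi = oi.tabulate_distribution(high_survey).percentages[0]
        lo = oi.tabulate_distribution(trans_survey).percentages[0]
        assert hi > lo + 10


class TestComposition:
    def test_single_age_dominates_every_interval(self):
        records = make_records(
            age_years=[20] * 40,
            last_birth_cmc=list(1200 - np.arange(40) * 6),
            parity=[1] * 40,
        )
        comp = oi.composition_by_interval(records, "age")
        filled = comp.shares.loc["20-24"].dropna()
        assert (filled == 100.0).all()

    def test_shares_sum_to_100_in_nonempty_intervals(self, high_survey):
        comp = oi.composition_by_interval(high_survey, "parity")
        sums = comp.shares.sum(axis=0, skipna=False).dropna()
        assert np.allclose(sums, 100.0)

    def test_mean_age_rises_with_interval_length(self, high_survey):
        comp = oi.composition_by_interval(high_survey, "age")
        means = comp.means[~np.isnan(comp.means)]
        # systematic increase: compare smoothed thirds of the curve
        assert means[:5].mean() < means[5:10].mean() < means[-5:].mean()

    def test_low_parities_gain_in_middle_intervals(self, trans_survey):
        comp = oi.composition_by_interval(trans_survey, "parity")
        share_1to3 = comp.shares.loc[["1", "2", "3"]].sum(axis=0)
        mid = share_1to3[list(range(7, 15))].mean()
        assert mid > share_1to3[1]

    def test_empty_interval_flagged_not_nan_propagated(self):
        records = make_records(parity=[1, 1], last_birth_cmc=[1195, 1190])
        comp = oi.composition_by_interval(records, "age")
        assert set(comp.empty_intervals) == set(range(2, 21))
        assert not np.isnan(comp.shares[1]).any()


class TestAgeParityTable:
    def test_all_nulliparous(self):
        records = make_records(parity=[0] * 6, last_birth_cmc=[None] * 6,
                               age_years=[17, 22, 27, 32, 37, 42])
        apt = oi.age_parity_table(records)
        filled = apt.table.dropna()
        assert (filled["p0"] == 100.0).all()
        assert (apt.row_means.dropna() == 0.0).all()

    def test_hand_built_row(self):
        records = make_records(
            age_years=[17] * 10,
            parity=[0] * 4 + [1] * 5 + [2],
            last_birth_cmc=[None] * 4 + [1190] * 6,
        )
        apt = oi.age_parity_table(records)
        row = apt.table.loc["15-19"]
        assert row[["p0", "p1", "p2"]].tolist() == [40.0, 50.0, 10.0]
        assert apt.row_means["15-19"] == pytest.approx(0.70)

    def test_true_parity_not_topcoded_in_means(self):
        records = make_records(age_years=[30] * 2, parity=[8, 0],
                               last_birth_cmc=[1190, None])
        apt = oi.age_parity_table(records)
        assert apt.row_means["30-34"] == pytest.approx(4.0)
        assert apt.table.loc["30-34", "p6plus"] == 50.0

    def test_includes_unmarried_never(self, trans_survey):
        apt = oi.age_parity_table(trans_survey)
        married = trans_survey[
            trans_survey["currently_married"]
            & trans_survey["age_years"].between(15, 49)
        ]
        assert apt.row_counts.sum() == len(married)


class TestPrintedRowMean:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((41.6, 48.7, 7.1, 0.9, 1.6, 0.0, 0.0), 0.72),  # Colombia 15-19 1990
            ((19.6, 48.8, 22.4, 7.7, 1.3, 0.2, 0.0), 1.23),  # Colombia 20-24 2015
            ((100, 0, 0, 0, 0, 0, 0), 0.00),
        ],
    )
    def test_reconstructs_printed_means(self, row, expected):
        assert oi.mean_parity_from_printed_row(row) == expected

    def test_rejects_negative_and_bad_sum(self):
        with pytest.raises(DomainError):
            oi.mean_parity_from_printed_row((-1, 101, 0, 0, 0, 0, 0))
        with pytest.raises(DomainError):
            oi.mean_parity_from_printed_row((10, 10, 10, 10, 10, 10, 10))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=7, max_size=7))
    def test_mean_bounded_by_support(self, raw):
        p = np.array(raw)
        if p.sum() == 0:
            return
        p = 100 * p / p.sum()
        m = oi.mean_parity_from_printed_row(p)
        assert 0.0 <= m <= 6.0


class TestMeanOpenInterval:
    def test_binned_all_first_interval(self):
        dist = oi.OpenIntervalDistribution("t", [10] + [0] * 19)
        assert oi.mean_open_interval(dist) == 0.5

    def test_binned_uniform(self):
        dist = oi.OpenIntervalDistribution("t", [5] * 20)
        assert oi.mean_open_interval(dist) == pytest.approx(10.0)

    def test_microdata_vs_binned_agree(self, trans_survey):
        exact = oi.mean_open_interval(trans_survey)
        binned = oi.mean_open_interval(oi.tabulate_distribution(trans_survey))
        assert abs(exact - binned) < 0.5
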