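"""Stratified descriptive statistics."""

import numpy as np
import pytest

import hedgelife as hl
from hedgelife.records import Cause, DeathRecord, Habitat, Sex


def rec(age=1, sex=Sex.MALE, month=None, cause=Cause.UNKNOWN, habitat=None, i=[0]):
    i[0] += 1
    return DeathRecord(id=f"r{i[0]}", sex=sex, age_years=age, death_month=month,
                       cause=cause, habitat=habitat)


class TestMeanAgeCI:
    @pytest.mark.parametrize(
        "stratum, expected_mean, ci",
        [
            ("all", 1.8, (1.62, 2.04)),
            ("female", 1.6, (1.32, 1.93)),
            ("male", 2.1, (1.73, 2.47)),
        ],
    )
    def test_study_sample_intervals(self, study_records, stratum, expected_mean, ci):
        data = (
            study_records
            if stratum == "all"
            else [r for r in study_records if r.sex.value == stratum]
        )
        est = hl.mean_age_ci(data)
        assert round(est.mean, 1) == expected_mean
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == ci
        assert est.ci_low <= est.mean <= est.ci_high

    def test_degenerate_spread(self):
        est = hl.mean_age_ci([2, 2, 2, 2])
        assert est.mean == 2 and est.sd == 0
        assert (est.ci_low, est.ci_high) == (2, 2)

    def test_single_observation_flagged(self):
        est = hl.mean_age_ci([3])
        assert est.mean == 3 and not est.ci_defined

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            hl.mean_age_ci([])
        with pytest.raises(ValueError):
            hl.mean_age_ci([1, 2], level=1.5)

    def test_ci_width_shrinks_as_root_n(self):
        # quadrupling the data roughly halves the interval (exactly, up to
        # the ddof=1 correction in the pooled standard deviation)
        base = [0, 1, 2, 3, 4]
        w1 = hl.mean_age_ci(base)
        w4 = hl.mean_age_ci(base * 4)
        assert (w1.ci_high - w1.ci_low) / (w4.ci_high - w4.ci_low) == pytest.approx(
            2.0, rel=0.1
        )

    def test_coverage_of_simulated_means(self):
        """The 95% z-interval covers the true mean ~95% of the time."""
        rng = np.random.default_rng(11)
        n, reps, true = 40, 1000, 5.0
        draws = rng.normal(true, 2.0, size=(reps, n))
        m = draws.mean(axis=1)
        half = 1.959963984540054 * draws.std(axis=1, ddof=1) / np.sqrt(n)
        coverage = np.mean((m - half <= true) & (true <= m + half))
        # binomial 3-sigma band around 0.95 at 1000 reps, z interval slightly light
        assert 0.92 <= coverage <= 0.975


class TestMeanAgeExcluding:
    def test_adults_only(self, study_records):
        est = hl.mean_age_excluding(study_records, 1)
        assert est.n == 279 and est.n_excluded == 109
        assert round(est.mean, 1) == 2.5

    def test_zero_threshold_is_noop(self, study_records):
        full = hl.mean_age_ci(study_records)
        filt = hl.mean_age_excluding(study_records, 0)
        assert (filt.n, filt.mean) == (full.n, full.mean)

    def test_filter_removing_everything_errors(self, study_records):
        with pytest.raises(ValueError):
            hl.mean_age_excluding(study_records, 99)


class TestMonthlyDistribution:
    def test_single_dated_record(self):
        dist = hl.monthly_distribution([rec(month=9)], by=())
        assert dist.proportions.loc["all", 9] == 1.0
        assert dist.peaks["all"] == {9}

    def test_uniform_counts_tie(self):
        records = [rec(month=m) for m in range(1, 13)]
        dist = hl.monthly_distribution(records, by=())
        assert dist.peaks["all"] == set(range(1, 13))

    def test_proportions_sum_to_one(self):
        records = [rec(month=m, sex=s) for m in (5, 7, 7, 9)
                   for s in (Sex.MALE, Sex.FEMALE)]
        dist = hl.monthly_distribution(records, by=("sex",))
        np.testing.assert_allclose(dist.proportions.sum(axis=1), 1.0)

    def test_simulated_default_peaks(self):
        """The packaged generator places the modal months by sex and cause
        class: July for males, September for female non-traffic deaths."""
        records = hl.simulate_cohort(hl.default_study_config(n=40000, seed=5))
        sexed = [r for r in records if r.sex is not Sex.UNKNOWN]
        dist = hl.monthly_distribution(sexed, by=("sex", "cause_class"))
        assert dist.peaks["male/non_traffic"] == {7}
        assert dist.peaks["male/traffic"] == {7}
        assert dist.peaks["female/traffic"] == {7}
        assert dist.peaks["female/non_traffic"] == {9}

    def test_undated_records_error(self):
        with pytest.raises(ValueError, match="death month"):
            hl.monthly_distribution([rec(month=None)])


class TestCrossTab:
    def test_cause_mixture_percentages(self):
        records = (
            [rec(cause=Cause.TRAFFIC) for _ in range(216)]
            + [rec(cause=Cause.IN_CARE) for _ in range(86)]
            + [rec(cause=Cause.WILD) for _ in range(84)]
            + [rec(cause=Cause.UNKNOWN) for _ in range(2)]
        )
        tab = hl.crosstab(records, "cause")
        pct = tab.percent_total()["n"].round(1)
        assert pct["traffic"] == 55.7
        assert pct["in_care"] == 22.2
        assert pct["wild"] == 21.6
        assert pct["unknown"] == 0.5

    def test_roadkill_habitat_split(self):
        records = [rec(cause=Cause.TRAFFIC, habitat=Habitat.URBAN) for _ in range(78)]
        records += [rec(cause=Cause.TRAFFIC, habitat=Habitat.RURAL) for _ in range(130)]
        tab = hl.crosstab(records, "habitat")
        pct = tab.percent_total()["n"].round(1)
        assert pct["urban"] == 37.5 and pct["rural"] == 62.5

    def test_margins_reconcile_with_tabulation(self, study_records):
        tab = hl.crosstab(study_records, "sex", "age_years")
        strata = hl.tabulate_ages(study_records, "sex")
        for sex, total in tab.row_margin.items():
            assert total == strata[sex].n_total
        assert tab.total == len(study_records)

    def test_percentages_sum_to_100(self, study_records):
        tab = hl.crosstab(study_records, "sex", "cause")
        assert tab.percent_total().to_numpy().sum() == pytest.approx(100.0)
        np.testing.assert_allclose(tab.percent_row().sum(axis=1), 100.0)

    def test_unknown_factor_errors(self, study_records):
        with pytest.raises(ValueError, match="unknown factor"):
            hl.crosstab(study_records, "color")


class TestSexLongevityRatio:
    def test_rounded_and_full_precision_variants(self):
        r = hl.sex_longevity_ratio(2.6, 2.1)
        assert round(r.full_precision) == 24
        r2 = hl.sex_longevity_ratio(2.602, 2.124)
        assert round(r2.full_precision, 1) == 22.5
        assert round(r2.rounded_inputs) == 24  # computed on 2.6 / 2.1

    def test_identity(self):
        r = hl.sex_longevity_ratio(1.7, 1.7)
        assert r.full_precision == 0.0

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            hl.sex_longevity_ratio(0.0, 1.0)
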