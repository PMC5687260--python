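"""Death rates, ESD outlier screening, tolerance zones, hospital selection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from codbench import (
    HospitalRates,
    ScreenResult,
    StatisticalError,
    ValidationError,
    count_zone_membership,
    generalized_esd,
    inpatient_death_rate,
    normality_check,
    screen_hospitals,
    select_top_contributors,
    tolerance_zone,
)
from codbench.rate_benchmarking import DEFAULT_BENCHMARKS


class TestDeathRate:
    def test_direct_arithmetic(self):
        assert inpatient_death_rate(5, 250) == 2.0
        assert inpatient_death_rate(0, 50) == 0.0

    @pytest.mark.parametrize("deaths,hosp", [(7, 0), (5, 4), (-1, 10)])
    def test_preconditions(self, deaths, hosp):
        with pytest.raises(ValidationError):
            inpatient_death_rate(deaths, hosp)


def _grubbs_two_sided(values, alpha):
    """Independent single-outlier oracle: two-sided Grubbs test."""
    x = np.asarray(values, float)
    n = x.size
    g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
    idx = int(np.argmax(np.abs(x - x.mean())))
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
    return (idx if g > g_crit else None), g


class TestGeneralizedEsd:
    def test_gross_outlier_flagged(self):
        res = generalized_esd([1, 2, 3, 4, 100], ids=list("abcde"), k_max=1, alpha=0.1)
        assert res.n_outliers == 1 and res.outlier_ids == ("e",)

    def test_constant_data_yields_no_outliers(self):
        res = generalized_esd([5.0] * 7, k_max=2, alpha=0.1)
        assert res.n_outliers == 0 and res.outlier_ids == ()

    def test_matches_grubbs_on_mixed_data(self):
        # single-outlier case must agree with the classical Grubbs test
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.normal(10, 2, 20)
            if rng.random() < 0.5:
                x[3] += rng.uniform(5, 15)
            res = generalized_esd(x, k_max=1, alpha=0.05)
            oracle_idx, g = _grubbs_two_sided(x, 0.05)
            assert res.statistics[0] == pytest.approx(g)
            if oracle_idx is None:
                assert res.n_outliers == 0
            else:
                assert res.n_outliers == 1 and res.outlier_ids == (str(oracle_idx),)

    @given(
        a=st.floats(min_value=0.1, max_value=50).flatmap(
            lambda v: st.sampled_from([v, -v])
        ),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, a, b):
        """Studentized deviations are location-scale invariant, so any affine
        transform preserves the flagged ids and the R_i sequence."""
        x = np.array([1.2, 3.4, 2.2, 1.9, 2.8, 2.1, 14.0, 2.6, 1.4, 2.3])
        base = generalized_esd(x, k_max=2, alpha=0.1)
        shifted = generalized_esd(a * x + b, k_max=2, alpha=0.1)
        assert shifted.outlier_ids == base.outlier_ids
        assert np.allclose(shifted.statistics, base.statistics)

    @pytest.mark.parametrize("seed", range(10))
    def test_alpha_monotonicity(self, seed):
        """Enlarging alpha can only declare more outliers, never fewer."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 25)
        x[:3] += rng.uniform(2, 8, 3)
        counts = [
            generalized_esd(x, k_max=5, alpha=a).n_outliers
            for a in (0.01, 0.05, 0.1, 0.2)
        ]
        assert counts == sorted(counts)

    def test_preconditions(self):
        with pytest.raises(StatisticalError):
            generalized_esd([1, 2, 3], k_max=2)  # n < k_max + 2
        with pytest.raises(StatisticalError):
            generalized_esd([1, 2, 3, 4], k_max=0)

    def test_result_shape_invariants(self):
        rng = np.random.default_rng(11)
        res = generalized_esd(rng.normal(size=30), k_max=4, alpha=0.1)
        assert len(res.statistics) == len(res.critical_values) == res.tested_k
        assert res.n_outliers <= res.tested_k
        assert len(res.outlier_ids) == res.n_outliers


class TestNormalityCheck:
    def test_too_small_sample_rejected(self):
        with pytest.raises(StatisticalError):
            normality_check([1.0, 2.0])

    def test_matches_independent_reference_implementation(self):
        # 27 standard-normal values from default_rng(20260929) rounded to 6
        # decimals; W and p frozen from R 4.3.3 shapiro.test on the same data
        x = np.round(np.random.default_rng(20260929).standard_normal(27), 6)
        res = normality_check(x, alpha=0.05)
        assert res.W == pytest.approx(0.97436291, abs=1e-6)
        assert res.p_value == pytest.approx(0.71933475, abs=1e-6)
        assert res.passed

    def test_uniform_data_rejected_at_n_200(self):
        u = np.round(np.random.default_rng(421).uniform(0, 1, 200), 6)
        res = normality_check(u, alpha=0.05)
        # frozen from R 4.3.3: W = 0.94245335, p = 3.77e-07
        assert res.W == pytest.approx(0.94245335, abs=1e-6)
        assert not res.passed


class TestToleranceZone:
    @pytest.mark.parametrize(
        "benchmark,sd,high", [(3.5, 1.2, 5.9), (4.4, 4.65, 13.7), (3.1, 2.15, 7.4)]
    )
    def test_upper_bound(self, benchmark, sd, high):
        assert tolerance_zone(benchmark, sd).zone_high == pytest.approx(high)

    def test_zero_width_zone(self):
        z = tolerance_zone(2.0, 0.0)
        assert z.zone_low == z.zone_high == 2.0

    @given(benchmark=st.floats(0, 50), sd=st.floats(0, 20))
    def test_width_is_four_sd_and_benchmark_inside(self, benchmark, sd):
        z = tolerance_zone(benchmark, sd)
        assert z.zone_high - z.zone_low == pytest.approx(4 * sd)
        assert z.zone_low <= z.benchmark_rate <= z.zone_high

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            tolerance_zone(3.5, -0.1)


def _cohort(rates_by_cat, region="R", seed=0, hosp=5000):
    """Hospitals whose category rates are set exactly (deaths = rate% of hosp)."""
    out = []
    for i, rates in enumerate(rates_by_cat):
        deaths = {c: int(round(r / 100 * hosp)) for c, r in rates.items()}
        out.append(
            HospitalRates(
                hospital_id=f"H{i:02d}",
                region=region,
                deaths=deaths,
                hospitalizations={c: hosp for c in rates},
            )
        )
    return out


BASE = {"heart": 3.5, "cancer": 4.4, "renal": 3.1, "other": 0.85}


class TestScreenHospitals:
    def test_cohort_at_benchmark_flags_nothing(self):
        cohort = _cohort([dict(BASE)] * 10)
        res = screen_hospitals(cohort)
        assert res.outlier_hospitals == frozenset()
        assert res.flagged == frozenset()

    def test_renal_only_exceedance_flagged_by_any_category_rule(self):
        rng = np.random.default_rng(3)
        rows = [
            {c: v + rng.normal(0, 0.1) for c, v in BASE.items()} for _ in range(14)
        ]
        rows.append({**BASE, "renal": BASE["renal"] + 2.5})
        res = screen_hospitals(_cohort(rows))
        assert "H14" in (res.flagged | res.outlier_hospitals)

    def test_outliers_leave_the_normalized_set(self):
        rng = np.random.default_rng(4)
        rows = [
            {c: v + rng.normal(0, 0.15) for c, v in BASE.items()} for _ in range(20)
        ]
        rows[2]["heart"] += 12.0
        res = screen_hospitals(_cohort(rows))
        assert res.outlier_hospitals & set(res.normalized_set) == set()
        assert res.flagged <= set(res.normalized_set)
        assert res.selected_contributors <= res.flagged
        assert res.study_hospitals == res.outlier_hospitals | res.selected_contributors

    def test_implanted_rate_inflation_detected(self):
        """Two hospitals with 5x heart mortality among 30 are caught by the
        ESD/zone screen in (essentially) every replicate."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            cohort = []
            for i in range(30):
                mult = 5.0 if i < 2 else 1.0
                deaths, hosp = {}, {}
                for c, r in BASE.items():
                    h = 4000
                    deaths[c] = int(rng.binomial(h, min(1.0, mult * r / 100) if c == "heart" else r / 100))
                    hosp[c] = h
                cohort.append(
                    HospitalRates(f"H{i:02d}", "R", deaths=deaths, hospitalizations=hosp)
                )
            res = screen_hospitals(cohort)
            if {"H00", "H01"} <= (res.outlier_hospitals | res.flagged):
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_normality_failure_is_warning_not_error(self):
        rng = np.random.default_rng(9)
        rows = [
            {c: v + float(rng.exponential(1.5)) for c, v in BASE.items()}
            for _ in range(25)
        ]
        res = screen_hospitals(_cohort(rows))  # heavily skewed rates
        assert any("Shapiro" in w for w in res.warnings)

    def test_deterministic_given_input_order(self):
        rng = np.random.default_rng(12)
        rows = [{c: v + rng.normal(0, 0.3) for c, v in BASE.items()} for _ in range(18)]
        cohort = _cohort(rows)
        a, b = screen_hospitals(cohort), screen_hospitals(cohort)
        assert a.to_dict() == b.to_dict()


class TestZoneMembership:
    def test_constructed_counts(self):
        # 10 hospitals in one region: 1 heart ESD outlier, 3 more above the
        # heart zone -> (within 6, outside 3, outliers 1)
        rows = [dict(BASE) for _ in range(10)]
        for i in (1, 2, 3):
            rows[i]["heart"] = 6.5
        rows[0]["heart"] = 20.0
        cohort = _cohort(rows)
        res = screen_hospitals(cohort)
        assert res.esd_by_category["heart"].outlier_ids == ("H00",)
        table = count_zone_membership(res, cohort).set_index(["region", "category"])
        heart = table.loc[("R", "heart")]
        assert (heart.within, heart.outside, heart.outliers) == (6, 3, 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_counts_partition_region_totals(self, seed):
        rng = np.random.default_rng(seed)
        regions = ["East"] * 9 + ["West"] * 11
        rows = []
        for _ in regions:
            row = {c: max(0.0, v + rng.normal(0, 0.6)) for c, v in BASE.items()}
            rows.append(row)
        cohort = [
            HospitalRates(
                f"H{i:02d}",
                regions[i],
                deaths={c: int(round(r / 100 * 5000)) for c, r in rows[i].items()},
                hospitalizations={c: 5000 for c in rows[i]},
            )
            for i in range(len(regions))
        ]
        res = screen_hospitals(cohort)
        table = count_zone_membership(res, cohort)
        totals = {"East": 9, "West": 11}
        for _, r in table.iterrows():
            assert r.within + r.outside + r.outliers == totals[r.region]

    def test_unlabeled_hospital_rejected(self):
        cohort = _cohort([dict(BASE)] * 10)
        res = screen_hospitals(cohort)
        bad = [
            HospitalRates(h.hospital_id, "", h.deaths, h.hospitalizations)
            for h in cohort
        ]
        with pytest.raises(ValidationError):
            count_zone_membership(res, bad)


class TestSelectTopContributors:
    def test_orders_by_death_volume(self):
        got = select_top_contributors(
            {"A", "B", "C"}, {"A": 100, "B": 300, "C": 200}, k=2
        )
        assert got == {"B", "C"}

    def test_k_equals_flagged_is_identity(self):
        flagged = {"A", "B", "C"}
        assert select_top_contributors(flagged, {"A": 1, "B": 2, "C": 3}, 3) == flagged

    def test_tie_broken_lexicographically(self):
        got = select_top_contributors({"A", "B", "C"}, {"A": 200, "B": 200, "C": 300}, 2)
        assert got == {"A", "C"}

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            select_top_contributors({"A"}, {"A": 1}, 2)
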