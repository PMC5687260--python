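"""Hospital death-rate benchmarking and outlier screening.

The screening algorithm identifies hospitals whose cause-specific inpatient
death rates deviate from a national benchmark:

1. For each disease category, compute each hospital's inpatient death rate —
   deaths from the cause per 100 hospitalizations with that diagnosis.
2. Run Rosner's generalized extreme Studentized deviate (ESD) test per
   category (two-sided, alpha = 0.1 by default) and remove the union of the
   flagged hospitals ("outliers").
3. Re-check the remaining ("normalized") rate sets for normality with the
   Shapiro–Wilk test; failure is a recorded warning, not an error.
4. Compute the per-category SD of the normalized rates and build a tolerance
   zone of benchmark ± 2 SD around the externally supplied benchmark rate.
5. Flag every remaining hospital whose rate reaches the upper zone bound in
   any disease category, and select the top contributors among the flagged
   by all-cause death volume.

The benchmark rates are inputs, never estimated from the cohort; packaged
defaults are the national inpatient rates heart 3.5, cancer 4.4, renal 3.1
and all-cause 2.0 per 100 hospitalizations. Only the high side of the zone
flags: excess mortality reporting is the screening concern, and low rates are
reported but not acted on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cause_coding import ALL_CAUSE, DISEASE_CATEGORIES
from .errors import StatisticalError, ValidationError

__all__ = [
    "DEFAULT_BENCHMARKS",
    "HospitalRates",
    "Benchmark",
    "EsdResult",
    "NormalityResult",
    "ScreenResult",
    "inpatient_death_rate",
    "generalized_esd",
    "normality_check",
    "tolerance_zone",
    "screen_hospitals",
    "count_zone_membership",
    "select_top_contributors",
]

#: National benchmark inpatient death rates (% of hospitalizations), supplied
#: externally; these packaged defaults come from national 2010 estimates.
DEFAULT_BENCHMARKS: dict[str, float] = {
    "heart": 3.5,
    "cancer": 4.4,
    "renal": 3.1,
    ALL_CAUSE: 2.0,
}


def inpatient_death_rate(deaths: int, hospitalizations: int) -> float:
    """Deaths from a cause per 100 hospitalizations with that diagnosis.

    Raises
    ------
    ValidationError
        If ``hospitalizations`` is zero/negative or ``deaths`` exceeds it.
    """
    if hospitalizations <= 0:
        raise ValidationError("hospitalizations must be positive")
    if deaths < 0 or deaths > hospitalizations:
        raise ValidationError(
            f"deaths ({deaths}) must lie in [0, hospitalizations={hospitalizations}]"
        )
    return 100.0 * deaths / hospitalizations


@dataclass(frozen=True)
class HospitalRates:
    """Per-hospital death and hospitalization counts by cause category.

    ``deaths`` and ``hospitalizations`` are keyed by category name; the
    all-cause totals are derived by summing over the categories present.
    """

    hospital_id: str
    region: str
    deaths: Mapping[str, int]
    hospitalizations: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.hospital_id:
            raise ValidationError("hospital_id must be non-empty")
        for cat, d in self.deaths.items():
            h = self.hospitalizations.get(cat)
            if h is None:
                raise ValidationError(
                    f"{self.hospital_id}: deaths given for {cat!r} without hospitalizations"
                )
            if h <= 0:
                raise ValidationError(f"{self.hospital_id}/{cat}: hospitalizations must be positive")
            if d < 0 or d > h:
                raise ValidationError(
                    f"{self.hospital_id}/{cat}: deaths ({d}) outside [0, {h}]"
                )

    @property
    def all_cause_deaths(self) -> int:
        return int(sum(self.deaths.values()))

    @property
    def all_cause_hospitalizations(self) -> int:
        return int(sum(self.hospitalizations.values()))

    def rate(self, category: str) -> float:
        """Death rate (%) for a category, or the all-cause rate."""
        if category == ALL_CAUSE:
            return inpatient_death_rate(self.all_cause_deaths, self.all_cause_hospitalizations)
        if category not in self.deaths:
            raise ValidationError(f"{self.hospital_id}: no counts for category {category!r}")
        return inpatient_death_rate(self.deaths[category], self.hospitalizations[category])


@dataclass(frozen=True)
class Benchmark:
    """A benchmark rate and its ±2 SD tolerance zone."""

    category: str
    benchmark_rate: float
    sd: float
    zone_low: float
    zone_high: float


def tolerance_zone(benchmark_rate: float, sd: float, category: str = ALL_CAUSE) -> Benchmark:
    """Build the benchmark ± 2 SD tolerance zone.

    ``sd`` is the standard deviation of the normalized (post-ESD) hospital
    rate set for the category, in percentage points.
    """
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    return Benchmark(
        category=category,
        benchmark_rate=float(benchmark_rate),
        sd=float(sd),
        zone_low=float(benchmark_rate - 2.0 * sd),
        zone_high=float(benchmark_rate + 2.0 * sd),
    )


@dataclass(frozen=True)
class EsdResult:
    """Outcome of Rosner's generalized ESD multi-outlier test.

    ``statistics[i]`` is R_{i+1}, the maximum studentized absolute deviation
    after removing i values; ``critical_values[i]`` the matching λ. By
    Rosner's rule ``n_outliers`` is the largest i with R_i > λ_i, and
    ``outlier_ids`` lists the first ``n_outliers`` removed values in removal
    order.
    """

    tested_k: int
    statistics: tuple[float, ...]
    critical_values: tuple[float, ...]
    n_outliers: int
    outlier_ids: tuple[str, ...]
    alpha: float


def _esd_critical_value(n: int, i: int, alpha: float, two_sided: bool) -> float:
    # Rosner's lambda_i: t quantile at 1 - alpha/(2(n-i+1)) (two-sided) with
    # n-i-1 degrees of freedom, for the sample of size n-i+1 remaining at step i.
    m = n - i + 1
    p = 1.0 - alpha / (2.0 * m) if two_sided else 1.0 - alpha / m
    nu = n - i - 1
    t = stats.t.ppf(p, nu)
    return (n - i) * t / math.sqrt((nu + t * t) * m)


def generalized_esd(
    values: Sequence[float],
    ids: Sequence[str] | None = None,
    k_max: int | None = None,
    alpha: float = 0.1,
    two_sided: bool = True,
) -> EsdResult:
    """Rosner's generalized ESD test for up to ``k_max`` outliers.

    At step i the value with the largest studentized deviation from the mean
    of the remaining data is removed and R_i recorded; the declared number of
    outliers is the largest i whose R_i exceeds the t-based critical value.
    A one-sided test (``two_sided=False``) considers only high deviations.

    ``k_max`` defaults to ``max(1, floor(0.2 n))``, a conventional cap on the
    outlier fraction. If the remaining values become constant (sample SD 0)
    the procedure stops early and declares no further outliers: constant data
    are legitimately outlier-free.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValidationError("ids must parallel values")
    if k_max is None:
        k_max = max(1, n // 5)
    if k_max < 1:
        raise StatisticalError("k_max must be at least 1")
    if n < k_max + 2:
        raise StatisticalError(f"need at least k_max+2={k_max + 2} values, got {n}")

    remaining = x.copy()
    rem_ids = list(ids)
    statistics: list[float] = []
    criticals: list[float] = []
    removed: list[str] = []
    for i in range(1, k_max + 1):
        m = remaining.mean()
        s = remaining.std(ddof=1)
        if s == 0.0:
            break
        dev = np.abs(remaining - m) if two_sided else remaining - m
        j = int(np.argmax(dev))
        statistics.append(float(dev[j] / s))
        criticals.append(_esd_critical_value(n, i, alpha, two_sided))
        removed.append(rem_ids.pop(j))
        remaining = np.delete(remaining, j)

    n_outliers = 0
    for i, (r, lam) in enumerate(zip(statistics, criticals), start=1):
        if r > lam:
            n_outliers = i
    return EsdResult(
        tested_k=len(statistics),
        statistics=tuple(statistics),
        critical_values=tuple(criticals),
        n_outliers=n_outliers,
        outlier_ids=tuple(removed[:n_outliers]),
        alpha=alpha,
    )


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro–Wilk test outcome; ``passed`` iff p ≥ alpha."""

    W: float
    p_value: float
    passed: bool
    alpha: float


def normality_check(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk normality test (requires 3 ≤ n ≤ 5000)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise StatisticalError(f"Shapiro–Wilk requires 3 <= n <= 5000, got {x.size}")
    w, p = stats.shapiro(x)
    return NormalityResult(W=float(w), p_value=float(p), passed=bool(p >= alpha), alpha=alpha)


@dataclass
class ScreenResult:
    """Full outcome of the benchmark screening flow."""

    outlier_hospitals: frozenset[str]
    normalized_set: tuple[str, ...]
    esd_by_category: dict[str, EsdResult]
    normality_by_category: dict[str, NormalityResult]
    benchmarks: dict[str, Benchmark]
    flagged: frozenset[str]
    selected_contributors: frozenset[str]
    study_hospitals: frozenset[str]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        """JSON-serializable representation (sets as sorted lists)."""
        return {
            "outlier_hospitals": sorted(self.outlier_hospitals),
            "normalized_set": list(self.normalized_set),
            "esd_by_category": {
                c: {
                    "tested_k": r.tested_k,
                    "statistics": list(r.statistics),
                    "critical_values": list(r.critical_values),
                    "n_outliers": r.n_outliers,
                    "outlier_ids": list(r.outlier_ids),
                    "alpha": r.alpha,
                }
                for c, r in self.esd_by_category.items()
            },
            "normality_by_category": {
                c: {"W": r.W, "p_value": r.p_value, "passed": r.passed, "alpha": r.alpha}
                for c, r in self.normality_by_category.items()
            },
            "benchmarks": {
                c: {
                    "benchmark_rate": b.benchmark_rate,
                    "sd": b.sd,
                    "zone_low": b.zone_low,
                    "zone_high": b.zone_high,
                }
                for c, b in self.benchmarks.items()
            },
            "flagged": sorted(self.flagged),
            "selected_contributors": sorted(self.selected_contributors),
            "study_hospitals": sorted(self.study_hospitals),
            "warnings": list(self.warnings),
        }


def select_top_contributors(
    flagged: Iterable[str], all_cause_deaths: Mapping[str, int], k: int
) -> frozenset[str]:
    """The ``k`` flagged hospitals contributing the most all-cause deaths.

    Ties at the cut are broken toward the lexicographically smaller hospital
    id so the selection is deterministic.
    """
    flagged = sorted(flagged)
    if k > len(flagged):
        raise ValidationError(f"k={k} exceeds number of flagged hospitals ({len(flagged)})")
    ranked = sorted(flagged, key=lambda h: (-all_cause_deaths[h], h))
    return frozenset(ranked[:k])


def screen_hospitals(
    rates: Sequence[HospitalRates],
    benchmark_rates: Mapping[str, float] | None = None,
    k_max: int | None = None,
    esd_alpha: float = 0.1,
    sw_alpha: float = 0.05,
    top_k: int = 3,
) -> ScreenResult:
    """Run the full benchmark screening flow on a hospital cohort.

    ``benchmark_rates`` maps category → national rate (%); disease categories
    are screened with ESD and flagged against their zones, and an all-cause
    zone is built for reporting. ``top_k`` caps the number of flagged
    hospitals selected by death volume (clamped to the number flagged).
    """
    if benchmark_rates is None:
        benchmark_rates = DEFAULT_BENCHMARKS
    ids = [h.hospital_id for h in rates]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate hospital ids")
    by_id = {h.hospital_id: h for h in rates}
    warnings: list[str] = []

    # (1) per-category ESD; the union of flagged hospitals leaves the cohort
    esd_by_category: dict[str, EsdResult] = {}
    outliers: set[str] = set()
    for cat in DISEASE_CATEGORIES:
        values = [h.rate(cat) for h in rates]
        res = generalized_esd(values, ids=ids, k_max=k_max, alpha=esd_alpha, two_sided=True)
        esd_by_category[cat] = res
        outliers.update(res.outlier_ids)

    normalized = tuple(i for i in ids if i not in outliers)
    if len(normalized) < 3:
        raise StatisticalError("fewer than 3 hospitals remain after outlier removal")

    # (3) normality re-check and (4) tolerance zones on the normalized set
    normality: dict[str, NormalityResult] = {}
    benchmarks: dict[str, Benchmark] = {}
    zone_categories = list(DISEASE_CATEGORIES) + (
        [ALL_CAUSE] if ALL_CAUSE in benchmark_rates else []
    )
    for cat in zone_categories:
        vals = np.array([by_id[i].rate(cat) for i in normalized])
        if cat in DISEASE_CATEGORIES and np.ptp(vals) > 0:  # SW undefined on constant data
            nres = normality_check(vals, alpha=sw_alpha)
            normality[cat] = nres
            if not nres.passed:
                warnings.append(
                    f"normalized {cat} rates fail Shapiro–Wilk normality "
                    f"(W={nres.W:.3f}, p={nres.p_value:.4f}); proceeding"
                )
        benchmarks[cat] = tolerance_zone(
            benchmark_rates[cat], float(vals.std(ddof=1)), category=cat
        )

    # (5) flag hospitals at/above the upper zone bound in any disease category;
    # a rate must also exceed the benchmark itself so a zero-width zone
    # (constant cohort) flags nobody
    flagged = frozenset(
        i for i in normalized if any(_outside_high(by_id[i], benchmarks[c]) for c in DISEASE_CATEGORIES)
    )
    deaths = {i: by_id[i].all_cause_deaths for i in flagged}
    selected = select_top_contributors(flagged, deaths, min(top_k, len(flagged)))
    return ScreenResult(
        outlier_hospitals=frozenset(outliers),
        normalized_set=normalized,
        esd_by_category=esd_by_category,
        normality_by_category=normality,
        benchmarks=benchmarks,
        flagged=flagged,
        selected_contributors=selected,
        study_hospitals=frozenset(outliers) | selected,
        warnings=tuple(warnings),
    )


def _outside_high(hospital: HospitalRates, benchmark: Benchmark) -> bool:
    r = hospital.rate(benchmark.category)
    return r >= benchmark.zone_high and r > benchmark.benchmark_rate


def count_zone_membership(result: ScreenResult, rates: Sequence[HospitalRates]):
    """Per-region, per-category tolerance-zone membership counts.

    For each region and category the hospitals split into three classes:
    that category's ESD outliers, remaining hospitals at/above the upper zone
    bound ("outside"), and the rest ("within"); the three counts sum to the
    region's hospital total. Returns a tidy DataFrame with columns
    ``region, category, within, outside, outliers``.
    """
    import pandas as pd

    for h in rates:
        if not h.region:
            raise ValidationError(f"hospital {h.hospital_id} has no region label")
    categories = list(result.benchmarks)
    rows = []
    regions = sorted({h.region for h in rates})
    for region in regions:
        cohort = [h for h in rates if h.region == region]
        for cat in categories:
            cat_outliers = (
                set(result.esd_by_category[cat].outlier_ids)
                if cat in result.esd_by_category
                else set()
            )
            n_out = sum(1 for h in cohort if h.hospital_id in cat_outliers)
            rest = [h for h in cohort if h.hospital_id not in cat_outliers]
            outside = sum(1 for h in rest if _outside_high(h, result.benchmarks[cat]))
            rows.append(
                {
                    "region": region,
                    "category": cat,
                    "within": len(rest) - outside,
                    "outside": outside,
                    "outliers": n_out,
                }
            )
    return pd.DataFrame(rows)
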