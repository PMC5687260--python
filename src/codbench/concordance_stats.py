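"""Certificate-versus-chart concordance statistics for matched death records.

Each reviewed death contributes a matched pair: the cause category coded on
the death certificate and the gold-standard category from the medical-chart
review. For a cause X the discordant counts are

* b — certificate says X, chart disagrees (overreporting of X), and
* c — chart says X, certificate disagrees (underreporting of X).

Marginal symmetry is tested with McNemar's test. The exact form is the
default because discordant counts are often small: the two-sided p-value is
``min(1, 2 P(X <= min(b, c)))`` with X ~ Binomial(b + c, 1/2). The matched
conditional odds ratio is b/c, with either an exact-conditional confidence
interval (Clopper–Pearson for b out of b + c, mapped through p/(1-p)) or the
log-normal interval exp(ln(b/c) ± z sqrt(1/b + 1/c)).

Reported percentages are rounded half-up to one decimal, matching
vital-statistics table style; internal values stay unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cause_coding import CATEGORIES, DISEASE_CATEGORIES, IcdCodeSet, classify_cause, default_codesets
from .errors import StatisticalError, ValidationError
from .rounding import round_half_up

__all__ = [
    "INSUFFICIENT",
    "PairedDeathRecord",
    "DiscordantPair",
    "McNemarResult",
    "OddsRatioResult",
    "ConcordanceSummary",
    "build_pairs",
    "concordance_table",
    "mean_row",
    "discordant_counts",
    "mcnemar_test",
    "matched_odds_ratio",
    "cause_direction_report",
]

#: Chart label for records whose medical chart could not support a cause
#: determination; such records are excluded from pairs and counted.
INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class PairedDeathRecord:
    """One death's certificate category matched with its chart category."""

    hospital_id: str
    death_id: str
    dc_category: str
    chart_category: str

    def __post_init__(self) -> None:
        for value in (self.dc_category, self.chart_category):
            if value not in CATEGORIES:
                raise ValidationError(f"unknown cause category {value!r}")

    @property
    def concordant(self) -> bool:
        return self.dc_category == self.chart_category


@dataclass(frozen=True)
class DiscordantPair:
    """Discordant counts for one cause: b overreports, c underreports."""

    cause: str
    b: int
    c: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValidationError("discordant counts must be non-negative")


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    level: float
    method: str  # "exact-conditional" | "log-normal"
    corrected: bool = False


def build_pairs(
    records: pd.DataFrame | Iterable[Mapping],
    codesets: Sequence[IcdCodeSet] | None = None,
) -> tuple[list[PairedDeathRecord], int]:
    """Derive matched pairs from reviewed records.

    ``records`` needs fields ``hospital_id, death_id, dc_icd10,
    chart_category``; the certificate category is obtained by classifying the
    ICD-10 code. Records whose chart label is ``"insufficient"`` are excluded
    and returned as a count.
    """
    if codesets is None:
        codesets = default_codesets()
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    pairs: list[PairedDeathRecord] = []
    n_insufficient = 0
    for rec in records:
        for field in ("hospital_id", "death_id", "dc_icd10", "chart_category"):
            if field not in rec or rec[field] is None or rec[field] == "":
                raise ValidationError(f"record missing field {field!r}: {rec!r}")
        chart = str(rec["chart_category"]).strip().lower()
        if chart == INSUFFICIENT:
            n_insufficient += 1
            continue
        pairs.append(
            PairedDeathRecord(
                hospital_id=str(rec["hospital_id"]),
                death_id=str(rec["death_id"]),
                dc_category=classify_cause(rec["dc_icd10"], codesets),
                chart_category=chart,
            )
        )
    return pairs, n_insufficient


@dataclass
class ConcordanceSummary:
    """Per-hospital inaccuracy percentages with an unweighted mean row.

    ``table`` holds unrounded values indexed by hospital id with columns
    ``n_reviewed, n_inaccurate, pct_inaccurate, pct_heart, pct_cancer,
    pct_renal``. The per-cause columns give, among a hospital's inaccurate
    certificates, the percentage whose *certificate* category was the named
    cause (the remainder had "other" on the certificate, so rows sum to at
    most 100).
    """

    table: pd.DataFrame

    @property
    def mean_row(self) -> pd.Series:
        return mean_row(self.table)

    def with_mean_row(self, decimals: int = 1) -> pd.DataFrame:
        """Report-style table: percentages rounded half-up, plus a Mean row."""
        pct_cols = [c for c in self.table.columns if c.startswith("pct_")]
        out = self.table.copy()
        out[pct_cols] = out[pct_cols].map(lambda v: round_half_up(v, decimals))
        mean = self.mean_row
        out.loc["Mean"] = [mean.get(c, np.nan) for c in out.columns]
        return out


def mean_row(table: pd.DataFrame, decimals: int = 1) -> pd.Series:
    """Unweighted mean of the per-hospital percentage columns, rounded half-up."""
    pct_cols = [c for c in table.columns if c.startswith("pct_")]
    if not pct_cols:
        raise ValidationError("no percentage columns (pct_*) to average")
    return table[pct_cols].mean().map(lambda v: round_half_up(v, decimals))


def concordance_table(pairs: Sequence[PairedDeathRecord]) -> ConcordanceSummary:
    """Per-hospital concordance summary over matched pairs.

    Raises :class:`ValidationError` on empty input (a hospital enters the
    table only with at least one reviewed pair).
    """
    if not pairs:
        raise ValidationError("no pairs to summarize")
    rows = {}
    hospitals = sorted({p.hospital_id for p in pairs})
    for hosp in hospitals:
        hp = [p for p in pairs if p.hospital_id == hosp]
        inacc = [p for p in hp if not p.concordant]
        n, n_in = len(hp), len(inacc)
        row = {
            "n_reviewed": n,
            "n_inaccurate": n_in,
            "pct_inaccurate": 100.0 * n_in / n,
        }
        for cause in DISEASE_CATEGORIES:
            num = sum(1 for p in inacc if p.dc_category == cause)
            row[f"pct_{cause}"] = 100.0 * num / n_in if n_in else 0.0
        rows[hosp] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "hospital_id"
    return ConcordanceSummary(table=table)


def discordant_counts(pairs: Sequence[PairedDeathRecord], cause: str) -> DiscordantPair:
    """Count overreports (b) and underreports (c) of ``cause``."""
    if cause not in CATEGORIES:
        raise ValidationError(f"unknown cause category {cause!r}")
    b = sum(1 for p in pairs if p.dc_category == cause and p.chart_category != cause)
    c = sum(1 for p in pairs if p.chart_category == cause and p.dc_category != cause)
    return DiscordantPair(cause=cause, b=b, c=c)


def mcnemar_test(dp: DiscordantPair, exact: bool = True, alpha: float = 0.05) -> McNemarResult:
    """McNemar's test of marginal symmetry from discordant counts.

    Exact: two-sided binomial tail p = min(1, 2 P(X <= min(b,c))) with
    X ~ Binomial(b+c, 1/2) (p = 1 when b + c = 0). Asymptotic: chi-square
    statistic (b-c)^2/(b+c) on 1 df, requiring b + c >= 1.
    """
    b, c = dp.b, dp.c
    n = b + c
    if exact:
        if n == 0:
            return McNemarResult(b, c, statistic=0.0, p_value=1.0, method="exact", alpha=alpha)
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return McNemarResult(b, c, statistic=float(min(b, c)), p_value=p, method="exact", alpha=alpha)
    if n == 0:
        raise StatisticalError("asymptotic McNemar requires b + c >= 1")
    chi2 = (b - c) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(b, c, statistic=float(chi2), p_value=p, method="asymptotic", alpha=alpha)


def matched_odds_ratio(
    dp: DiscordantPair,
    level: float = 0.95,
    method: str = "exact-conditional",
    continuity: bool = False,
) -> OddsRatioResult:
    """Matched-pair conditional odds ratio b/c with a confidence interval.

    ``exact-conditional`` transforms the Clopper–Pearson interval for
    p = b/(b+c) through p/(1-p); ``log-normal`` uses the Wald interval on the
    log odds ratio. With ``continuity`` both counts get +1/2 (needed for a
    finite point estimate when c = 0).
    """
    b, c = dp.b, dp.c
    n = b + c
    if n == 0:
        raise StatisticalError("odds ratio undefined with no discordant pairs")
    bb, cc = (b + 0.5, c + 0.5) if continuity else (float(b), float(c))
    if cc == 0:
        raise StatisticalError("c = 0: point estimate requires continuity correction")
    or_value = bb / cc
    if method == "exact-conditional":
        ci = stats.binomtest(b, n, 0.5).proportion_ci(confidence_level=level, method="exact")
        lo = ci.low / (1.0 - ci.low) if ci.low < 1.0 else math.inf
        hi = ci.high / (1.0 - ci.high) if ci.high < 1.0 else math.inf
    elif method == "log-normal":
        if bb == 0:
            raise StatisticalError("b = 0: log-normal CI requires continuity correction")
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = math.sqrt(1.0 / bb + 1.0 / cc)
        lo = math.exp(math.log(or_value) - z * se)
        hi = math.exp(math.log(or_value) + z * se)
    else:
        raise ValidationError(f"unknown OR method {method!r}")
    return OddsRatioResult(
        or_value=float(or_value), ci_low=float(lo), ci_high=float(hi),
        level=level, method=method, corrected=continuity,
    )


def cause_direction_report(
    pairs: Sequence[PairedDeathRecord],
    by_hospital: bool = False,
    exact: bool = True,
    level: float = 0.95,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cause over/underreporting directions with tests and odds ratios.

    One row per cause (and per hospital when ``by_hospital``): discordant
    counts, McNemar statistic and p-value, the matched odds ratio with its
    exact-conditional CI, and the direction (``overreport`` when b > c,
    ``underreport`` when b < c, ``none`` on ties). When either discordant
    count is zero the reported OR uses the +1/2 continuity correction.
    """
    groups = (
        sorted({p.hospital_id for p in pairs}) if by_hospital else [None]
    )
    rows = []
    for group in groups:
        gp = [p for p in pairs if group is None or p.hospital_id == group]
        for cause in CATEGORIES:
            dp = discordant_counts(gp, cause)
            mc = mcnemar_test(dp, exact=exact, alpha=alpha)
            if dp.b + dp.c == 0:
                orr = None
            else:
                orr = matched_odds_ratio(
                    dp, level=level, continuity=(min(dp.b, dp.c) == 0)
                )
            direction = (
                "overreport" if dp.b > dp.c else "underreport" if dp.b < dp.c else "none"
            )
            rows.append(
                {
                    **({"hospital_id": group} if by_hospital else {}),
                    "cause": cause,
                    "b": dp.b,
                    "c": dp.c,
                    "statistic": mc.statistic,
                    "p_value": mc.p_value,
                    "significant": mc.significant,
                    "or_value": orr.or_value if orr else np.nan,
                    "ci_low": orr.ci_low if orr else np.nan,
                    "ci_high": orr.ci_high if orr else np.nan,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)
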