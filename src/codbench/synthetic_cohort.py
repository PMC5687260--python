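"""Synthetic hospital cohorts with a known cause-misreporting mechanism.

The generator produces a cohort of hospitals with per-category
hospitalization counts (negative binomial, for realistic size
heterogeneity), per-category true death probabilities, and individual death
records. Misreporting is modelled as a row-stochastic cause-transfer matrix
T: a death whose true (chart) cause is X is certified as cause Y with
probability T[X][Y]. Transfer moves cause labels without changing death
counts, so a hospital's all-cause certificate rate is invariant to T — the
signature of pure misclassification, as opposed to genuinely excess
mortality.

Every death record carries the true category (which doubles as the
gold-standard chart category), a certificate ICD-10 root sampled from the
certified category's code set, and a Bernoulli chart-availability flag.
Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cause_coding import CATEGORIES, OTHER, default_codesets
from .errors import ValidationError
from .rate_benchmarking import HospitalRates

__all__ = [
    "OTHER_ICD_ROOTS",
    "SimConfig",
    "SyntheticStudy",
    "identity_transfer",
    "simulate_study",
    "expected_certified_rate",
    "make_paper_like_scenario",
]

#: Representative ICD-10 roots for deaths outside the three disease
#: categories (pneumonia, COPD, sepsis, dementia, diabetes, liver failure,
#: stroke, respiratory failure, hip fracture, accident).
OTHER_ICD_ROOTS: tuple[str, ...] = (
    "J18", "J44", "A41", "G30", "E11", "K72", "I64", "J96", "S72", "V89",
)
# note: I64 is *not* in the heart set (I00-I51); stroke stays "other".

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


def identity_transfer() -> np.ndarray:
    """The no-misreporting transfer matrix."""
    return np.eye(len(CATEGORIES))


def _as_matrix(t) -> np.ndarray:
    m = np.asarray(t, dtype=float)
    if m.shape != (len(CATEGORIES), len(CATEGORIES)):
        raise ValidationError(f"transfer matrix must be {len(CATEGORIES)}x{len(CATEGORIES)}")
    if np.any(m < 0) or np.any(m > 1):
        raise ValidationError("transfer probabilities must lie in [0, 1]")
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("each transfer-matrix row must sum to 1")
    return m


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration for one synthetic cohort.

    ``transfer_matrix`` applies to every hospital index listed in
    ``misreporting_hospitals``; ``transfer_overrides`` may replace it for
    specific hospitals (e.g. a more severe small-hospital tier), and
    ``size_multipliers`` scales each hospital's mean hospitalization counts.
    ``hosp_dispersion`` is the negative-binomial shape (variance
    m + m^2/k); ``None`` gives Poisson counts.
    """

    n_hospitals: int
    region_labels: tuple[str, ...]
    hosp_means: Mapping[str, float]
    true_death_prob: Mapping[str, float]
    transfer_matrix: tuple = field(default_factory=lambda: tuple(map(tuple, np.eye(4))))
    misreporting_hospitals: tuple[int, ...] = ()
    chart_availability: float = 0.88
    seed: int = 0
    hosp_dispersion: float | None = 50.0
    size_multipliers: tuple[float, ...] | None = None
    transfer_overrides: Mapping[int, tuple] | None = None

    def validate(self) -> None:
        if self.n_hospitals < 5:
            raise ValidationError("need at least 5 hospitals")
        if len(self.region_labels) != self.n_hospitals:
            raise ValidationError("region_labels must have one label per hospital")
        for cat in CATEGORIES:
            if cat not in self.hosp_means or self.hosp_means[cat] <= 0:
                raise ValidationError(f"positive hospitalization mean required for {cat!r}")
            p = self.true_death_prob.get(cat)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValidationError(f"true death probability for {cat!r} must lie in [0, 1]")
        if not 0.0 <= self.chart_availability <= 1.0:
            raise ValidationError("chart_availability must lie in [0, 1]")
        _as_matrix(self.transfer_matrix)
        for idx in self.misreporting_hospitals:
            if not 0 <= idx < self.n_hospitals:
                raise ValidationError(f"misreporting hospital index {idx} out of range")
        if self.size_multipliers is not None and len(self.size_multipliers) != self.n_hospitals:
            raise ValidationError("size_multipliers must have one entry per hospital")
        for idx, t in (self.transfer_overrides or {}).items():
            if idx not in self.misreporting_hospitals:
                raise ValidationError(f"transfer override for non-misreporting hospital {idx}")
            _as_matrix(t)
        if self.hosp_dispersion is not None and self.hosp_dispersion <= 0:
            raise ValidationError("hosp_dispersion must be positive (or None for Poisson)")

    # -- helpers -----------------------------------------------------------
    def hospital_id(self, idx: int) -> str:
        return f"H{idx:02d}"

    @property
    def misreporting_ids(self) -> frozenset[str]:
        return frozenset(self.hospital_id(i) for i in self.misreporting_hospitals)

    def transfer_for(self, idx: int) -> np.ndarray:
        if idx not in self.misreporting_hospitals:
            return identity_transfer()
        if self.transfer_overrides and idx in self.transfer_overrides:
            return _as_matrix(self.transfer_overrides[idx])
        return _as_matrix(self.transfer_matrix)

    def size_multiplier(self, idx: int) -> float:
        return 1.0 if self.size_multipliers is None else float(self.size_multipliers[idx])

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_hospitals": self.n_hospitals,
            "region_labels": list(self.region_labels),
            "hosp_means": dict(self.hosp_means),
            "true_death_prob": dict(self.true_death_prob),
            "transfer_matrix": np.asarray(self.transfer_matrix, dtype=float).tolist(),
            "misreporting_hospitals": list(self.misreporting_hospitals),
            "chart_availability": self.chart_availability,
            "seed": self.seed,
            "hosp_dispersion": self.hosp_dispersion,
            "size_multipliers": None
            if self.size_multipliers is None
            else list(self.size_multipliers),
            "transfer_overrides": None
            if self.transfer_overrides is None
            else {
                str(k): np.asarray(v, dtype=float).tolist()
                for k, v in self.transfer_overrides.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        cfg = cls(
            n_hospitals=int(d["n_hospitals"]),
            region_labels=tuple(d["region_labels"]),
            hosp_means=dict(d["hosp_means"]),
            true_death_prob=dict(d["true_death_prob"]),
            transfer_matrix=tuple(map(tuple, d.get("transfer_matrix", np.eye(4)))),
            misreporting_hospitals=tuple(d.get("misreporting_hospitals", ())),
            chart_availability=float(d.get("chart_availability", 0.88)),
            seed=int(d.get("seed", 0)),
            hosp_dispersion=d.get("hosp_dispersion", 50.0),
            size_multipliers=None
            if d.get("size_multipliers") is None
            else tuple(float(x) for x in d["size_multipliers"]),
            transfer_overrides=None
            if d.get("transfer_overrides") is None
            else {int(k): tuple(map(tuple, v)) for k, v in d["transfer_overrides"].items()},
        )
        cfg.validate()
        return cfg


@dataclass
class SyntheticStudy:
    """A simulated cohort: counts, individual death records, and truth."""

    counts: pd.DataFrame  # hospital_id, region, category, hospitalizations, true_deaths, certified_deaths
    deaths: pd.DataFrame  # hospital_id, death_id, true_category, dc_icd10, chart_category, available
    config: SimConfig

    def hospital_rates(self) -> list[HospitalRates]:
        """Certificate-based :class:`HospitalRates` — what vital records show."""
        out = []
        for (hosp, region), grp in self.counts.groupby(["hospital_id", "region"], sort=True):
            out.append(
                HospitalRates(
                    hospital_id=hosp,
                    region=region,
                    deaths={r.category: int(r.certified_deaths) for r in grp.itertuples()},
                    hospitalizations={
                        r.category: int(r.hospitalizations) for r in grp.itertuples()
                    },
                )
            )
        return out


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Draw one synthetic study cohort; fully reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    codes_by_cat = {cs.category: sorted(cs.prefixes) for cs in default_codesets()}
    codes_by_cat[OTHER] = sorted(OTHER_ICD_ROOTS)

    count_rows = []
    death_rows = []
    for idx in range(config.n_hospitals):
        hosp = config.hospital_id(idx)
        region = config.region_labels[idx]
        T = config.transfer_for(idx)
        mult = config.size_multiplier(idx)
        for cat in CATEGORIES:
            mean = config.hosp_means[cat] * mult
            if config.hosp_dispersion is None:
                h = int(rng.poisson(mean))
            else:
                k = config.hosp_dispersion
                h = int(rng.negative_binomial(k, k / (k + mean)))
            h = max(h, 1)  # a hospital with a category has at least one admission
            d = int(rng.binomial(h, config.true_death_prob[cat]))
            d = min(d, h)
            dc_idx = rng.choice(len(CATEGORIES), size=d, p=T[_CAT_INDEX[cat]])
            available = rng.random(d) < config.chart_availability
            for j in range(d):
                dc_cat = CATEGORIES[dc_idx[j]]
                roots = codes_by_cat[dc_cat]
                death_rows.append(
                    {
                        "hospital_id": hosp,
                        "death_id": f"{hosp}-{cat}-{j:04d}",
                        "true_category": cat,
                        "dc_icd10": roots[int(rng.integers(len(roots)))],
                        "chart_category": cat,
                        "available": bool(available[j]),
                    }
                )
            count_rows.append(
                {
                    "hospital_id": hosp,
                    "region": region,
                    "category": cat,
                    "hospitalizations": h,
                    "true_deaths": d,
                }
            )
    counts = pd.DataFrame(count_rows)
    deaths = pd.DataFrame(
        death_rows,
        columns=["hospital_id", "death_id", "true_category", "dc_icd10", "chart_category", "available"],
    )
    # certified (certificate-category) death counts per hospital x category
    if len(deaths):
        dc_cat = deaths["dc_icd10"].map(
            {root: cat for cat, roots in codes_by_cat.items() for root in roots}
        )
        cert = (
            deaths.assign(dc_category=dc_cat)
            .groupby(["hospital_id", "dc_category"])
            .size()
            .rename("certified_deaths")
            .reset_index()
        )
        counts = counts.merge(
            cert,
            left_on=["hospital_id", "category"],
            right_on=["hospital_id", "dc_category"],
            how="left",
        ).drop(columns="dc_category")
        counts["certified_deaths"] = counts["certified_deaths"].fillna(0).astype(int)
    else:
        counts["certified_deaths"] = 0
    return SyntheticStudy(counts=counts, deaths=deaths, config=config)


def expected_certified_rate(config: SimConfig, hospital: int, category: str) -> float:
    """Closed-form expected certificate-based death rate (%), the simulation
    oracle: sum over true causes of (hospitalization mean x death
    probability x transfer probability), over the category's hospitalization
    mean. Size multipliers cancel. ``all_cause`` rates are invariant to T.
    """
    config.validate()
    T = config.transfer_for(hospital)
    means = config.hosp_means
    probs = config.true_death_prob
    if category == "all_cause":
        num = sum(means[t] * probs[t] for t in CATEGORIES)
        den = sum(means[t] for t in CATEGORIES)
        return 100.0 * num / den
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    j = _CAT_INDEX[category]
    num = sum(means[t] * probs[t] * T[_CAT_INDEX[t], j] for t in CATEGORIES)
    return 100.0 * num / means[category]


def make_paper_like_scenario(seed: int = 0) -> SimConfig:
    """A packaged 32-hospital two-region scenario with implanted misreporting.

    Baseline true death probabilities equal the packaged national benchmarks
    (heart 3.5%, cancer 4.4%, renal 3.1%; "other" set so the all-cause rate
    is 2.0%). Eight hospitals misreport in two tiers, mirroring the
    outliers-plus-top-contributors structure of the screening flow:

    * five small hospitals (0.3x size) with severe transfer — 90% of cancer
      deaths certified as heart disease and 90% of other-cause deaths
      certified as renal disease;
    * three large hospitals (2x size) with moderate transfer — 70%
      cancer-to-heart and 45% other-to-renal.

    Chart availability is 0.88, matching typical completeness of hospital
    medical records at review.
    """
    n = 32
    regions = tuple(["St. Louis"] * 17 + ["Kansas City"] * 15)
    outlier_tier = (3, 11, 20, 25, 29)   # 2 St. Louis + 3 Kansas City
    moderate_tier = (5, 8, 22)           # 2 St. Louis + 1 Kansas City

    def transfer(cancer_to_heart: float, other_to_renal: float) -> tuple:
        t = identity_transfer()
        ic, ih = _CAT_INDEX["cancer"], _CAT_INDEX["heart"]
        io, ir = _CAT_INDEX[OTHER], _CAT_INDEX["renal"]
        t[ic, ih], t[ic, ic] = cancer_to_heart, 1.0 - cancer_to_heart
        t[io, ir], t[io, io] = other_to_renal, 1.0 - other_to_renal
        return tuple(map(tuple, t))

    sizes = [1.0] * n
    for i in outlier_tier:
        sizes[i] = 0.3
    for i in moderate_tier:
        sizes[i] = 2.0
    cfg = SimConfig(
        n_hospitals=n,
        region_labels=regions,
        # four-year category hospitalization volumes for a mid-size hospital
        hosp_means={"heart": 3000.0, "cancer": 1500.0, "renal": 1000.0, OTHER: 8000.0},
        # benchmarks as truth; "other" tuned so the all-cause rate is 2.0%
        true_death_prob={"heart": 0.035, "cancer": 0.044, "renal": 0.031, OTHER: 0.0085},
        transfer_matrix=transfer(0.70, 0.45),
        misreporting_hospitals=tuple(sorted(outlier_tier + moderate_tier)),
        chart_availability=0.88,
        seed=seed,
        hosp_dispersion=50.0,  # ~15% CV on four-year aggregate category volumes
        size_multipliers=tuple(sizes),
        transfer_overrides={i: transfer(0.90, 0.90) for i in outlier_tier},
    )
    cfg.validate()
    return cfg
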