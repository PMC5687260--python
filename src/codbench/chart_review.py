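"""Chart-review sampling: sample-size calculation, random draws, availability.

Sample sizes target detection of a death-certificate completion error rate of
at least ``p_alt`` (default 20%) against a tolerable baseline ``p0`` (default
5%) with an exact one-sample binomial test. Charts are drawn per hospital by
simple random sampling without replacement, and a fraction of drawn charts is
unavailable or incomplete at review time (complete-case handling: unavailable
charts are dropped, no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import StatisticalError, ValidationError
from .rounding import round_half_up

__all__ = [
    "SamplePlan",
    "chart_sample_size",
    "draw_chart_sample",
    "apply_availability",
]


@dataclass(frozen=True)
class SamplePlan:
    """Bookkeeping for one hospital's chart sample.

    Invariant: ``n_reviewed <= n_drawn <= min(n_target, eligible_deaths)``.
    """

    hospital_id: str
    eligible_deaths: int
    n_target: int
    n_drawn: int
    n_reviewed: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_reviewed <= self.n_drawn <= min(self.n_target, self.eligible_deaths)):
            raise ValidationError(
                f"{self.hospital_id}: inconsistent sample plan "
                f"(reviewed {self.n_reviewed} <= drawn {self.n_drawn} <= "
                f"min(target {self.n_target}, eligible {self.eligible_deaths}) violated)"
            )

    @property
    def review_pct(self) -> int:
        """Reviewed share of drawn charts, as a rounded whole percentage."""
        if self.n_drawn == 0:
            return 0
        return int(round_half_up(100.0 * self.n_reviewed / self.n_drawn, 0))


def _critical_value(n: int, p0: float, alpha: float) -> int:
    """Smallest c with P(X >= c | n, p0) <= alpha (one-sided exact test)."""
    c = int(stats.binom.isf(alpha, n, p0)) + 1
    # isf can land one off at discontinuities; adjust to the exact definition
    while c > 0 and stats.binom.sf(c - 2, n, p0) <= alpha:
        c -= 1
    while stats.binom.sf(c - 1, n, p0) > alpha:
        c += 1
    return c


def chart_sample_size(
    p0: float,
    p_alt: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_max: int = 100_000,
) -> int:
    """Smallest n for which the exact one-sample binomial test of
    H0: p = ``p0`` rejects with probability ≥ ``power`` when p = ``p_alt``.

    The test is one-sided (reject for large error counts), appropriate for
    detecting an error rate of at least ``p_alt``.
    """
    if not (0 <= p0 < p_alt <= 1):
        raise ValidationError("require 0 <= p0 < p_alt <= 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    for n in range(1, n_max + 1):
        c = _critical_value(n, p0, alpha)
        if c > n:
            continue  # no rejection region at this n
        if stats.binom.sf(c - 1, n, p_alt) >= power:
            return n
    raise StatisticalError(f"no n <= {n_max} achieves the requested power")


def draw_chart_sample(death_ids: Sequence[str], n: int, seed: int) -> list[str]:
    """Uniform simple random sample of ``n`` death ids without replacement.

    Deterministic given (``death_ids`` order, ``n``, ``seed``).
    """
    if n > len(death_ids):
        raise ValidationError(f"sample size {n} exceeds population {len(death_ids)}")
    if n < 0:
        raise ValidationError("sample size must be non-negative")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(death_ids), size=n, replace=False)
    return [death_ids[i] for i in idx]


def apply_availability(
    sample: Sequence[str],
    availability: Mapping[str, bool] | float,
    seed: int | None = None,
    hospital_id: str = "",
    eligible_deaths: int | None = None,
    n_target: int | None = None,
) -> tuple[list[str], SamplePlan]:
    """Restrict a drawn sample to the charts actually available for review.

    ``availability`` is either a per-record boolean mapping or a global rate
    in [0, 1] applied as independent Bernoulli draws (requires ``seed``).
    Returns the reviewed subset and the hospital's :class:`SamplePlan`.
    """
    sample = list(sample)
    if isinstance(availability, (int, float)) and not isinstance(availability, bool):
        rate = float(availability)
        if not 0.0 <= rate <= 1.0:
            raise ValidationError("availability rate must lie in [0, 1]")
        if seed is None:
            raise ValidationError("a seed is required with a global availability rate")
        rng = np.random.default_rng(seed)
        flags = rng.random(len(sample)) < rate
        reviewed = [d for d, ok in zip(sample, flags) if ok]
    else:
        missing = [d for d in sample if d not in availability]
        if missing:
            raise ValidationError(f"availability flags missing for {len(missing)} records")
        reviewed = [d for d in sample if availability[d]]
    plan = SamplePlan(
        hospital_id=hospital_id,
        eligible_deaths=len(sample) if eligible_deaths is None else eligible_deaths,
        n_target=len(sample) if n_target is None else n_target,
        n_drawn=len(sample),
        n_reviewed=len(reviewed),
        seed=-1 if seed is None else int(seed),
    )
    return reviewed, plan
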