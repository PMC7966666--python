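"""Abridged life-table identities for youth mortality work.

The quantities manipulated here are period probabilities of dying
:math:`{}_nq_x` — the probability that a person alive at exact age *x* dies
before age *x + n* under the mortality rates of a given year — and the
corresponding central death rates :math:`{}_nm_x` (deaths per person-year of
exposure).  The headline indicator throughout the package is
:math:`{}_{10}q_{15}`, together with its split into :math:`{}_5q_{15}` and
:math:`{}_5q_{20}`.

All probabilities are stored per 1 internally; the per-1000 convention used in
reporting is applied only at the output layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "AgeBand",
    "QProbability",
    "CentralRate",
    "QObservation",
    "BAND_15_19",
    "BAND_20_24",
    "BAND_15_24",
    "BAND_0_4",
    "compose_q",
    "split_q",
    "q_to_m",
    "m_to_q",
    "annual_rate_of_reduction",
    "report_round",
    "OBSERVATION_COLUMNS",
    "SOURCE_TYPES",
]

#: Recognised observation source types.
SOURCE_TYPES = ("vr_complete", "vr_incomplete", "srs", "sibling", "census")

#: Column schema for observation tables (CSV and in-memory DataFrames).
OBSERVATION_COLUMNS = [
    "country",
    "series_id",
    "source_type",
    "ref_time",
    "collection_time",
    "age_start",
    "age_width",
    "q",
    "se_logq",
    "excluded",
    "exclusion_reason",
]


@dataclass(frozen=True, order=True)
class AgeBand:
    """Closed-open age interval [start_age, start_age + width).

    Parameters
    ----------
    start_age : int
        Exact age at the start of the band, in years.
    width : int
        Band width in years; must be positive.
    """

    start_age: int
    width: int

    def __post_init__(self) -> None:
        if self.start_age < 0 or self.width <= 0:
            raise ValueError(f"invalid age band ({self.start_age}, {self.width})")
        if self.start_age + self.width > 125:
            raise ValueError("age band extends past age 125")

    @property
    def end_age(self) -> int:
        return self.start_age + self.width

    def __str__(self) -> str:  # e.g. "15-24"
        return f"{self.start_age}-{self.end_age - 1}"


BAND_0_4 = AgeBand(0, 5)
BAND_15_19 = AgeBand(15, 5)
BAND_20_24 = AgeBand(20, 5)
BAND_15_24 = AgeBand(15, 10)


@dataclass(frozen=True)
class QProbability:
    """A probability of dying over an age band, stored per 1."""

    band: AgeBand
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value < 1.0:
            raise ValueError(f"q must lie in [0, 1), got {self.value}")

    @property
    def per_1000(self) -> float:
        return 1000.0 * self.value


@dataclass(frozen=True)
class CentralRate:
    """Central death rate over an age band (deaths per person-year)."""

    band: AgeBand
    value: float

    def __post_init__(self) -> None:
        if self.value < 0.0:
            raise ValueError("central rate must be non-negative")


@dataclass
class QObservation:
    """One mortality measurement entering the estimation database.

    The retrospective lag ``collection_time - ref_time`` is the time between
    the field date of the source (survey or census) and the midpoint of the
    period the measurement refers to; it drives the recall-bias model for
    sibling and census sources.  For vital registration the two coincide.
    """

    country: str
    series_id: str
    source_type: str
    ref_time: float
    collection_time: float
    band: AgeBand
    q: float
    se_logq: float
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        if self.collection_time < self.ref_time:
            raise ValueError("retrospective lag must be non-negative")
        if self.source_type in ("sibling", "census") and not self.se_logq > 0:
            raise ValueError("sibling/census observations require se_logq > 0")

    @property
    def lag(self) -> float:
        return self.collection_time - self.ref_time


def _as_value(q: QProbability | float) -> float:
    return q.value if isinstance(q, QProbability) else float(q)


def compose_q(q_a: QProbability, q_b: QProbability) -> QProbability:
    """Combine probabilities over adjacent bands: q = 1 - (1-q_a)(1-q_b).

    Survival probabilities multiply over adjacent age intervals, so the
    probability of dying over the union band is one minus the product of the
    band survivals.
    """
    if q_a.band.end_age != q_b.band.start_age:
        raise ValueError(
            f"bands {q_a.band} and {q_b.band} are not adjacent; cannot compose"
        )
    value = 1.0 - (1.0 - q_a.value) * (1.0 - q_b.value)
    return QProbability(AgeBand(q_a.band.start_age, q_a.band.width + q_b.band.width), value)


def split_q(q_total: QProbability, q_first: QProbability) -> QProbability:
    """Recover the second-segment probability from a total and its first part.

    Inverse of :func:`compose_q`: given :math:`{}_mq_x` and :math:`{}_nq_x`
    with n < m and the bands left-aligned, returns
    :math:`{}_{m-n}q_{x+n} = 1 - (1 - {}_mq_x) / (1 - {}_nq_x)`.
    """
    if q_first.band.start_age != q_total.band.start_age:
        raise ValueError("bands must be left-aligned")
    if q_first.band.width >= q_total.band.width:
        raise ValueError("first band must be strictly nested in the total band")
    if q_first.value > q_total.value + 1e-12:  # tolerate rounding at equality
        raise ValueError("q_first exceeds q_total; no valid split exists")
    value = max(1.0 - (1.0 - q_total.value) / (1.0 - q_first.value), 0.0)
    band = AgeBand(q_first.band.end_age, q_total.band.width - q_first.band.width)
    return QProbability(band, value)


def q_to_m(q: float, n: float, a_sep: float | None = None) -> float:
    """Convert a death probability over an n-year band to a central rate.

    Uses the standard abridged life-table relation
    ``m = q / (n - q * (n - a))`` where *a* is the average number of years
    lived within the band by those dying in it.  The default ``a = n/2``
    assumes deaths uniformly distributed over the band, a good approximation
    in the near-linear youth segment of the survival curve.
    """
    if a_sep is None:
        a_sep = n / 2.0
    if not 0.0 < a_sep < n:
        raise ValueError(f"a_sep must lie in (0, {n}), got {a_sep}")
    if not 0.0 <= q < 1.0:
        raise ValueError("q must lie in [0, 1)")
    return q / (n - q * (n - a_sep))


def m_to_q(m: float, n: float, a_sep: float | None = None) -> float:
    """Convert a central death rate back to a band death probability.

    Exact inverse of :func:`q_to_m`: ``q = n*m / (1 + (n - a)*m)``.
    """
    if a_sep is None:
        a_sep = n / 2.0
    if not 0.0 < a_sep < n:
        raise ValueError(f"a_sep must lie in (0, {n}), got {a_sep}")
    if m < 0:
        raise ValueError("central rate must be non-negative")
    return n * m / (1.0 + (n - a_sep) * m)


def annual_rate_of_reduction(
    q1: QProbability | float, q2: QProbability | float, t1: float, t2: float
) -> float:
    """Annual rate of reduction in percent per year: 100 ln(q1/q2)/(t2-t1).

    Positive when mortality declines from t1 to t2.  Antisymmetric under
    swapping the two endpoints.
    """
    v1, v2 = _as_value(q1), _as_value(q2)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("ARR requires strictly positive probabilities")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return 100.0 * math.log(v1 / v2) / (t2 - t1)


def report_round(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the stated number of decimals.

    Python's builtin ``round`` uses banker's rounding; printed demographic
    tables conventionally round halves away from zero (0.55 -> 0.6,
    -0.55 -> -0.6), so the quantisation is done in decimal arithmetic.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
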