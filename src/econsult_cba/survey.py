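"""Descriptive survey summaries with binomial uncertainty.

Two instruments feed the pipeline: a short post-consultation survey (one per
consult, answered by the requesting primary-care provider or the responding
specialist) and a provider-experience survey (one per provider). Analysis is
deliberately descriptive — proportions, top-two-box Likert rates and their
binomial standard errors — with no weighting or hypothesis testing.

Tri-state answers are the lowercase tokens "yes" / "no" / "not_applicable";
"not_applicable" and missing values are excluded from denominators and
reported separately, because each printed percentage in the source tables has
its own denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, ValidationError
from .money import round_half_up
from .utilization import Role

NECESSITY_LEVELS = (
    "unnecessary",
    "somewhat_unnecessary",
    "somewhat_necessary",
    "necessary",
)
UNNECESSARY_GROUP = frozenset(NECESSITY_LEVELS[:2])
NECESSARY_GROUP = frozenset(NECESSITY_LEVELS[2:])

USAGE_BANDS = ("1-5", "6-10", "10-20", ">20")

IMPACT_ITEMS = (
    "access",
    "referral_quality",
    "time_to_diagnosis",
    "capacity_comfort",
    "patient_care",
    "interprofessional",
)


@dataclass(frozen=True)
class PostConsultResponse:
    """One per-consult survey answer.

    Referral-avoidance items are asked of primary-care responders only;
    the referral-necessity item of specialist responders only.
    """

    consult_id: str
    responder_role: Role
    satisfaction: int  # ordinal 1-5
    avoided_referral: str | None = None  # yes / no / not_applicable
    intended_to_avoid: str | None = None
    improved_referral_quality: str | None = None
    improved_interim_care: str | None = None
    necessity: str | None = None  # one of NECESSITY_LEVELS, or None if declined

    def __post_init__(self) -> None:
        _check_likert(self.satisfaction, self.consult_id)
        if self.necessity is not None and self.necessity not in NECESSITY_LEVELS:
            raise ValidationError(
                f"consult {self.consult_id}: bad necessity {self.necessity!r}"
            )


@dataclass(frozen=True)
class ExperienceResponse:
    """One provider-experience survey answer (all items Likert 1-5)."""

    responder_role: Role
    usage_band: str
    overall_satisfaction: int
    intend_to_continue: int
    would_recommend: int
    impact_items: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.usage_band not in USAGE_BANDS:
            raise ValidationError(f"unknown usage band {self.usage_band!r}")
        for v in (self.overall_satisfaction, self.intend_to_continue, self.would_recommend):
            _check_likert(v, self.usage_band)
        for item, v in self.impact_items.items():
            _check_likert(v, item)


@dataclass(frozen=True)
class ProportionEstimate:
    """A count-based proportion with its binomial standard error."""

    numerator: int
    denominator: int
    proportion: float
    se: float

    def percent(self, ndigits: int = 0) -> float:
        return round_half_up(100 * self.proportion, ndigits)


@dataclass(frozen=True)
class NecessityBreakdown:
    """Grouped shares of the 4-level referral-necessity item.

    Shares are over all submitted responses including declines, so the three
    shares sum to 1 before rounding; ``n_declined`` is reported separately.
    """

    unnecessary_share: float  # unnecessary or somewhat_unnecessary
    necessary_share: float  # somewhat_necessary or necessary
    residual_share: float  # declined / absent
    n: int
    n_declined: int


def _check_likert(value: int, context: str) -> None:
    if value not in (1, 2, 3, 4, 5):
        raise ValidationError(f"{context}: Likert value {value!r} outside 1..5")


def proportion_estimate(flags: Sequence[bool]) -> ProportionEstimate:
    """Proportion of True with SE sqrt(p(1-p)/n); empty input is an error."""
    n = len(flags)
    if n == 0:
        raise DomainError("proportion_estimate requires at least one response")
    k = sum(bool(f) for f in flags)
    p = k / n
    return ProportionEstimate(k, n, p, math.sqrt(p * (1 - p) / n))


def top_two_box(values: Sequence[int]) -> ProportionEstimate:
    """Share of Likert responses in the two most favourable categories (>= 4)."""
    if not values:
        raise DomainError("top_two_box requires at least one response")
    for v in values:
        _check_likert(v, "top_two_box input")
    return proportion_estimate([v >= 4 for v in values])


def necessity_breakdown(responses: Iterable[str | None]) -> NecessityBreakdown:
    """Grouped necessity shares over all submitted responses (declines counted)."""
    values = list(responses)
    if not values:
        raise DomainError("necessity_breakdown requires at least one response")
    n_unnec = n_nec = n_declined = 0
    for v in values:
        if v is None:
            n_declined += 1
        elif v in UNNECESSARY_GROUP:
            n_unnec += 1
        elif v in NECESSARY_GROUP:
            n_nec += 1
        else:
            raise ValidationError(f"bad necessity value {v!r}")
    n = len(values)
    return NecessityBreakdown(n_unnec / n, n_nec / n, n_declined / n, n, n_declined)


def usage_band_distribution(
    responses: Iterable[ExperienceResponse],
) -> list[tuple[str, int, float]]:
    """(band, count, share) in fixed band order; shares over all respondents."""
    counts = {band: 0 for band in USAGE_BANDS}
    total = 0
    for r in responses:
        counts[r.usage_band] += 1
        total += 1
    return [(b, c, c / total if total else 0.0) for b, c in counts.items()]


def non_avoided_followup(
    responses: Iterable[PostConsultResponse],
) -> dict[str, ProportionEstimate]:
    """Follow-up shares among consults that did NOT avoid a referral.

    Returns estimates for: never intended to avoid a referral, improved the
    quality of the resulting referral, improved interim patient care. Each
    denominator excludes not-applicable/missing answers to that item.
    """
    subset = [r for r in responses if r.avoided_referral == "no"]
    if not subset:
        raise DomainError("no responses with avoided_referral == 'no'")

    def est(getter, positive: str) -> ProportionEstimate:
        flags = [
            getter(r) == positive
            for r in subset
            if getter(r) in ("yes", "no")
        ]
        if not flags:
            raise DomainError("all answers missing/not applicable for an item")
        return proportion_estimate(flags)

    return {
        "not_intended_to_avoid": est(lambda r: r.intended_to_avoid, "no"),
        "improved_referral_quality": est(lambda r: r.improved_referral_quality, "yes"),
        "improved_interim_care": est(lambda r: r.improved_interim_care, "yes"),
    }
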