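"""Fee-schedule cost arithmetic for phone e-consultations.

Under a fee-for-service system, every billable service carries a number of
Medical Service Units (MSUs) and payment is MSU count times a provincial
rate per MSU. A completed phone consult bills two codes — the requesting
family physician's call and the answering specialist's call — and this
"encounter cost" is paid whether or not the patient is later referred. The
saving from an averted in-person referral is therefore the specialist's
comprehensive consultation fee minus the encounter cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .errors import ConfigurationError, DomainError, SpecialtyLookupError
from .money import Cents, format_cents

log = logging.getLogger(__name__)

#: Default billing codes for one completed phone consultation.
CONS_CODE = "CONS 03.09 L"  # family physician requesting advice, 11.5 MSU
VIST_CODE = "VIST 03.09 K"  # specialist providing advice, 25 MSU
DEFAULT_RATE_PER_MSU = 2.68  # 2022 CAD per MSU


@dataclass(frozen=True)
class FeeCode:
    """One billing code: identifier, free-text description, MSU weight."""

    code_id: str
    description: str
    msu_units: float

    def __post_init__(self) -> None:
        if not self.code_id:
            raise DomainError("code_id must be non-empty")
        if self.msu_units < 0:
            raise DomainError(f"msu_units must be >= 0, got {self.msu_units}")


@dataclass(frozen=True)
class FeeSchedule:
    """Rate per MSU, billing codes, and per-specialty comprehensive consult fees.

    ``comprehensive_fee`` maps specialty name to the fee (integer cents) billed
    for an in-person comprehensive specialist consultation; it is a required
    input because provincial manuals are not bundled.
    """

    rate_per_msu: float
    codes: tuple[FeeCode, ...]
    comprehensive_fee: dict[str, Cents] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate_per_msu < 0:
            raise DomainError(f"rate_per_msu must be >= 0, got {self.rate_per_msu}")
        ids = [c.code_id for c in self.codes]
        if len(ids) != len(set(ids)):
            raise DomainError("duplicate code_id in schedule")
        for spec, fee in self.comprehensive_fee.items():
            if fee < 0:
                raise DomainError(f"comprehensive fee for {spec!r} is negative")

    def code(self, code_id: str) -> FeeCode:
        for c in self.codes:
            if c.code_id == code_id:
                return c
        raise ConfigurationError(f"fee schedule is missing code {code_id!r}")


@dataclass(frozen=True)
class AvoidedCostBreakdown:
    """Net saving per averted referral for one specialty.

    ``component_one`` is the phone-encounter cost (paid either way);
    ``component_two`` the comprehensive in-person consult fee;
    ``net_avoided`` their exact difference. All integer cents.
    """

    specialty: str
    component_one: Cents
    component_two: Cents
    net_avoided: Cents
    warning: str | None = None


def default_codes() -> tuple[FeeCode, FeeCode]:
    return (
        FeeCode(CONS_CODE, "Family physician-to-specialist phone call", 11.5),
        FeeCode(VIST_CODE, "Specialist-to-physician/NP phone call", 25.0),
    )


def msu_cost(msu_units: float, rate_per_msu: float) -> Cents:
    """MSU count times rate per MSU, rounded half-up to cents.

    11.5 MSU at $2.68/MSU bills $30.82, returned as 3082 cents.
    """
    if msu_units < 0 or rate_per_msu < 0:
        raise DomainError("msu_units and rate_per_msu must be non-negative")
    amount = Decimal(repr(msu_units)) * Decimal(repr(rate_per_msu)) * 100
    return int(amount.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def vh_encounter_cost(schedule: FeeSchedule) -> Cents:
    """Total phone-consult billing: both codes of one completed encounter."""
    total = 0
    for code_id in (CONS_CODE, VIST_CODE):
        code = schedule.code(code_id)  # raises ConfigurationError if absent
        total += msu_cost(code.msu_units, schedule.rate_per_msu)
    return total


def net_avoided_cost(specialty: str, schedule: FeeSchedule) -> AvoidedCostBreakdown:
    """Saving per averted in-person referral: comprehensive fee minus encounter cost.

    A negative net saving (a specialty whose in-person fee is below the phone
    encounter cost) is returned but flagged with a warning, since the paying
    system then loses money on each "avoided" referral.
    """
    if specialty not in schedule.comprehensive_fee:
        raise SpecialtyLookupError(specialty)
    component_one = vh_encounter_cost(schedule)
    component_two = schedule.comprehensive_fee[specialty]
    net = component_two - component_one
    warning = None
    if net < 0:
        warning = (
            f"net avoided cost for {specialty!r} is negative "
            f"({format_cents(net)}): comprehensive fee below encounter cost"
        )
        log.warning(warning)
    return AvoidedCostBreakdown(specialty, component_one, component_two, net, warning)
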