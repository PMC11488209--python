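"""Deterministic cost-benefit engine.

Costs are a one-off onboarding fee per specialist group (month 0) plus an
ongoing monthly platform license; an annual opportunity cost of capital is
applied to the ongoing fees by monthly compounding, onboarding undiscounted.
Benefits are the monetary value of in-person referrals averted: for each
specialty, consult volume times the avoidance proportion times the net saving
per averted referral. Point metrics are net benefit B − C, benefit-cost
ratio B/C, and return on investment (B − C)/C; the analysis is from the
healthcare-payer perspective, so patient time and travel are not valued.

Averted-referral counts stay unrounded in all monetary arithmetic; rounding
happens once, at display.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .money import Cents, round_half_up


@dataclass(frozen=True)
class CostConfig:
    """Implementation-cost ledger parameters (money in integer cents)."""

    onboarding_fee_mean: Cents = 126_500  # per specialist group
    onboarding_fee_sd: Cents = 23_000
    n_groups: int = 16
    monthly_license: Cents = 1_000_000
    horizon_months: int = 13
    annual_discount_rate: float = 0.07  # opportunity cost of capital
    discounting_enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.onboarding_fee_mean, self.onboarding_fee_sd, self.monthly_license) < 0:
            raise DomainError("monies must be non-negative")
        if self.n_groups < 0 or self.horizon_months < 0:
            raise DomainError("counts must be non-negative")
        if not 0 <= self.annual_discount_rate < 1:
            raise DomainError("annual_discount_rate must be in [0, 1)")


@dataclass(frozen=True)
class LedgerRow:
    month: int  # 0 = onboarding, 1..horizon = license months
    item: str
    nominal: Cents
    discounted: Cents  # display-rounded; totals are computed unrounded


@dataclass(frozen=True)
class CostLedger:
    rows: tuple[LedgerRow, ...]
    total: Cents  # discounted total, rounded once
    nominal_total: Cents


@dataclass(frozen=True)
class BenefitInputs:
    """Everything the benefit side needs, aligned by specialty."""

    consults_by_specialty: dict[str, int]
    avoidance_proportion: float
    net_avoided_by_specialty: dict[str, Cents]

    def __post_init__(self) -> None:
        if not 0 <= self.avoidance_proportion <= 1:
            raise DomainError("avoidance_proportion must be in [0, 1]")
        missing = set(self.consults_by_specialty) - set(self.net_avoided_by_specialty)
        if missing:
            raise ConfigurationError(
                f"specialties missing a net-avoided fee: {sorted(missing)}"
            )


@dataclass(frozen=True)
class ReferralsAvoided:
    per_specialty: dict[str, float]
    total: float  # unrounded
    total_rounded: int  # round-half-up display integer


@dataclass(frozen=True)
class CbaPointResult:
    total_cost: Cents
    total_benefit: Cents
    net_benefit: Cents
    bcr: float | None  # None when total_cost == 0 (undefined)
    roi: float | None
    referrals_avoided_total: float | None = None
    referrals_avoided_rounded: int | None = None


def implementation_cost(
    config: CostConfig, onboarding_total: Cents | None = None
) -> CostLedger:
    """Accrue onboarding plus discounted monthly license fees.

    Month-m license fees are discounted by d^m with d = (1+r)^(-1/12);
    onboarding sits at month 0 and is never discounted. ``onboarding_total``
    lets a caller substitute realized (sampled) group fees for the mean.
    """
    if onboarding_total is None:
        onboarding_total = config.n_groups * config.onboarding_fee_mean
    d = (
        (1.0 + config.annual_discount_rate) ** (-1.0 / 12.0)
        if config.discounting_enabled
        else 1.0
    )
    rows = [LedgerRow(0, "onboarding", onboarding_total, onboarding_total)]
    discounted_total = float(onboarding_total)
    nominal_total = onboarding_total
    for m in range(1, config.horizon_months + 1):
        disc = config.monthly_license * d**m
        rows.append(
            LedgerRow(m, "license", config.monthly_license, int(round_half_up(disc)))
        )
        discounted_total += disc
        nominal_total += config.monthly_license
    return CostLedger(tuple(rows), int(round_half_up(discounted_total)), nominal_total)


def referrals_avoided(inputs: BenefitInputs) -> ReferralsAvoided:
    """Per-specialty averted referrals: consults times the avoidance proportion."""
    per = {
        s: n * inputs.avoidance_proportion
        for s, n in inputs.consults_by_specialty.items()
    }
    total = sum(per.values())
    return ReferralsAvoided(per, total, int(round_half_up(total)))


def total_benefit(inputs: BenefitInputs) -> Cents:
    """Value of averted referrals, summed unrounded and rounded once to cents."""
    avoided = referrals_avoided(inputs).per_specialty
    raw = sum(
        avoided[s] * inputs.net_avoided_by_specialty[s]
        for s in inputs.consults_by_specialty
    )
    return int(round_half_up(raw))


def cba_point(
    total_benefit: Cents,
    total_cost: Cents,
    referrals: ReferralsAvoided | None = None,
) -> CbaPointResult:
    """Point metrics; ratio metrics are undefined (None) at zero cost."""
    net = total_benefit - total_cost
    bcr = roi = None
    if total_cost != 0:
        bcr = total_benefit / total_cost
        roi = net / total_cost
    return CbaPointResult(
        total_cost=total_cost,
        total_benefit=total_benefit,
        net_benefit=net,
        bcr=bcr,
        roi=roi,
        referrals_avoided_total=referrals.total if referrals else None,
        referrals_avoided_rounded=referrals.total_rounded if referrals else None,
    )
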