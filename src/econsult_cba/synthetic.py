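"""Synthetic study data with the statistical structure the analysis assumes.

The administrative and survey data behind the evaluation are not deposited,
so every pipeline stage is exercised on generated stand-ins: a consult log
drawn multinomially over the observed specialty mix, a provider registry
with the observed role split, per-consult and provider-experience surveys
drawn Bernoulli/categorically at the reported response rates, a fee schedule
with the two phone-consult codes plus gamma-distributed comprehensive fees,
and an onboarding/licensing cost ledger. Defaults reproduce the study
conditions; every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .cba import CostConfig
from .errors import DomainError, ValidationError
from .fee_model import FeeSchedule, default_codes, vh_encounter_cost
from .money import Cents, round_half_up, to_cents
from .psa import _substream
from .survey import (
    IMPACT_ITEMS,
    NECESSITY_LEVELS,
    USAGE_BANDS,
    ExperienceResponse,
    PostConsultResponse,
)
from .utilization import ConsultRecord, ProviderRecord, Role

# Observed specialty mix: top-ten counts as printed, remainder pooled.
DEFAULT_SPECIALTY_COUNTS: dict[str, int] = {
    "internal_medicine": 1318,
    "psychiatry": 1020,
    "obgyn": 431,
    "endocrinology": 383,
    "hematology": 322,
    "hepatology": 279,
    "rheumatology": 243,
    "pediatrics": 237,
    "infectious_diseases": 176,
    "general_surgery": 103,
    "other": 1560,
}
DEFAULT_N_CONSULTS = sum(DEFAULT_SPECIALTY_COUNTS.values())  # 6,072

UTILIZATION_WINDOW = (dt.date(2022, 5, 1), dt.date(2024, 1, 31))


@dataclass(frozen=True)
class SurveyParams:
    n_pcp_responses: int = 608
    n_specialist_responses: int = 653
    avoidance: float = 0.84
    pcp_satisfaction: float = 0.99  # top-two-box rates
    specialist_satisfaction: float = 0.96
    # among non-avoided: not-intended, improved-quality, improved-interim-care
    non_avoided_rates: tuple[float, float, float] = (0.89, 0.89, 0.90)
    # necessity split: (unnecessary-ish, necessary-ish, declined)
    necessity_split: tuple[float, float, float] = (0.55, 0.40, 0.05)
    n_experience: int = 89
    usage_band_weights: tuple[float, ...] = (34, 20, 18, 17)
    experience_pcp_share: float = 0.75
    experience_satisfaction: tuple[float, float] = (0.96, 0.92)  # (pcp, specialist)
    intend_to_continue: float = 0.97
    would_recommend: float = 0.97
    impact_rates: dict[str, float] = field(
        default_factory=lambda: {
            "access": 0.95,
            "referral_quality": 0.78,
            "time_to_diagnosis": 0.93,
            "capacity_comfort": 0.98,
            "patient_care": 0.99,
            "interprofessional": 0.98,
        }
    )


@dataclass(frozen=True)
class FeeParams:
    rate_per_msu: float = 2.68
    comprehensive_fee_mean: float = 174.17  # calibrated so net saving ~ $76.35
    comprehensive_fee_sd: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_consults: int = DEFAULT_N_CONSULTS
    specialty_shares: dict[str, float] = field(
        default_factory=lambda: {
            s: n / DEFAULT_N_CONSULTS for s, n in DEFAULT_SPECIALTY_COUNTS.items()
        }
    )
    n_primary_care: int = 873
    n_specialists: int = 143
    window: tuple[dt.date, dt.date] = UTILIZATION_WINDOW
    survey: SurveyParams = field(default_factory=SurveyParams)
    fees: FeeParams = field(default_factory=FeeParams)
    costs: CostConfig = field(default_factory=CostConfig)

    def __post_init__(self) -> None:
        total = sum(self.specialty_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"specialty shares sum to {total}, expected 1")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _likert_top_two(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    """Likert 1-5 draws with P(value >= 4) == rate; 4/5 and 1/2/3 equiprobable."""
    top = rng.random(n) < rate
    high = rng.integers(4, 6, n)
    low = rng.integers(1, 4, n)
    return np.where(top, high, low)


def gen_consult_log(config: GeneratorConfig) -> list[ConsultRecord]:
    """Completed consults with multinomial specialties and uniform dates."""
    if config.n_consults < 0:
        raise DomainError("n_consults must be >= 0")
    rng = _substream(config.seed, "consult_log")
    specialties = sorted(config.specialty_shares)
    probs = np.array([config.specialty_shares[s] for s in specialties])
    draws = rng.choice(len(specialties), size=config.n_consults, p=probs)
    start, end = config.window
    offsets = rng.integers(0, (end - start).days + 1, config.n_consults)
    return [
        ConsultRecord(
            consult_id=f"C{i:05d}",
            specialty=specialties[k],
            date=start + dt.timedelta(days=int(off)),
            completed=True,
            requesting_role=Role.PRIMARY_CARE,
        )
        for i, (k, off) in enumerate(zip(draws, offsets))
    ]


def gen_provider_registry(config: GeneratorConfig) -> list[ProviderRecord]:
    rng = _substream(config.seed, "providers")
    start, end = config.window
    n_days = (end - start).days + 1
    records = []
    for i in range(config.n_primary_care + config.n_specialists):
        role = Role.PRIMARY_CARE if i < config.n_primary_care else Role.SPECIALIST
        records.append(
            ProviderRecord(
                provider_id=f"P{i:04d}",
                role=role,
                join_date=start + dt.timedelta(days=int(rng.integers(0, n_days))),
            )
        )
    return records


def gen_post_consult_surveys(
    log: list[ConsultRecord], config: GeneratorConfig
) -> tuple[list[PostConsultResponse], list[PostConsultResponse]]:
    """(primary-care responses, specialist responses), linked to consults.

    Respondent consults are sampled without replacement from the log, keeping
    the per-consult linkage of the real pop-up survey. Primary-care responses
    carry the avoidance items; specialist responses the necessity item.
    """
    sp = config.survey
    for n in (sp.n_pcp_responses, sp.n_specialist_responses):
        if n > len(log):
            raise ValidationError("survey response count exceeds consult log size")
    rng = _substream(config.seed, "post_consult")

    pcp_idx = rng.choice(len(log), sp.n_pcp_responses, replace=False)
    satisfaction = _likert_top_two(rng, sp.pcp_satisfaction, sp.n_pcp_responses)
    avoided = rng.random(sp.n_pcp_responses) < sp.avoidance
    r_int, r_qual, r_care = sp.non_avoided_rates
    pcp: list[PostConsultResponse] = []
    for j, (i, sat, av) in enumerate(zip(pcp_idx, satisfaction, avoided)):
        if av:
            extra = dict(avoided_referral="yes")
        else:
            extra = dict(
                avoided_referral="no",
                intended_to_avoid="no" if rng.random() < r_int else "yes",
                improved_referral_quality="yes" if rng.random() < r_qual else "no",
                improved_interim_care="yes" if rng.random() < r_care else "no",
            )
        pcp.append(
            PostConsultResponse(
                consult_id=log[i].consult_id,
                responder_role=Role.PRIMARY_CARE,
                satisfaction=int(sat),
                **extra,
            )
        )

    spec_idx = rng.choice(len(log), sp.n_specialist_responses, replace=False)
    s_sat = _likert_top_two(rng, sp.specialist_satisfaction, sp.n_specialist_responses)
    cat = rng.choice(3, sp.n_specialist_responses, p=np.array(sp.necessity_split))
    specialist: list[PostConsultResponse] = []
    for i, sat, c in zip(spec_idx, s_sat, cat):
        if c == 0:
            necessity = NECESSITY_LEVELS[int(rng.integers(0, 2))]
        elif c == 1:
            necessity = NECESSITY_LEVELS[int(rng.integers(2, 4))]
        else:
            necessity = None  # declined the necessity item
        specialist.append(
            PostConsultResponse(
                consult_id=log[i].consult_id,
                responder_role=Role.SPECIALIST,
                satisfaction=int(sat),
                necessity=necessity,
            )
        )
    return pcp, specialist


def gen_experience_surveys(config: GeneratorConfig) -> list[ExperienceResponse]:
    sp = config.survey
    rng = _substream(config.seed, "experience")
    weights = np.asarray(sp.usage_band_weights, dtype=float)
    bands = rng.choice(len(USAGE_BANDS), sp.n_experience, p=weights / weights.sum())
    is_pcp = rng.random(sp.n_experience) < sp.experience_pcp_share
    out = []
    for band, pcp in zip(bands, is_pcp):
        sat_rate = sp.experience_satisfaction[0 if pcp else 1]
        out.append(
            ExperienceResponse(
                responder_role=Role.PRIMARY_CARE if pcp else Role.SPECIALIST,
                usage_band=USAGE_BANDS[int(band)],
                overall_satisfaction=int(_likert_top_two(rng, sat_rate, 1)[0]),
                intend_to_continue=int(_likert_top_two(rng, sp.intend_to_continue, 1)[0]),
                would_recommend=int(_likert_top_two(rng, sp.would_recommend, 1)[0]),
                impact_items={
                    item: int(_likert_top_two(rng, sp.impact_rates[item], 1)[0])
                    for item in IMPACT_ITEMS
                },
            )
        )
    return out


def gen_fee_schedule(config: GeneratorConfig) -> FeeSchedule:
    """Schedule with the two phone-consult codes plus per-specialty fees.

    Comprehensive fees are gamma-distributed around the configured mean and,
    by default, truncated below at the phone-encounter cost so net savings
    stay non-negative.
    """
    fp = config.fees
    if fp.comprehensive_fee_mean <= 0:
        raise DomainError("comprehensive_fee_mean must be > 0")
    rng = _substream(config.seed, "fees")
    base = FeeSchedule(fp.rate_per_msu, default_codes())
    floor = vh_encounter_cost(base)
    fees: dict[str, Cents] = {}
    for s in sorted(config.specialty_shares):
        if fp.comprehensive_fee_sd == 0:
            fee = to_cents(fp.comprehensive_fee_mean)
        else:
            shape = (fp.comprehensive_fee_mean / fp.comprehensive_fee_sd) ** 2
            scale = fp.comprehensive_fee_sd**2 / fp.comprehensive_fee_mean
            fee = to_cents(float(rng.gamma(shape, scale)))
            fee = max(fee, floor)
        fees[s] = fee
    return FeeSchedule(fp.rate_per_msu, default_codes(), fees)


def gen_cost_ledger(config: GeneratorConfig) -> tuple[CostConfig, list[Cents]]:
    """Cost config plus realized per-group onboarding fees (gamma-distributed)."""
    cc = config.costs
    rng = _substream(config.seed, "costs")
    if cc.n_groups == 0:
        return cc, []
    if cc.onboarding_fee_sd == 0:
        fees = [cc.onboarding_fee_mean] * cc.n_groups
    else:
        shape = (cc.onboarding_fee_mean / cc.onboarding_fee_sd) ** 2
        scale = cc.onboarding_fee_sd**2 / cc.onboarding_fee_mean
        # draws are already in cents; round half-up to whole cents
        fees = [int(round_half_up(float(x))) for x in rng.gamma(shape, scale, cc.n_groups)]
    return cc, fees
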