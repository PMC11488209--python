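"""CSV/JSON readers and writers for every pipeline input and output.

All files are plain text: consult logs, provider registries and survey
responses as CSV with ISO-8601 dates and lowercase enum tokens; the fee
schedule as a CSV of codes plus a JSON sidecar holding the rate per MSU and
the specialty fee mapping; the cost config as JSON. Money is stored as fixed
2-decimal text and parsed back to integer cents, so values round-trip
without loss.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import pandas as pd

from .cba import CostConfig
from .fee_model import FeeCode, FeeSchedule
from .money import Cents, format_cents, to_cents
from .survey import IMPACT_ITEMS, ExperienceResponse, PostConsultResponse
from .utilization import ConsultRecord, ProviderRecord, Role

# ---------------------------------------------------------------- consults


def write_consult_log(records: list[ConsultRecord], path: Path | str) -> None:
    pd.DataFrame(
        {
            "consult_id": [r.consult_id for r in records],
            "specialty": [r.specialty for r in records],
            "date": [r.date.isoformat() for r in records],
            "completed": [str(r.completed).lower() for r in records],
            "requesting_role": [r.requesting_role.value for r in records],
        }
    ).to_csv(path, index=False)


def read_consult_log(path: Path | str) -> list[ConsultRecord]:
    df = pd.read_csv(path, dtype=str)
    return [
        ConsultRecord(
            consult_id=row.consult_id,
            specialty=row.specialty,
            date=dt.date.fromisoformat(row.date),
            completed=row.completed == "true",
            requesting_role=Role(row.requesting_role),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------- providers


def write_provider_registry(records: list[ProviderRecord], path: Path | str) -> None:
    pd.DataFrame(
        {
            "provider_id": [r.provider_id for r in records],
            "role": [r.role.value for r in records],
            "join_date": [r.join_date.isoformat() for r in records],
        }
    ).to_csv(path, index=False)


def read_provider_registry(path: Path | str) -> list[ProviderRecord]:
    df = pd.read_csv(path, dtype=str)
    return [
        ProviderRecord(row.provider_id, Role(row.role), dt.date.fromisoformat(row.join_date))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------- surveys

_TRI = ("avoided_referral", "intended_to_avoid", "improved_referral_quality", "improved_interim_care")


def write_post_consult_surveys(
    responses: list[PostConsultResponse], path: Path | str
) -> None:
    rows = []
    for r in responses:
        row = {
            "consult_id": r.consult_id,
            "responder_role": r.responder_role.value,
            "satisfaction": r.satisfaction,
            "necessity": r.necessity or "",
        }
        for f in _TRI:
            row[f] = getattr(r, f) or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_post_consult_surveys(path: Path | str) -> list[PostConsultResponse]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples():
        out.append(
            PostConsultResponse(
                consult_id=row.consult_id,
                responder_role=Role(row.responder_role),
                satisfaction=int(row.satisfaction),
                avoided_referral=row.avoided_referral or None,
                intended_to_avoid=row.intended_to_avoid or None,
                improved_referral_quality=row.improved_referral_quality or None,
                improved_interim_care=row.improved_interim_care or None,
                necessity=row.necessity or None,
            )
        )
    return out


def write_experience_surveys(
    responses: list[ExperienceResponse], path: Path | str
) -> None:
    rows = []
    for r in responses:
        row = {
            "responder_role": r.responder_role.value,
            "usage_band": r.usage_band,
            "overall_satisfaction": r.overall_satisfaction,
            "intend_to_continue": r.intend_to_continue,
            "would_recommend": r.would_recommend,
        }
        for item in IMPACT_ITEMS:
            row[f"impact_{item}"] = r.impact_items.get(item, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_experience_surveys(path: Path | str) -> list[ExperienceResponse]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        ExperienceResponse(
            responder_role=Role(row.responder_role),
            usage_band=row.usage_band,
            overall_satisfaction=int(row.overall_satisfaction),
            intend_to_continue=int(row.intend_to_continue),
            would_recommend=int(row.would_recommend),
            impact_items={
                item: int(getattr(row, f"impact_{item}")) for item in IMPACT_ITEMS
            },
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------- fee schedule


def write_fee_schedule(schedule: FeeSchedule, codes_csv: Path | str, sidecar_json: Path | str) -> None:
    pd.DataFrame(
        {
            "code_id": [c.code_id for c in schedule.codes],
            "description": [c.description for c in schedule.codes],
            "msu_units": [c.msu_units for c in schedule.codes],
        }
    ).to_csv(codes_csv, index=False)
    sidecar = {
        "rate_per_msu": schedule.rate_per_msu,
        "comprehensive_fee": {
            s: format_cents(fee) for s, fee in schedule.comprehensive_fee.items()
        },
        "currency": "2022 CAD",
    }
    Path(sidecar_json).write_text(json.dumps(sidecar, indent=2))


def read_fee_schedule(codes_csv: Path | str, sidecar_json: Path | str) -> FeeSchedule:
    df = pd.read_csv(codes_csv)
    codes = tuple(
        FeeCode(row.code_id, row.description, float(row.msu_units))
        for row in df.itertuples()
    )
    sidecar = json.loads(Path(sidecar_json).read_text())
    fees: dict[str, Cents] = {
        s: to_cents(v) for s, v in sidecar["comprehensive_fee"].items()
    }
    return FeeSchedule(float(sidecar["rate_per_msu"]), codes, fees)


# ---------------------------------------------------------------- cost config


def write_cost_config(
    config: CostConfig, path: Path | str, onboarding_fees: list[Cents] | None = None
) -> None:
    doc = {
        "onboarding_fee_mean": format_cents(config.onboarding_fee_mean),
        "onboarding_fee_sd": format_cents(config.onboarding_fee_sd),
        "n_groups": config.n_groups,
        "monthly_license": format_cents(config.monthly_license),
        "horizon_months": config.horizon_months,
        "annual_discount_rate": config.annual_discount_rate,
        "discounting_enabled": config.discounting_enabled,
    }
    if onboarding_fees is not None:
        doc["onboarding_fees"] = [format_cents(f) for f in onboarding_fees]
    Path(path).write_text(json.dumps(doc, indent=2))


def read_cost_config(path: Path | str) -> tuple[CostConfig, list[Cents] | None]:
    doc = json.loads(Path(path).read_text())
    config = CostConfig(
        onboarding_fee_mean=to_cents(doc["onboarding_fee_mean"]),
        onboarding_fee_sd=to_cents(doc["onboarding_fee_sd"]),
        n_groups=int(doc["n_groups"]),
        monthly_license=to_cents(doc["monthly_license"]),
        horizon_months=int(doc["horizon_months"]),
        annual_discount_rate=float(doc["annual_discount_rate"]),
        discounting_enabled=bool(doc["discounting_enabled"]),
    )
    fees = doc.get("onboarding_fees")
    return config, [to_cents(f) for f in fees] if fees is not None else None
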