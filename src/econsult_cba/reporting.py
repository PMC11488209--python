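"""Pipeline orchestration and table rendering.

`run_pipeline` chains the stages — synthetic-data generation (or reading an
existing dataset directory), utilization tallies, survey summaries, fee-model
savings, the deterministic CBA, the reference-case PSA and the doubled-cost
scenario — and writes the three study tables as CSV plus aligned text, a
metrics JSON, and a run log. Renderers only format numbers already present
in the metrics; they never recompute.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as eio
from .cba import BenefitInputs, cba_point, implementation_cost, referrals_avoided, total_benefit
from .errors import ConfigurationError
from .fee_model import net_avoided_cost
from .money import cents_to_dollars, round_half_up
from .psa import DistributionSpec, PsaSpec, PsaSummary, component_model, run_psa
from .survey import (
    necessity_breakdown,
    non_avoided_followup,
    proportion_estimate,
    top_two_box,
    usage_band_distribution,
)
from .synthetic import (
    GeneratorConfig,
    gen_consult_log,
    gen_cost_ledger,
    gen_experience_surveys,
    gen_fee_schedule,
    gen_post_consult_surveys,
    gen_provider_registry,
)
from .utilization import Role, filter_window, provider_mix, tally_by_specialty, top_specialties

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    outdir: Path
    seed: int = 0
    data_dir: Path | None = None  # read existing dataset; None -> generate
    n_draws: int = 1000
    cost_multiplier: float = 2.0  # one-way scenario
    utilization_window: tuple[dt.date, dt.date] | None = None
    economics_window: tuple[dt.date, dt.date] | None = None
    min_consults_top: int = 100
    log_level: str = "INFO"


def generate_dataset(config: GeneratorConfig, outdir: Path) -> None:
    """Write a complete synthetic dataset directory from one config + seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    consults = gen_consult_log(config)
    eio.write_consult_log(consults, outdir / "consults.csv")
    eio.write_provider_registry(gen_provider_registry(config), outdir / "providers.csv")
    pcp, spec = gen_post_consult_surveys(consults, config)
    eio.write_post_consult_surveys(pcp + spec, outdir / "post_consult_surveys.csv")
    eio.write_experience_surveys(gen_experience_surveys(config), outdir / "experience_surveys.csv")
    schedule = gen_fee_schedule(config)
    eio.write_fee_schedule(schedule, outdir / "fee_codes.csv", outdir / "fee_schedule.json")
    cost_config, onboarding = gen_cost_ledger(config)
    eio.write_cost_config(cost_config, outdir / "cost_config.json", onboarding)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the metrics."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    data_dir = Path(config.data_dir) if config.data_dir else outdir / "data"
    if config.data_dir is None:
        generate_dataset(GeneratorConfig(seed=config.seed), data_dir)
    for name in ("consults.csv", "fee_codes.csv", "fee_schedule.json", "cost_config.json"):
        if not (data_dir / name).exists():
            raise ConfigurationError(f"input stage: missing required file {name!r} in {data_dir}")

    # --- utilization stage
    consults = eio.read_consult_log(data_dir / "consults.csv")
    if config.utilization_window:
        consults_util = filter_window(consults, *config.utilization_window)
    else:
        consults_util = consults
    tallies = tally_by_specialty(consults_util)
    top, combined_share = top_specialties(tallies, config.min_consults_top)
    mix = provider_mix(eio.read_provider_registry(data_dir / "providers.csv"))

    # --- survey stage
    responses = eio.read_post_consult_surveys(data_dir / "post_consult_surveys.csv")
    pcp = [r for r in responses if r.responder_role == Role.PRIMARY_CARE]
    spec_resp = [r for r in responses if r.responder_role == Role.SPECIALIST]
    avoidance = proportion_estimate(
        [r.avoided_referral == "yes" for r in pcp if r.avoided_referral in ("yes", "no")]
    )
    pcp_sat = top_two_box([r.satisfaction for r in pcp])
    spec_sat = top_two_box([r.satisfaction for r in spec_resp])
    necessity = necessity_breakdown([r.necessity for r in spec_resp])
    followup = non_avoided_followup(pcp)
    experience = eio.read_experience_surveys(data_dir / "experience_surveys.csv")
    bands = usage_band_distribution(experience)

    # --- fee-model + CBA stage (economics window may differ from utilization)
    schedule = eio.read_fee_schedule(data_dir / "fee_codes.csv", data_dir / "fee_schedule.json")
    if config.economics_window:
        consults_econ = filter_window(consults, *config.economics_window)
    else:
        consults_econ = consults
    econ_tallies = tally_by_specialty(consults_econ)
    net_by_specialty = {}
    for t in econ_tallies:
        breakdown = net_avoided_cost(t.specialty, schedule)
        if breakdown.warning:
            log.warning("fee stage: %s", breakdown.warning)
        net_by_specialty[t.specialty] = breakdown.net_avoided
    benefit_inputs = BenefitInputs(
        consults_by_specialty={t.specialty: t.count for t in econ_tallies},
        avoidance_proportion=avoidance.proportion,
        net_avoided_by_specialty=net_by_specialty,
    )
    avoided = referrals_avoided(benefit_inputs)
    benefit = total_benefit(benefit_inputs)
    cost_config, onboarding = eio.read_cost_config(data_dir / "cost_config.json")
    ledger = implementation_cost(
        cost_config, sum(onboarding) if onboarding is not None else None
    )
    point = cba_point(benefit, ledger.total, avoided)

    # --- PSA stage: beta on the avoidance proportion (binomial SE), gamma on
    # total cost (10%-of-mean rule: no stated SD or CI exists for this ledger)
    psa_spec = PsaSpec(
        quantity_specs={
            "avoidance_proportion": DistributionSpec(
                "beta", avoidance.proportion, avoidance.se, source="stated_sd"
            ),
            "total_cost": DistributionSpec(
                "gamma",
                cents_to_dollars(ledger.total),
                0.10 * cents_to_dollars(ledger.total),
                source="ten_percent_rule",
            ),
        },
        n_draws=config.n_draws,
        seed=config.seed,
    )
    model = component_model(
        benefit_inputs.consults_by_specialty,
        {s: cents_to_dollars(c) for s, c in net_by_specialty.items()},
    )
    psa_ref = run_psa(model, psa_spec)
    psa_sens = run_psa(model, psa_spec, cost_multiplier=config.cost_multiplier)

    metrics = {
        "version": __version__,
        "seed": config.seed,
        "utilization": {
            "total_consults": sum(t.count for t in tallies),
            "tallies": [dataclasses.asdict(t) for t in tallies],
            "top": {
                "min_consults": config.min_consults_top,
                "n_specialties": len(top),
                "combined_share": combined_share,
            },
            "provider_mix": {"counts": mix.counts, "total": mix.total, "shares": mix.shares},
        },
        "survey": {
            "avoidance": dataclasses.asdict(avoidance),
            "pcp_satisfaction": dataclasses.asdict(pcp_sat),
            "specialist_satisfaction": dataclasses.asdict(spec_sat),
            "necessity": dataclasses.asdict(necessity),
            "non_avoided_followup": {k: dataclasses.asdict(v) for k, v in followup.items()},
            "usage_bands": [
                {"band": b, "count": c, "share": s} for b, c, s in bands
            ],
        },
        "cba": {
            "total_cost": cents_to_dollars(ledger.total),
            "total_benefit": cents_to_dollars(benefit),
            "net_benefit": cents_to_dollars(point.net_benefit),
            "bcr": point.bcr,
            "roi": point.roi,
            "referrals_avoided": avoided.total,
            "referrals_avoided_rounded": avoided.total_rounded,
        },
        "psa": {
            "reference": _summary_dict(psa_ref),
            "sensitivity": _summary_dict(psa_sens),
            "cost_multiplier": config.cost_multiplier,
        },
    }

    _write_bundle(metrics, tallies, mix, psa_ref, psa_sens, outdir)
    _write_run_log(config, outdir)
    return metrics


def _summary_dict(s: PsaSummary) -> dict:
    return {
        "n_draws": s.n_draws,
        "seed": s.seed,
        "means": s.means,
        "ci_low": s.ci_low,
        "ci_high": s.ci_high,
    }


def _write_bundle(metrics, tallies, mix, psa_ref, psa_sens, outdir: Path) -> None:
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    render_table1(mix).to_csv(outdir / "table1_provider_mix.csv", index=False)
    render_table2(tallies).to_csv(outdir / "table2_specialty_consults.csv", index=False)
    render_table3(psa_ref, psa_sens).to_csv(outdir / "table3_net_benefits.csv", index=False)
    for name, df in (
        ("table1_provider_mix", render_table1(mix)),
        ("table2_specialty_consults", render_table2(tallies)),
        ("table3_net_benefits", render_table3(psa_ref, psa_sens)),
    ):
        (outdir / f"{name}.txt").write_text(df.to_string(index=False) + "\n")
    psa_ref.draws.to_csv(outdir / "psa_draws_reference.csv", index=False)
    psa_sens.draws.to_csv(outdir / "psa_draws_sensitivity.csv", index=False)


def _write_run_log(config: RunConfig, outdir: Path) -> None:
    cfg_repr = repr(config).encode()
    (outdir / "run_log.txt").write_text(
        "\n".join(
            [
                f"timestamp: {dt.datetime.now().isoformat()}",
                f"version: {__version__}",
                f"seed: {config.seed}",
                f"config_sha256: {hashlib.sha256(cfg_repr).hexdigest()}",
            ]
        )
        + "\n"
    )


# ---------------------------------------------------------------- renderers


def render_table1(mix) -> pd.DataFrame:
    """Provider mix: counts and whole-percent shares."""
    rows = []
    labels = {"primary_care": "Primary care providers", "specialist": "Specialists"}
    for role, label in labels.items():
        share = mix.share_percent(role)
        rows.append(
            {
                "healthcare_professional": label,
                "count": mix.counts.get(role, 0),
                "share": f"{share}%" if share is not None else "",
            }
        )
    rows.append(
        {"healthcare_professional": "Total", "count": mix.total, "share": "100%" if mix.total else ""}
    )
    return pd.DataFrame(rows)


def render_table2(tallies) -> pd.DataFrame:
    """Consults by specialty: counts and 1-decimal percent shares."""
    return pd.DataFrame(
        [
            {
                "specialty": t.specialty,
                "share": f"{round_half_up(100 * t.share, 1):.1f}%",
                "consults": t.count,
            }
            for t in tallies
        ],
        columns=["specialty", "share", "consults"],
    )


def _money_cell(v: float) -> str:
    return f"${round_half_up(v):,.0f}"


def _fmt(mean: float, lo: float, hi: float, money: bool) -> str:
    if money:
        return f"{_money_cell(mean)} ({_money_cell(lo)} to {_money_cell(hi)})"
    return f"{round_half_up(mean, 1):.1f} ({round_half_up(lo, 1):.1f} to {round_half_up(hi, 1):.1f})"


def render_table3(reference: PsaSummary, sensitivity: PsaSummary) -> pd.DataFrame:
    """Net-benefit table: per-metric PSA mean (95% percentile CI), both cases."""
    spec = [
        ("Implementation and ongoing costs", "total_cost", True),
        ("In-person referral costs avoided", "total_benefit", True),
        ("Benefit-cost ratio", "bcr", False),
        ("Cumulative net benefits", "net_benefit", True),
        ("Return on investment (ROI)", "roi", False),
    ]
    rows = []
    for label, metric, money in spec:
        rows.append(
            {
                "indicator": label,
                "reference_case": _fmt(
                    reference.means[metric], reference.ci_low[metric], reference.ci_high[metric], money
                ),
                "sensitivity_doubled_costs": _fmt(
                    sensitivity.means[metric], sensitivity.ci_low[metric], sensitivity.ci_high[metric], money
                ),
            }
        )
    return pd.DataFrame(rows)
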