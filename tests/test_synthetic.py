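"""Generator determinism and parameter recovery of the synthetic study data."""

import numpy as np
import pytest

from econsult_cba.cba import CostConfig
from econsult_cba.errors import ValidationError
from econsult_cba.fee_model import CONS_CODE, VIST_CODE, net_avoided_cost
from econsult_cba.survey import (
    necessity_breakdown,
    proportion_estimate,
    top_two_box,
    usage_band_distribution,
)
from econsult_cba.synthetic import (
    DEFAULT_SPECIALTY_COUNTS,
    FeeParams,
    GeneratorConfig,
    gen_consult_log,
    gen_cost_ledger,
    gen_experience_surveys,
    gen_fee_schedule,
    gen_post_consult_surveys,
)
from econsult_cba.utilization import tally_by_specialty

from dataclasses import replace


def test_consult_log_recovers_specialty_mix():
    """Multinomial counts land within 3 SEs of the configured per-specialty targets."""
    config = GeneratorConfig(seed=0)
    log = gen_consult_log(config)
    assert len(log) == 6072
    counts = {t.specialty: t.count for t in tally_by_specialty(log)}
    for specialty, target in DEFAULT_SPECIALTY_COUNTS.items():
        p = target / 6072
        se = np.sqrt(6072 * p * (1 - p))
        assert abs(counts.get(specialty, 0) - target) < 3 * se, specialty


def test_consult_log_empty_and_deterministic():
    assert gen_consult_log(replace(GeneratorConfig(seed=1), n_consults=0)) == []
    assert gen_consult_log(GeneratorConfig(seed=5)) == gen_consult_log(GeneratorConfig(seed=5))


def test_bad_shares_rejected():
    with pytest.raises(ValidationError):
        GeneratorConfig(specialty_shares={"a": 0.5, "b": 0.4})


def test_post_consult_recovery_of_survey_rates():
    config = GeneratorConfig(seed=2)
    log = gen_consult_log(config)
    pcp, specialist = gen_post_consult_surveys(log, config)
    assert len(pcp) == 608 and len(specialist) == 653

    est = proportion_estimate([r.avoided_referral == "yes" for r in pcp])
    assert abs(est.proportion - 0.84) < 2 * est.se

    sat = top_two_box([r.satisfaction for r in pcp])
    assert abs(sat.proportion - 0.99) < 2 * max(sat.se, np.sqrt(0.99 * 0.01 / 608))

    nec = necessity_breakdown([r.necessity for r in specialist])
    for share, target in [(nec.unnecessary_share, 0.55), (nec.necessary_share, 0.40)]:
        assert abs(share - target) < 2 * np.sqrt(target * (1 - target) / 638)

    # consult linkage preserved: every response points at a generated consult
    ids = {r.consult_id for r in log}
    assert all(r.consult_id in ids for r in pcp + specialist)


def test_certain_avoidance_leaves_no_followup_records():
    config = GeneratorConfig(seed=4)
    config = replace(config, survey=replace(config.survey, avoidance=1.0))
    pcp, _ = gen_post_consult_surveys(gen_consult_log(config), config)
    assert all(r.avoided_referral == "yes" for r in pcp)


def test_survey_size_cannot_exceed_log():
    config = replace(GeneratorConfig(seed=0), n_consults=10)
    with pytest.raises(ValidationError):
        gen_post_consult_surveys(gen_consult_log(config), config)


def test_experience_band_recovery():
    config = GeneratorConfig(seed=6)
    out = gen_experience_surveys(config)
    assert len(out) == 89
    dist = usage_band_distribution(out)
    for (band, count, share), target in zip(dist, (34, 20, 18, 17)):
        p = target / 89
        assert abs(share - p) < 2 * np.sqrt(p * (1 - p) / 89), band


def test_experience_degenerate_weights():
    config = GeneratorConfig(seed=1)
    config = replace(config, survey=replace(config.survey, usage_band_weights=(1, 0, 0, 0)))
    out = gen_experience_surveys(config)
    assert all(r.usage_band == "1-5" for r in out)


def test_fee_schedule_contains_codes_and_calibrated_net():
    config = replace(GeneratorConfig(seed=0), fees=FeeParams(comprehensive_fee_sd=0.0))
    schedule = gen_fee_schedule(config)
    assert {c.code_id for c in schedule.codes} >= {CONS_CODE, VIST_CODE}
    # mean fee $174.17 with sd 0 gives net saving $76.35 for every specialty
    for specialty in config.specialty_shares:
        assert net_avoided_cost(specialty, schedule).net_avoided == 7635


def test_fee_schedule_truncated_above_encounter_cost():
    config = replace(
        GeneratorConfig(seed=0), fees=FeeParams(comprehensive_fee_mean=100.0, comprehensive_fee_sd=40.0)
    )
    schedule = gen_fee_schedule(config)
    for specialty in config.specialty_shares:
        assert net_avoided_cost(specialty, schedule).net_avoided >= 0


def test_cost_ledger_onboarding_draws():
    config = replace(GeneratorConfig(seed=0), costs=CostConfig(onboarding_fee_sd=0, n_groups=3))
    _, fees = gen_cost_ledger(config)
    assert sum(fees) == 3 * 126_500  # $3,795 at sd 0

    config = replace(GeneratorConfig(seed=0), costs=CostConfig(n_groups=0))
    _, fees = gen_cost_ledger(config)
    assert fees == []

    config = replace(GeneratorConfig(seed=0), costs=CostConfig(n_groups=10_000))
    _, fees = gen_cost_ledger(config)
    se = 23_000 / np.sqrt(10_000)
    assert abs(np.mean(fees) - 126_500) < 3 * se
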