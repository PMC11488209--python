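#!/usr/bin/env python
"""Deterministic cost-benefit analysis of the generated dataset.

Chains the fee model (net saving per averted referral by specialty), the
survey-estimated avoidance proportion, and the onboarding/licensing cost
ledger with its 7%/yr opportunity cost of capital into point estimates of
total cost, total benefit, net benefit, BCR and ROI. Writes results/cba_point.json.
"""

import argparse
import json
from pathlib import Path

from econsult_cba import io as eio
from econsult_cba.cba import BenefitInputs, cba_point, implementation_cost, referrals_avoided, total_benefit
from econsult_cba.fee_model import net_avoided_cost, vh_encounter_cost
from econsult_cba.money import cents_to_dollars, format_dollars_whole
from econsult_cba.survey import proportion_estimate
from econsult_cba.utilization import Role, tally_by_specialty

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

consults = eio.read_consult_log(args.data_dir / "consults.csv")
schedule = eio.read_fee_schedule(args.data_dir / "fee_codes.csv", args.data_dir / "fee_schedule.json")
responses = eio.read_post_consult_surveys(args.data_dir / "post_consult_surveys.csv")
pcp = [r for r in responses if r.responder_role == Role.PRIMARY_CARE]
avoidance = proportion_estimate([r.avoided_referral == "yes" for r in pcp])

tallies = tally_by_specialty(consults)
net = {t.specialty: net_avoided_cost(t.specialty, schedule).net_avoided for t in tallies}
inputs = BenefitInputs(
    consults_by_specialty={t.specialty: t.count for t in tallies},
    avoidance_proportion=avoidance.proportion,
    net_avoided_by_specialty=net,
)
avoided = referrals_avoided(inputs)
benefit = total_benefit(inputs)
cost_config, onboarding = eio.read_cost_config(args.data_dir / "cost_config.json")
ledger = implementation_cost(cost_config, sum(onboarding) if onboarding else None)
point = cba_point(benefit, ledger.total, avoided)

args.outdir.mkdir(parents=True, exist_ok=True)
(args.outdir / "cba_point.json").write_text(
    json.dumps(
        {
            "encounter_cost": cents_to_dollars(vh_encounter_cost(schedule)),
            "avoidance_proportion": avoidance.proportion,
            "referrals_avoided": avoided.total,
            "total_benefit": cents_to_dollars(benefit),
            "total_cost": cents_to_dollars(ledger.total),
            "net_benefit": cents_to_dollars(point.net_benefit),
            "bcr": point.bcr,
            "roi": point.roi,
        },
        indent=2,
    )
)

print(f"phone-encounter cost per consult: ${cents_to_dollars(vh_encounter_cost(schedule)):.2f}")
print(f"avoidance proportion (survey): {avoidance.proportion:.4f}")
print(f"referrals avoided: {avoided.total:.2f} (~{avoided.total_rounded:,})")
print(f"total benefit:  ${format_dollars_whole(benefit)}")
print(f"total cost:     ${format_dollars_whole(ledger.total)}")
print(f"net benefit:    ${format_dollars_whole(point.net_benefit)}")
print(f"BCR {point.bcr:.3f}, ROI {point.roi:.3f} (ratio-of-means point estimates)")
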