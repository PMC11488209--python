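#!/usr/bin/env python
"""Summarize the post-consultation and provider-experience surveys.

Computes the figure-equivalent numbers: satisfaction top-two-box rates by
role, the referral-avoidance proportion with binomial SE, the necessity
breakdown among specialist responses, follow-up items among non-avoided
consults, and the usage-band distribution. Writes results/survey_summary.json.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from econsult_cba import io as eio
from econsult_cba.survey import (
    necessity_breakdown,
    non_avoided_followup,
    proportion_estimate,
    top_two_box,
    usage_band_distribution,
)
from econsult_cba.utilization import Role

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

responses = eio.read_post_consult_surveys(args.data_dir / "post_consult_surveys.csv")
pcp = [r for r in responses if r.responder_role == Role.PRIMARY_CARE]
spec = [r for r in responses if r.responder_role == Role.SPECIALIST]

avoidance = proportion_estimate([r.avoided_referral == "yes" for r in pcp])
summary = {
    "avoidance": dataclasses.asdict(avoidance),
    "pcp_satisfaction": dataclasses.asdict(top_two_box([r.satisfaction for r in pcp])),
    "specialist_satisfaction": dataclasses.asdict(top_two_box([r.satisfaction for r in spec])),
    "necessity": dataclasses.asdict(necessity_breakdown([r.necessity for r in spec])),
    "non_avoided_followup": {
        k: dataclasses.asdict(v) for k, v in non_avoided_followup(pcp).items()
    },
    "usage_bands": [
        {"band": b, "count": c, "share": s}
        for b, c, s in usage_band_distribution(
            eio.read_experience_surveys(args.data_dir / "experience_surveys.csv")
        )
    ],
}

args.outdir.mkdir(parents=True, exist_ok=True)
(args.outdir / "survey_summary.json").write_text(json.dumps(summary, indent=2))

print(
    f"avoidance: {avoidance.numerator}/{avoidance.denominator} "
    f"= {avoidance.percent()}% (se {avoidance.se:.4f})"
)
print(f"pcp satisfaction (top-two-box): {summary['pcp_satisfaction']['proportion']:.0%}")
print(f"specialist satisfaction: {summary['specialist_satisfaction']['proportion']:.0%}")
print(
    "necessity among specialist responses: "
    f"{summary['necessity']['unnecessary_share']:.0%} unnecessary-ish / "
    f"{summary['necessity']['necessary_share']:.0%} necessary-ish"
)
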