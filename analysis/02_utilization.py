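#!/usr/bin/env python
"""Tally platform utilization: consults by specialty and the provider mix.

Reads the dataset written by 01_generate_data.py, reproduces the two
utilization tables (provider counts with whole-percent shares; per-specialty
consult counts with 1-decimal shares and the top-specialty cut at 100
consults), and writes them under results/.
"""

import argparse
from pathlib import Path

from econsult_cba import io as eio
from econsult_cba.money import round_half_up
from econsult_cba.reporting import render_table1, render_table2
from econsult_cba.utilization import provider_mix, tally_by_specialty, top_specialties

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

consults = eio.read_consult_log(args.data_dir / "consults.csv")
tallies = tally_by_specialty(consults)
top, combined = top_specialties(tallies, min_consults=100)
mix = provider_mix(eio.read_provider_registry(args.data_dir / "providers.csv"))

args.outdir.mkdir(parents=True, exist_ok=True)
render_table1(mix).to_csv(args.outdir / "table1_provider_mix.csv", index=False)
render_table2(tallies).to_csv(args.outdir / "table2_specialty_consults.csv", index=False)

print(render_table1(mix).to_string(index=False))
print()
print(render_table2(tallies).to_string(index=False))
print(
    f"\n{len(top)} specialties reached 100+ consults, together "
    f"{round_half_up(100 * combined)}% of {sum(t.count for t in tallies)} consults"
)
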