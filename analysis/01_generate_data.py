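#!/usr/bin/env python
"""Generate the synthetic study dataset.

Writes a complete input directory — consult log (6,072 completed consults at
the observed specialty mix), provider registry (873 primary care + 143
specialists), post-consultation and provider-experience surveys at the
reported response rates, the fee schedule with the two phone-consult codes,
and the onboarding/licensing cost ledger — under results/data/.
"""

import argparse
from pathlib import Path

from econsult_cba.reporting import generate_dataset
from econsult_cba.synthetic import GeneratorConfig

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results/data"))
args = parser.parse_args()

config = GeneratorConfig(seed=args.seed)
generate_dataset(config, args.outdir)
print(f"wrote dataset for seed {args.seed} to {args.outdir}:")
for f in sorted(args.outdir.iterdir()):
    print(f"  {f.name}  ({f.stat().st_size} bytes)")
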