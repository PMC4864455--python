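#!/usr/bin/env python
"""Estimate growth rates and relative rates (mu) from the simulated plate.

Reads results/inputs/plate.csv, fits the log-phase slope of each well, and
reports each strain's mu against the wild-type rescue.  Writes
results/rates.tsv.
"""

import argparse
from pathlib import Path

from compscore.pipeline import compute_plate_rates

parser = argparse.ArgumentParser()
parser.add_argument("--plate", type=Path, default=Path("results/inputs/plate.csv"))
parser.add_argument("--out", type=Path, default=Path("results/rates.tsv"))
args = parser.parse_args()

rates = compute_plate_rates(args.plate)
args.out.parent.mkdir(parents=True, exist_ok=True)
rates.to_csv(args.out, sep="\t", index=False)

print(rates.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(f"\nwrote {args.out}")
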