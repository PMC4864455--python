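#!/usr/bin/env python
"""Benchmark FCS/FCT against the computational predictor across reference sets.

Reads results/inputs/cohort.tsv, reports the FCS operating point at the 0.6
cutoff and the predictor at its matched-recall threshold, then computes
AUPRC / AUROC / MCC / REC90 for each scorer on each annotation-stringency
reference set.  Writes results/benchmark_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from compscore.benchmark import confusion_at_threshold, matched_recall_threshold, summarize
from compscore.refsets import build_reference, records_from_frame, refset_frame
from compscore.synthetic_data import read_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/inputs/cohort.tsv"))
parser.add_argument("--out", type=Path, default=Path("results/benchmark_summary.tsv"))
args = parser.parse_args()

cohort = read_cohort(args.cohort)
labels = cohort["label"].to_numpy(dtype=int)
cc = confusion_at_threshold(cohort["fcs"], labels, 0.6)
print(
    f"FCS >= 0.6: precision {100 * cc.precision:.0f}%  recall {100 * cc.sensitivity:.0f}%  "
    f"specificity {100 * cc.specificity:.0f}%"
)
t = matched_recall_threshold(cohort["predictor"], labels, cc.sensitivity)
pc = confusion_at_threshold(cohort["predictor"], labels, t)
print(
    f"predictor at matched recall (t={t:.2f}): precision {100 * pc.precision:.0f}%  "
    f"specificity {100 * pc.specificity:.0f}%"
)

records = records_from_frame(cohort)
rows = []
for mode in ("original", "dm_only", "dm_and_clinvar", "exac_any", "exac_lt_1e-3"):
    rf = refset_frame(build_reference(records, mode))
    y = rf["label"].to_numpy(dtype=int)
    for scorer in ("fcs", "fct", "predictor"):
        s = rf[scorer].to_numpy(dtype=float)
        thr = 0.6 if scorer in ("fcs", "fct") else t
        rows.append({"refset": mode, **summarize(s, y, scorer, threshold=thr).__dict__})
summary = pd.DataFrame(rows)
args.out.parent.mkdir(parents=True, exist_ok=True)
summary.to_csv(args.out, sep="\t", index=False)

cols = ["refset", "scorer", "auprc", "auroc", "mcc", "rec90", "auprc_norm", "prior"]
print("\n" + summary[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
ratio = (
    summary.query("scorer == 'fcs'").set_index("refset")["auprc"]
    / summary.query("scorer == 'predictor'").set_index("refset")["auprc"]
)
print("\nAUPRC ratio (FCS / predictor) per reference set:")
print(ratio.to_string(float_format=lambda x: f"{x:.3f}"))
print(f"\nwrote {args.out}")
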