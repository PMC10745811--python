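"""Render the significance summary of the association panel: one row per
bacterial measure with direction arrows per genotype and axis, and a '+'
wherever the genotype regression slopes differ significantly."""

import argparse
from pathlib import Path

import pandas as pd

from frailmicro.association import AssociationTable, render_summary_markdown, summarize

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results/associations.csv"))
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

results = pd.read_csv(args.results)
summary = summarize(AssociationTable(results), alpha=args.alpha)
print(render_summary_markdown(summary))

diff = results.dropna(subset=["slope_diff_p"])
sig = diff[diff["slope_diff_p"] < args.alpha]
print(f"{sig['measure_name'].nunique()} measures with a significant genotype "
      "slope difference on at least one axis")
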