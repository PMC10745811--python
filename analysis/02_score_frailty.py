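"""Compute the frailty instrument: per-item penetrance weights, the wild-type
age screen over the behavioural tasks, and the three per-animal scores
(Mfs, Pcs, frailty = 2000/(Mfs+Pcs)).  Writes scores.csv, penetrance.csv and
screen.csv under results/."""

import argparse
from pathlib import Path

from frailmicro.frailty import score_cohort, write_scores
from frailmicro.io_model import Config, read_cohort_dir
from frailmicro.stats import pearson_test

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_cohort_dir(args.cohort)
scores = score_cohort(cohort, Config())
args.out.mkdir(parents=True, exist_ok=True)
write_scores(scores, args.out / "scores.csv")
scores.pc.penetrance.rename("fraction_affected").to_csv(args.out / "penetrance.csv")
scores.mf.screen.table.to_csv(args.out / "screen.csv", index=False)

print("task screen (wild type, both sexes pooled):")
print(scores.mf.screen.table[["task", "n", "pearson_r", "p_value", "included"]]
      .to_string(index=False))
s = scores.scores.dropna(subset=["frailty"])
for geno, grp in s.groupby("genotype"):
    r, p = pearson_test(grp["age_months"], grp["frailty"])
    print(f"frailty vs age, {geno}: r = {r:.4f}, p = {p:.4g} (n = {len(grp)})")
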