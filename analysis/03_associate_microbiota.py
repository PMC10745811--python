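"""Associate every quantified bacterial group (and the Bacteroidetes/
Firmicutes ratio) with chronological age and with the frailty score, per
genotype, with ROUT outlier removal at Q = 1% in every regression and an
ANCOVA slope-equality test between genotypes.  Also compares measures between
genotypes in the old (>10 months) sub-cohort.  Writes associations.csv,
summary.csv/.md, aged_comparison.csv and detection_filter.csv."""

import argparse
from pathlib import Path

from frailmicro.frailty import read_scores
from frailmicro.io_model import Config, read_cohort_dir
from frailmicro.pipeline import associate_cohort, write_association_outputs

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--scores", type=Path, default=Path("results/scores.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_cohort_dir(args.cohort)
scores = read_scores(args.scores)
outputs = associate_cohort(cohort, scores, Config())
write_association_outputs(outputs, args.out)

dropped = outputs.detection_decisions.loc[~outputs.detection_decisions["kept"],
                                          "group_name"]
print(f"groups dropped below detection threshold: {list(dropped)}")
cells = outputs.panel.results.dropna(subset=["p_r"])
print(f"{(cells.p_r < 0.05).sum()} of {len(cells)} association cells significant "
      "at p < 0.05")
if len(outputs.aged):
    print("aged (>10 months) genotype comparisons:")
    print(outputs.aged[["group_name", "n_wildtype", "n_5xFAD", "p", "age_p"]]
          .to_string(index=False))
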