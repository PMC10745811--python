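"""End-to-end drivers: simulate -> score -> associate -> report.

Thin orchestration over the library modules so the command-line interface,
the analysis scripts and the acceptance checks all run the identical path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import association, microbiota
from .association import AssociationTable
from .frailty import CohortScores, score_cohort
from .io_model import Cohort, Config, write_cohort, write_results
from .simulate import GeneratorSpec, simulate_cohort, write_ground_truth

log = logging.getLogger("frailmicro")


@dataclass
class AssociationOutputs:
    measures: pd.DataFrame
    panel: AssociationTable
    summary: pd.DataFrame
    aged: pd.DataFrame
    detection_decisions: pd.DataFrame


def simulate_to_dir(spec: GeneratorSpec, out_dir: str | Path) -> Cohort:
    """Simulate a cohort and write its CSV tables plus ground truth."""
    out = Path(out_dir)
    cohort, truth = simulate_cohort(spec)
    write_cohort(cohort, out)
    write_ground_truth(truth, out / "ground_truth.json")
    spec.to_yaml(out / "generator_spec.yaml")
    log.info("simulated cohort of %d animals into %s", len(cohort.animals), out)
    return cohort


def associate_cohort(
    cohort: Cohort, scores: CohortScores | pd.DataFrame, config: Config | None = None
) -> AssociationOutputs:
    """Quantify microbes, filter for detection, add the B/F ratio, run the
    correlation panel and the aged-subset comparison, and build the summary."""
    config = config or Config()
    scores_df = scores.scores if isinstance(scores, CohortScores) else scores
    measures = microbiota.quantify_cohort(cohort)
    measures, decisions = microbiota.detection_filter(
        measures, cohort.animals, min_evaluable_n=config.min_evaluable_n
    )
    measures = microbiota.add_bf_ratio(measures)
    panel = association.correlate_panel(measures, scores_df, config)
    summary = association.summarize(panel, alpha=config.sig_alpha)
    aged = microbiota.aged_subset_from_config(measures, cohort.animals, config)
    return AssociationOutputs(
        measures=measures, panel=panel, summary=summary, aged=aged,
        detection_decisions=decisions,
    )


def run_all(
    spec: GeneratorSpec | None = None, config: Config | None = None
) -> tuple[Cohort, CohortScores, AssociationOutputs]:
    """Simulate, score and associate in memory (no files)."""
    cohort, _ = simulate_cohort(spec or GeneratorSpec())
    scores = score_cohort(cohort, config)
    outputs = associate_cohort(cohort, scores, config)
    return cohort, scores, outputs


def write_association_outputs(outputs: AssociationOutputs, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(outputs.panel.results, out / "associations.csv")
    outputs.summary.to_csv(out / "summary.csv", index=False)
    (out / "summary.md").write_text(
        association.render_summary_markdown(outputs.summary), encoding="utf-8"
    )
    if len(outputs.aged):
        outputs.aged.to_csv(out / "aged_comparison.csv", index=False, float_format="%.12g")
    outputs.detection_decisions.to_csv(out / "detection_filter.csv", index=False)
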