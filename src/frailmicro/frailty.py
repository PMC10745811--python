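"""Composite frailty score.

Fitness is the mean of the musculoskeletal function score (Mfs) and the
physical constitution score (Pcs), both expressed as percent of the young
wild-type control mean.  Frailty is the reciprocal of fitness scaled to a
convenient magnitude:

    frailty = 2000 / (Mfs + Pcs) = 1000 / fitness

so a control-level animal (Mfs = Pcs = 100) scores exactly 10, and frailty
grows as performance declines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviour import MfResult, compute_mf_scores
from .io_model import Cohort, Config
from .phenotype import PcResult, compute_pc_scores

log = logging.getLogger("frailmicro")


def frailty_score(mfs: float, pcs: float) -> float:
    """2000 / (mfs + pcs); undefined (error) for a fully deficient profile."""
    if mfs < 0 or pcs < 0:
        raise ValueError(f"component scores must be >= 0, got mfs={mfs}, pcs={pcs}")
    if mfs + pcs == 0:
        raise ValueError(
            "frailty undefined for a fully deficient profile (mfs + pcs = 0)"
        )
    return 2000.0 / (mfs + pcs)


@dataclass
class CohortScores:
    """Per-animal scores plus the intermediate artefacts that produced them."""

    scores: pd.DataFrame  # animal_id, genotype, sex, age_months, mfs, pcs, fitness, frailty
    pc: PcResult
    mf: MfResult


def score_cohort(cohort: Cohort, config: Config | None = None) -> CohortScores:
    """Compute Mfs, Pcs, fitness and frailty for every animal in a cohort.

    Deterministic given cohort and config.  Animals missing either component
    score get an explicit missing frailty (no imputation — fitness averages
    both components, so neither can stand in for the other).
    """
    config = config or Config()
    pc = compute_pc_scores(cohort, config)
    mf = compute_mf_scores(cohort, config)
    df = cohort.animals[["animal_id", "genotype", "sex", "age_months"]].merge(
        pc.scores[["animal_id", "pcs"]], on="animal_id", how="left"
    ).merge(mf.scores, on="animal_id", how="left")

    frailties = []
    for _, row in df.iterrows():
        if not (np.isfinite(row["mfs"]) and np.isfinite(row["pcs"])):
            log.info(
                "frailty: animal %s missing %s; frailty missing",
                row["animal_id"],
                "mfs" if not np.isfinite(row["mfs"]) else "pcs",
            )
            frailties.append(np.nan)
        else:
            frailties.append(frailty_score(row["mfs"], row["pcs"]))
    df["fitness"] = (df["mfs"] + df["pcs"]) / 2.0
    df["frailty"] = frailties
    return CohortScores(scores=df, pc=pc, mf=mf)


def write_scores(scores: CohortScores, path) -> None:
    scores.scores.to_csv(path, index=False, float_format="%.12g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal_id": str}, encoding="utf-8")
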