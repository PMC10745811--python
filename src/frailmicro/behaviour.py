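"""Behavioural-task recording rules, trial aggregation, the wild-type age
screen, and the musculoskeletal function (Mf) score.

Tasks and their recording rules:

cage_top
    Inverted cage-lid hang, 60 s cap.  A fall within 10 s voids the trial
    (immediate retry); holding the full minute records 60 s.
tight_rope
    Forelimb rope hang, 60 s observation.  Falling records the time; reaching
    the far end in t seconds records 120 - t (faster traversal scores higher);
    holding for the full 60 s records 60; falls before 10 s are retried.
    Recorded values therefore live in [10, 120].
grip_strength
    Newton-meter peak gram-force, averaged over trials then divided by body
    weight (gram-force per gram).
open_field:<metric>
    ANY-maze summary metrics (average speed, distance, rearing frequency,
    movement duration, percent time moving); ingested as ready values and
    treated as candidate tasks like any other — the age screen decides whether
    they enter the Mf score.

Only tasks whose wild-type values correlate significantly with chronological
age are admitted to the Mf score: a frailty-relevant task must per se track
normal ageing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Cohort, Config, Genotype
from .stats import DegenerateDataError, pearson_test

log = logging.getLogger("frailmicro")

GRIP_TASKS = ("cage_top", "tight_rope", "grip_strength")

#: sentinel returned by recording rules when the trial must be repeated
RETRY = "retry"


def record_tightrope_trial(outcome: str, t: float) -> float | str:
    """Apply the tight-rope recording rule to one trial.

    ``outcome`` is "fell", "reached_end" or "held_full"; ``t`` is the fall /
    traversal time in seconds (0 < t <= 60).  Falls before 10 s signal a
    retry.
    """
    if not 0 < t <= 60:
        raise ValueError(f"tight-rope trial time must be in (0, 60] s, got {t}")
    if outcome == "fell":
        return RETRY if t < 10 else float(t)
    if outcome == "reached_end":
        return 120.0 - float(t)
    if outcome == "held_full":
        return 60.0
    raise ValueError(f"unknown tight-rope outcome {outcome!r}")


def record_cagetop_trial(outcome: str, t: float) -> float | str:
    """Apply the cage-top recording rule: falls record the time (retry if
    under 10 s), holding the full 60 s records 60."""
    if not 0 < t <= 60:
        raise ValueError(f"cage-top trial time must be in (0, 60] s, got {t}")
    if outcome == "fell":
        return RETRY if t < 10 else float(t)
    if outcome == "held_full":
        return 60.0
    raise ValueError(f"unknown cage-top outcome {outcome!r}")


def normalize_grip(gram_force: float, body_weight: float) -> float:
    """Gram-force divided by body weight (gram-force per gram)."""
    if not body_weight > 0:
        raise ValueError(f"body weight must be > 0 g, got {body_weight}")
    if gram_force < 0:
        raise ValueError(f"gram force must be >= 0, got {gram_force}")
    return gram_force / body_weight


def aggregate_trials(values: list[float]) -> float | None:
    """Arithmetic mean of the valid trials of one task; ``None`` when no valid
    trial remains (the caller logs and treats the task as missing)."""
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return float(np.mean(vals))


_RECORD_RULES = {"cage_top": record_cagetop_trial, "tight_rope": record_tightrope_trial}


def aggregate_cohort_trials(cohort: Cohort) -> pd.DataFrame:
    """Per-animal, per-task mean values with recording rules applied.

    Timed tasks run their outcome rule per trial (rows that would signal a
    retry are dropped with a log line — the raw data is expected to contain
    post-retry values already).  Grip-strength gram-force is averaged first
    and then normalised by body weight.  Returns a long frame with columns
    animal_id, task, mean_value.
    """
    if cohort.trials.empty:
        return pd.DataFrame(columns=["animal_id", "task", "mean_value"])
    weights = dict(zip(cohort.animals["animal_id"], cohort.animals["body_weight_g"]))
    rows = []
    for (aid, task), grp in cohort.trials.groupby(["animal_id", "task"]):
        values = []
        for _, tr in grp.iterrows():
            if task in _RECORD_RULES:
                rec = _RECORD_RULES[task](tr["outcome"], float(tr["value"]))
                if rec == RETRY:
                    log.info(
                        "trials: animal %s task %s trial %s voided (fell before 10 s)",
                        aid, task, tr["trial_index"],
                    )
                    continue
                values.append(rec)
            else:
                values.append(float(tr["value"]))
        if task in GRIP_TASKS and len(values) > 3:
            raise ValueError(f"animal {aid!r} task {task!r}: more than 3 valid trials")
        mean = aggregate_trials(values)
        if mean is None:
            log.info("trials: animal %s task %s has no valid trials; value missing", aid, task)
            continue
        if task == "grip_strength":
            mean = normalize_grip(mean, float(weights[aid]))
        rows.append({"animal_id": aid, "task": task, "mean_value": mean})
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Outcome of the wild-type age-correlation screen, per task."""

    table: pd.DataFrame  # task, n, pearson_r, p_value, included, reason

    @property
    def included_tasks(self) -> list[str]:
        return list(self.table.loc[self.table["included"], "task"])


def screen_age_correlated(
    aggregates: pd.DataFrame, animals: pd.DataFrame, alpha: float = 0.05
) -> ScreenResult:
    """Decide per task whether it correlates with chronological age.

    Run on wild-type animals only (both sexes pooled): Pearson r of the task
    mean against age, two-sided p; a task is included when p < alpha.  Tasks
    with fewer than 3 wild-type values or zero variance are excluded with a
    logged reason.
    """
    wt_ids = set(
        animals.loc[animals["genotype"] == Genotype.wildtype.value, "animal_id"]
    )
    merged = aggregates.merge(
        animals[["animal_id", "age_months"]], on="animal_id", how="left"
    )
    rows = []
    for task, grp in merged.groupby("task", sort=True):
        sub = grp[grp["animal_id"].isin(wt_ids)]
        n = len(sub)
        rec = {"task": task, "n": n, "pearson_r": np.nan, "p_value": np.nan,
               "included": False, "reason": ""}
        if n < 3:
            rec["reason"] = "fewer than 3 wild-type animals"
        else:
            try:
                r, p = pearson_test(sub["age_months"], sub["mean_value"])
                rec.update(pearson_r=r, p_value=p,
                           included=bool(p < alpha),
                           reason="" if p < alpha else f"p = {p:.4g} >= {alpha}")
            except DegenerateDataError:
                rec["reason"] = "zero variance"
        if not rec["included"]:
            log.info("screen: task %s excluded (%s)", task, rec["reason"])
        else:
            log.info("screen: task %s included (r = %.4f, p = %.4g)",
                     task, rec["pearson_r"], rec["p_value"])
        rows.append(rec)
    return ScreenResult(table=pd.DataFrame(rows))


def mf_score(
    animal_aggregates: dict[str, float],
    control_means: dict[str, float],
    included_tasks: list[str],
) -> float:
    """Musculoskeletal function score for one animal.

    Mean over the screened-in tasks of the animal's task mean expressed as a
    percentage of the control mean.  ``NaN`` when the animal has no value for
    any included task.
    """
    ratios = []
    for task in included_tasks:
        cm = control_means.get(task)
        if cm is None or not np.isfinite(cm):
            continue
        if not cm > 0:
            raise ValueError(f"control mean for included task {task!r} must be > 0, got {cm}")
        v = animal_aggregates.get(task)
        if v is None or not np.isfinite(v):
            continue
        ratios.append(100.0 * v / cm)
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


@dataclass
class MfResult:
    screen: ScreenResult
    control_ids: list[str]
    control_means: dict[str, float]
    scores: pd.DataFrame  # animal_id, mfs


def compute_mf_scores(cohort: Cohort, config: Config) -> MfResult:
    """Full Mf pipeline: aggregate trials, screen tasks, score every animal.

    Uses the same reference group as the Pc score (wild type, age at most
    ``config.control_max_age`` months).  An animal missing every included task
    receives a missing Mfs (logged).
    """
    agg = aggregate_cohort_trials(cohort)
    if agg.empty:
        raise ValueError("cohort has no behavioural trials")
    screen = screen_age_correlated(agg, cohort.animals, alpha=config.screen_alpha)
    included = screen.included_tasks
    if not included:
        raise ValueError("no task passed the wild-type age-correlation screen")

    animals = cohort.animals
    ctrl_ids = list(
        animals.loc[
            (animals["genotype"] == Genotype.wildtype.value)
            & (animals["age_months"] <= config.control_max_age),
            "animal_id",
        ]
    )
    if not ctrl_ids:
        raise ValueError(
            f"empty control group: no wild-type animals aged <= {config.control_max_age} months"
        )
    ctrl_agg = agg[agg["animal_id"].isin(ctrl_ids)]
    control_means = {
        task: float(grp["mean_value"].mean())
        for task, grp in ctrl_agg.groupby("task") if task in included
    }

    by_animal = {
        aid: dict(zip(grp["task"], grp["mean_value"]))
        for aid, grp in agg.groupby("animal_id")
    }
    rows = []
    for aid in animals["animal_id"]:
        mfs = mf_score(by_animal.get(aid, {}), control_means, included)
        if not np.isfinite(mfs):
            log.info("mf: animal %s has no value on any included task; Mfs missing", aid)
        rows.append({"animal_id": aid, "mfs": mfs})
    return MfResult(
        screen=screen, control_ids=ctrl_ids, control_means=control_means,
        scores=pd.DataFrame(rows),
    )
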