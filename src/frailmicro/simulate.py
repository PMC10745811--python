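"""Synthetic ageing-cohort generator.

Emulates a cross-sectional two-genotype cohort (default 40 wild type + 40
5xFAD, balanced sexes, ages uniform over 3-16 months) with the statistical
structure the frailty pipeline assumes:

* behavioural performance declines linearly with age, faster in transgenics,
  with per-trial measurement noise and the task recording rules applied;
* each animal carries a latent frailty propensity ``u ~ N(0, frailty_sd)``
  (a z-score, default unit variance) that depresses its grip-task levels by
  ``frailty_scale`` task units per unit of ``u`` and raises its
  examination-item affection odds by ``frailty_gain`` logits — the individual
  quality-of-ageing variation that makes frailty more than a relabelling of
  age;
* examination items follow logistic penetrance curves in age and genotype;
* open-field metrics carry no age signal (they emulate exploration-driven
  measures and should be screened out);
* microbial log10 abundances follow ``mu + delta_age*age + delta_frail*F +
  delta_tg*tg + noise`` where ``F`` is the animal's *latent* frailty — the
  composite score computed from its noiseless task means and realised item
  scores — so the pipeline's estimated frailty is a noisy proxy by design.

Everything is reproducible from ``rng_seed`` through named substreams, and a
ground-truth record (planted parameters, per-animal latent frailty, planted
outlier indices) is returned alongside the cohort for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .behaviour import mf_score
from .io_model import Cohort, Config, Genotype
from .phenotype import pc_raw, pc_score, penetrance_table

QPCR_LOD_CT = 35.0  #: replicate Ct above this fails to amplify (undetermined)


@dataclass
class TaskModel:
    """Linear decline model for one behavioural task.

    The animal's true task level is ``intercept + (age_slope + tg_age_slope*tg
    + sex_age_slope*male) * age - frailty_scale * u`` where ``u`` is its
    latent frailty propensity (standard-normal scale), so a frail animal
    underperforms on every linked task by a correlated, age-independent
    amount.  Per-trial Gaussian noise is added and the result clipped to the
    task's recordable range ``[lo, hi]`` (the retry floor and the protocol
    ceiling).  Default ranges keep the wild-type bulk clear of both rails so
    the recorded values stay linear in age.
    """

    intercept: float
    age_slope: float = 0.0
    tg_age_slope: float = 0.0
    sex_age_slope: float = 0.0
    noise_sd: float = 0.0
    lo: Optional[float] = None
    hi: Optional[float] = None
    n_trials: int = 3
    frailty_scale: float = 0.0


@dataclass
class ItemModel:
    """Logistic penetrance curve for one examination item.

    logit P(affected) = alpha + beta*age + gamma*tg + gamma_age*tg*age +
    frailty_gain*u; an affected animal scores 0 with probability
    ``severe_frac``, else 0.5.  ``gamma_age`` carries the accelerated
    transgenic decline, ``gamma`` a constant genotype incidence shift, and
    ``frailty_gain`` couples the item to the animal's latent propensity.
    """

    alpha: float
    beta: float = 0.0
    gamma: float = 0.0
    gamma_age: float = 0.0
    severe_frac: float = 0.25
    frailty_gain: float = 0.6


@dataclass
class MicrobeModel:
    """Log10-abundance model for one bacterial group.

    ``kind`` decides the raw encoding: "plate" rows carry Poisson colony
    counts with plating metadata, "qpcr" rows carry triplicate Cts against a
    standard curve (replicates beyond the LOD are undetermined).
    """

    mu: float
    delta_age: float = 0.0
    delta_frail: float = 0.0
    delta_tg: float = 0.0
    delta_age_tg: float = 0.0
    noise_sd: float = 0.5
    kind: str = "qpcr"
    plated_volume_ml: float = 1.0
    counted_area_fraction: float = 1.0
    curve_slope: float = -3.4
    curve_intercept: float = 38.0
    per_gram_factor: float = 1e6


def default_tasks() -> dict[str, TaskModel]:
    return {
        "cage_top": TaskModel(54.0, -1.9, -2.0, 0.0, 4.0, lo=10.0, hi=60.0,
                              frailty_scale=6.0),
        "tight_rope": TaskModel(95.0, -3.5, -3.5, 0.0, 7.0, lo=10.0, hi=110.0,
                                frailty_scale=10.0),
        "grip_strength": TaskModel(6.0, -0.22, -0.18, 0.0, 0.45, lo=0.3,
                                   frailty_scale=0.6),
        "open_field:avg_speed": TaskModel(4.0, 0.0, 0.0, 0.0, 1.0, lo=0.1, n_trials=1),
        "open_field:distance": TaskModel(2400.0, 0.0, 0.0, 0.0, 600.0, lo=10.0, n_trials=1),
        "open_field:rearing_freq": TaskModel(20.0, 0.0, 0.0, 0.0, 6.0, lo=0.5, n_trials=1),
        "open_field:movement_duration": TaskModel(300.0, 0.0, 0.0, 0.0, 80.0, lo=5.0,
                                                  n_trials=1),
        "open_field:pct_time_moving": TaskModel(50.0, 0.0, 0.0, 0.0, 12.0, lo=1.0,
                                                hi=100.0, n_trials=1),
    }


def default_items() -> dict[str, ItemModel]:
    common = dict(beta=0.30, gamma_age=0.18, severe_frac=0.30, frailty_gain=1.5)
    items = {
        "hearing": ItemModel(alpha=-4.5, **common),
        "visual_placing": ItemModel(alpha=-5.0, **common),
        "coat_condition": ItemModel(alpha=-4.0, **common),
        "kyphosis": ItemModel(alpha=-5.0, **common),
        "gait_disorder": ItemModel(alpha=-5.5, **common),
        "tail_stiffening": ItemModel(alpha=-4.8, **common),
        "whisker_loss": ItemModel(alpha=-4.2, **common),
        "dermatitis": ItemModel(alpha=-5.2, **common),
        "body_condition": ItemModel(alpha=-4.6, **common),
        "menace_reflex": ItemModel(alpha=-5.0, **common),
        "eye_discharge": ItemModel(alpha=-5.4, **common),
        "piloerection": ItemModel(alpha=-4.4, **common),
        # items the wild type shows more often (coat/lens/weight phenotypes)
        "alopecia": ItemModel(alpha=-3.6, beta=0.30, gamma=-0.4,
                              severe_frac=0.30, frailty_gain=1.5),
        "cataracts": ItemModel(alpha=-5.0, beta=0.30, gamma=-0.8,
                               severe_frac=0.30, frailty_gain=1.5),
        "adiposity": ItemModel(alpha=-4.8, beta=0.30, gamma=-0.9,
                               severe_frac=0.30, frailty_gain=1.5),
    }
    # items essentially absent from the colony: penetrance ~0, weight ~0
    for rare in ("tumours", "microphthalmia", "nasal_discharge",
                 "incontinence", "tremor"):
        items[rare] = ItemModel(alpha=-15.0, beta=0.0, gamma=0.0)
    return items


def default_microbes() -> dict[str, MicrobeModel]:
    return {
        # cultured families (CFU/g)
        "Lactobacillaceae": MicrobeModel(4.8, delta_age=0.03, noise_sd=0.45,
                                         kind="plate", counted_area_fraction=0.1),
        "Enterobacteriaceae": MicrobeModel(4.2, delta_age=0.13, delta_age_tg=-0.13,
                                           noise_sd=0.35, kind="plate"),
        "Schaedler": MicrobeModel(6.0, delta_frail=0.08, noise_sd=0.35,
                                  kind="plate", plated_volume_ml=0.01),
        # qPCR targets (bacteria/g)
        "Akkermansia_muciniphila": MicrobeModel(9.3, noise_sd=0.6),
        "Bifidobacterium": MicrobeModel(9.0, delta_frail=0.06, noise_sd=0.4),
        "Bacteroides": MicrobeModel(9.5, delta_frail=0.06, delta_tg=-0.45, noise_sd=0.4),
        "Bacteroidetes": MicrobeModel(10.3, delta_age=0.05, delta_frail=0.05, noise_sd=0.4),
        "Firmicutes": MicrobeModel(10.5, delta_age=0.06, noise_sd=0.4),
        "Lactobacilli_Enterococci": MicrobeModel(9.2, noise_sd=0.5),
        # low-abundance targets sitting below the assay LOD for most samples
        "Prevotella": MicrobeModel(6.0, noise_sd=0.8),
        "Clostridium_coccoides": MicrobeModel(5.9, noise_sd=0.8),
    }


@dataclass
class GeneratorSpec:
    """Full description of one synthetic cohort; serialisable to YAML."""

    n_per_genotype: int = 40
    sex_balance: float = 0.5
    age_range: tuple[float, float] = (3.0, 16.0)
    frailty_sd: float = 1.0
    control_max_age: float = 6.0
    tasks: dict[str, TaskModel] = field(default_factory=default_tasks)
    items: dict[str, ItemModel] = field(default_factory=default_items)
    microbes: dict[str, MicrobeModel] = field(default_factory=default_microbes)
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_per_genotype < 1:
            problems.append(f"n_per_genotype must be >= 1, got {self.n_per_genotype}")
        if not 0 <= self.sex_balance <= 1:
            problems.append(f"sex_balance must be in [0, 1], got {self.sex_balance}")
        if not self.age_range[0] > 0 or self.age_range[1] < self.age_range[0]:
            problems.append(f"age_range must be positive and ordered, got {self.age_range}")
        if self.frailty_sd < 0:
            problems.append(f"frailty_sd must be >= 0, got {self.frailty_sd}")
        for name, t in self.tasks.items():
            if t.noise_sd < 0:
                problems.append(f"task {name}: noise_sd must be >= 0")
            if not 1 <= t.n_trials <= 3:
                problems.append(f"task {name}: n_trials must be in 1..3")
        for name, it in self.items.items():
            if not 0 <= it.severe_frac <= 1:
                problems.append(f"item {name}: severe_frac must be in [0, 1]")
        for name, m in self.microbes.items():
            if m.noise_sd < 0:
                problems.append(f"microbe {name}: noise_sd must be >= 0")
            if m.kind not in ("plate", "qpcr"):
                problems.append(f"microbe {name}: unknown kind {m.kind!r}")
        if not 0 <= self.outlier_fraction < 0.2:
            problems.append(
                f"outlier_fraction must be in [0, 0.2), got {self.outlier_fraction}"
            )
        if problems:
            raise ValueError("invalid GeneratorSpec: " + "; ".join(problems))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        data["tasks"] = {k: TaskModel(**v) for k, v in data.get("tasks", {}).items()}
        data["items"] = {k: ItemModel(**v) for k, v in data.get("items", {}).items()}
        data["microbes"] = {k: MicrobeModel(**v) for k, v in data.get("microbes", {}).items()}
        if "age_range" in data:
            data["age_range"] = tuple(data["age_range"])
        return cls(**data)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("animals", "frailty", "items", "tasks", "microbes", "outliers")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _clip(v: float, lo: Optional[float], hi: Optional[float]) -> float:
    if lo is not None:
        v = max(v, lo)
    if hi is not None:
        v = min(v, hi)
    return v


def _true_task_mean(t: TaskModel, age: float, tg: int, male: int, u: float) -> float:
    base = t.intercept + (t.age_slope + t.tg_age_slope * tg + t.sex_age_slope * male) * age
    base -= t.frailty_scale * u
    return _clip(base, t.lo, t.hi)


def _encode_timed_trial(task: str, value: float) -> tuple[str, float]:
    """Map a recorded cage-top / tight-rope value back to (outcome, time)."""
    if task == "cage_top":
        if value >= 60.0:
            return "held_full", 60.0
        return "fell", value
    # tight rope: recorded > 60 means the rope end was reached in 120 - value
    if value > 60.0:
        return "reached_end", 120.0 - value
    if value == 60.0:
        return "held_full", 60.0
    return "fell", value


def simulate_cohort(spec: GeneratorSpec | None = None) -> tuple[Cohort, dict]:
    """Generate a full cohort (all four tables) plus its ground-truth record.

    Reproducible: the same spec (including ``rng_seed``) yields identical
    output.  The ground truth carries per-animal latent frailty, the noiseless
    task means, and the planted microbe outlier row indices.
    """
    spec = spec or GeneratorSpec()
    spec.validate()
    rngs = _substreams(spec.rng_seed)
    lo_age, hi_age = spec.age_range

    # --- animals ------------------------------------------------------------
    animal_rows = []
    rng = rngs["animals"]
    for g in Genotype:
        n_female = int(round(spec.n_per_genotype * spec.sex_balance))
        sexes = ["female"] * n_female + ["male"] * (spec.n_per_genotype - n_female)
        for k, sex in enumerate(sexes):
            age = float(rng.uniform(lo_age, hi_age))
            weight = 24.0 + 4.0 * (sex == "male") + 0.15 * age + float(rng.normal(0, 1.5))
            animal_rows.append({
                "animal_id": f"{'WT' if g is Genotype.wildtype else 'TG'}{k + 1:03d}",
                "genotype": g.value, "sex": sex,
                "age_months": round(age, 3),
                "body_weight_g": round(max(weight, 15.0), 2),
            })
    animals = pd.DataFrame(animal_rows)
    ages = animals["age_months"].to_numpy()
    tg_flags = (animals["genotype"] == Genotype.tg5xFAD.value).to_numpy().astype(int)
    male_flags = (animals["sex"] == "male").to_numpy().astype(int)

    # --- latent frailty propensity ------------------------------------------
    u = rngs["frailty"].normal(0.0, spec.frailty_sd, size=len(animals))

    # --- examination items ---------------------------------------------------
    rng = rngs["items"]
    item_rows = []
    realized_scores: dict[str, dict[str, float]] = {aid: {} for aid in animals["animal_id"]}
    for name, it in spec.items.items():
        logit = (it.alpha + it.beta * ages + it.gamma * tg_flags
                 + it.gamma_age * tg_flags * ages + it.frailty_gain * u)
        p_aff = 1.0 / (1.0 + np.exp(-logit))
        affected = rng.random(len(animals)) < p_aff
        severe = rng.random(len(animals)) < it.severe_frac
        scores = np.where(affected, np.where(severe, 0.0, 0.5), 1.0)
        for i, aid in enumerate(animals["animal_id"]):
            s = float(scores[i])
            realized_scores[aid][name] = s
            row = {"animal_id": aid, "item_name": name, "score": s}
            if name == "hearing":
                # encode the raw click-test responses; the score column is left
                # blank so the pipeline's scoring rule reconstructs it
                responses = 3 if s == 1.0 else (0 if s == 0.0 else int(rng.integers(1, 3)))
                row.update(score=np.nan, responses=responses)
            elif name == "visual_placing":
                if s == 1.0:
                    lr = (2, 2)
                elif s == 0.5:
                    lr = [(1, 1), (2, 1), (1, 2)][int(rng.integers(0, 3))]
                else:
                    lr = [(0, 0), (2, 0), (0, 2), (1, 0), (0, 1)][int(rng.integers(0, 5))]
                row.update(score=np.nan, left_successes=lr[0], right_successes=lr[1])
            item_rows.append(row)
    items = pd.DataFrame(item_rows)

    # --- behavioural trials --------------------------------------------------
    rng = rngs["tasks"]
    trial_rows = []
    true_means: dict[str, dict[str, float]] = {aid: {} for aid in animals["animal_id"]}
    for name, t in spec.tasks.items():
        for i, aid in enumerate(animals["animal_id"]):
            m = _true_task_mean(t, ages[i], tg_flags[i], male_flags[i], u[i])
            true_means[aid][name] = m
            for trial in range(1, t.n_trials + 1):
                v = _clip(m + float(rng.normal(0, t.noise_sd)), t.lo, t.hi)
                if name in ("cage_top", "tight_rope"):
                    outcome, tv = _encode_timed_trial(name, v)
                    trial_rows.append({
                        "animal_id": aid, "task": name, "trial_index": trial,
                        "outcome": outcome, "value": round(tv, 3),
                    })
                elif name == "grip_strength":
                    bw = float(animals.loc[i, "body_weight_g"])
                    trial_rows.append({
                        "animal_id": aid, "task": name, "trial_index": trial,
                        "outcome": "measured", "value": round(v * bw, 3),
                    })
                else:
                    trial_rows.append({
                        "animal_id": aid, "task": name, "trial_index": trial,
                        "outcome": "measured", "value": round(v, 3),
                    })
    trials = pd.DataFrame(trial_rows)

    # --- latent frailty: composite of the noiseless phenotype ----------------
    latent = _latent_frailty(spec, animals, realized_scores, true_means)

    # --- microbes ------------------------------------------------------------
    rng = rngs["microbes"]
    microbe_rows = []
    curve_rows = []
    for name, mm in spec.microbes.items():
        if mm.kind == "qpcr":
            curve_rows.append({
                "curve_id": f"curve_{name}", "slope": mm.curve_slope,
                "intercept": mm.curve_intercept, "per_gram_factor": mm.per_gram_factor,
            })
        for i, aid in enumerate(animals["animal_id"]):
            log10v = (
                mm.mu
                + (mm.delta_age + mm.delta_age_tg * tg_flags[i]) * ages[i]
                + mm.delta_frail * latent[aid]
                + mm.delta_tg * tg_flags[i]
                + float(rng.normal(0, mm.noise_sd))
            )
            value = 10.0 ** log10v
            if mm.kind == "plate":
                mass_mg = float(rng.uniform(40.0, 80.0))
                expected = value * mm.counted_area_fraction * mm.plated_volume_ml / 100.0
                colonies = int(rng.poisson(expected))
                microbe_rows.append({
                    "animal_id": aid, "group_name": name, "kind": "plate",
                    "colonies": colonies, "faeces_mass_mg": round(mass_mg, 1),
                    "plated_volume_ml": mm.plated_volume_ml,
                    "counted_area_fraction": mm.counted_area_fraction,
                })
            else:
                copies = value / mm.per_gram_factor
                ct_mean = mm.curve_intercept + mm.curve_slope * np.log10(max(copies, 1e-12))
                cts = ct_mean + rng.normal(0, 0.15, size=3)
                row = {"animal_id": aid, "group_name": name, "kind": "qpcr",
                       "curve_id": f"curve_{name}"}
                for j, ct in enumerate(cts, start=1):
                    row[f"ct{j}"] = round(float(ct), 3) if ct <= QPCR_LOD_CT else np.nan
                microbe_rows.append(row)
    microbes = pd.DataFrame(microbe_rows)
    curves = pd.DataFrame(curve_rows)

    # --- planted outliers ----------------------------------------------------
    planted: list[int] = []
    if spec.outlier_fraction > 0 and spec.outlier_magnitude != 0:
        microbes, planted = plant_outliers(
            microbes, spec, rngs["outliers"]
        )

    cohort = Cohort(animals=animals, items=items, trials=trials,
                    microbes=microbes, curves=curves)
    truth = {
        "spec": dataclasses.asdict(spec),
        "latent_frailty": latent,
        "true_task_means": true_means,
        "planted_outlier_rows": planted,
    }
    return cohort, truth


def _latent_frailty(
    spec: GeneratorSpec,
    animals: pd.DataFrame,
    realized_scores: dict[str, dict[str, float]],
    true_means: dict[str, dict[str, float]],
) -> dict[str, float]:
    """Composite frailty of each animal's noiseless phenotype.

    Runs the actual scoring formulas on the noiseless task means (tasks with a
    negative age slope are the frailty-relevant set) and the realised item
    scores, with the control group defined exactly as in the pipeline.
    """
    from .frailty import frailty_score

    items_long = pd.DataFrame(
        [{"animal_id": a, "item_name": n, "score": s}
         for a, d in realized_scores.items() for n, s in d.items()]
    )
    pen = penetrance_table(items_long)
    n_items = int(items_long["item_name"].nunique())
    ctrl_ids = list(animals.loc[
        (animals["genotype"] == Genotype.wildtype.value)
        & (animals["age_months"] <= spec.control_max_age), "animal_id",
    ])
    if not ctrl_ids:
        raise ValueError("GeneratorSpec yields no control animals (wild type, young)")
    raw = {a: pc_raw(realized_scores[a], pen, n_items) for a in animals["animal_id"]}
    ctrl_raw_mean = float(np.mean([raw[a] for a in ctrl_ids]))
    relevant = [n for n, t in spec.tasks.items() if t.age_slope < 0]
    ctrl_means = {
        n: float(np.mean([true_means[a][n] for a in ctrl_ids])) for n in relevant
    }
    latent = {}
    for a in animals["animal_id"]:
        # performance cannot be negative; specs without recording floors could
        # otherwise push an extreme animal's noiseless mean below zero
        mfs = max(mf_score(true_means[a], ctrl_means, relevant), 0.0)
        pcs = pc_score(raw[a], ctrl_raw_mean)
        latent[a] = frailty_score(mfs, pcs)
    return latent


def plant_outliers(
    microbes: pd.DataFrame,
    spec: GeneratorSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[int]]:
    """Displace a random fraction of qPCR measurements by
    ``outlier_magnitude`` times the group's noise SD (in log10 units).

    Returns the modified microbes table and the planted row indices.  Only
    qPCR rows are displaced (the shift is applied to the replicate Cts through
    the standard curve, so the pipeline sees a coherent gross outlier).
    """
    if not 0 <= spec.outlier_fraction < 0.2:
        raise ValueError(
            f"outlier_fraction must be in [0, 0.2), got {spec.outlier_fraction}"
        )
    microbes = microbes.copy()
    planted: list[int] = []
    for name, mm in spec.microbes.items():
        if mm.kind != "qpcr":
            continue
        idx = microbes.index[(microbes["group_name"] == name)
                             & (microbes["kind"] == "qpcr")].to_numpy()
        n_out = int(round(spec.outlier_fraction * idx.size))
        if n_out == 0:
            continue
        chosen = rng.choice(idx, size=n_out, replace=False)
        shift_log10 = spec.outlier_magnitude * mm.noise_sd
        dct = mm.curve_slope * shift_log10  # Ct shift equivalent to the log10 shift
        sign = rng.choice([-1.0, 1.0], size=n_out)
        for s, i in zip(sign, chosen):
            for c in ("ct1", "ct2", "ct3"):
                if pd.notna(microbes.loc[i, c]):
                    microbes.loc[i, c] = round(float(microbes.loc[i, c]) + s * dct, 3)
            planted.append(int(i))
    return microbes, sorted(planted)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    out = {
        "spec": truth["spec"],
        "latent_frailty": truth["latent_frailty"],
        "planted_outlier_rows": truth["planted_outlier_rows"],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=1, default=float)


def latent_frailty_frame(truth: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"animal_id": a, "latent_frailty": f}
         for a, f in truth["latent_frailty"].items()]
    )
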