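"""Domain types, configuration and CSV input/output for frailty cohorts.

A cohort is stored as up to four normalised CSV tables keyed by ``animal_id``:

``animals.csv``
    animal_id, genotype, sex, age_months, body_weight_g
``items.csv``
    animal_id, item_name, score [, left_successes, right_successes, responses]
``trials.csv``
    animal_id, task, trial_index, outcome, value
``microbes.csv``
    animal_id, group_name, kind, plus kind-specific columns (see
    :mod:`frailmicro.microbiota`); qPCR rows reference ``curves.csv``.

All files are comma-separated UTF-8 with a header row and "." as the decimal
separator.  Validation is total: every malformed row raises
:class:`CohortValidationError` naming the offending row; nothing is silently
coerced.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("frailmicro")

ITEM_SCORES = (0.0, 0.5, 1.0)


class Genotype(str, enum.Enum):
    """Genotype of an animal: non-transgenic littermate or 5xFAD transgenic."""

    wildtype = "wildtype"
    tg5xFAD = "5xFAD"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a documented invariant."""


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's metadata; ``animal_id`` is the join key for all tables."""

    animal_id: str
    genotype: Genotype
    sex: Sex
    age_months: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if not self.age_months > 0:
            raise CohortValidationError(
                f"animal {self.animal_id!r}: age must be > 0 months, got {self.age_months}"
            )
        if not self.body_weight_g > 0:
            raise CohortValidationError(
                f"animal {self.animal_id!r}: body weight must be > 0 g, got {self.body_weight_g}"
            )


@dataclass(frozen=True)
class ItemObservation:
    """One physical-examination item for one animal.

    ``score`` uses the three-level deficit scale: 0 severe deficit, 0.5 mild
    deficit, 1 no deficit.  ``raw`` optionally carries the task-specific trial
    outcome (e.g. orienting-response counts) from which the score was derived.
    """

    animal_id: str
    item_name: str
    score: float
    raw: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.score not in ITEM_SCORES:
            raise CohortValidationError(
                f"animal {self.animal_id!r}, item {self.item_name!r}: "
                f"score {self.score} not in allowed set {{0, 0.5, 1}}"
            )


@dataclass(frozen=True)
class MicrobeMeasure:
    """One bacterial group's abundance for one animal, per gram of faeces."""

    animal_id: str
    group_name: str
    value: float
    unit: str  # "cfu_per_g" or "bacteria_per_g"
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.unit not in ("cfu_per_g", "bacteria_per_g"):
            raise CohortValidationError(
                f"animal {self.animal_id!r}: unknown abundance unit {self.unit!r}"
            )
        if not self.below_detection and self.value < 0:
            raise CohortValidationError(
                f"animal {self.animal_id!r}, group {self.group_name!r}: "
                f"abundance must be >= 0, got {self.value}"
            )


@dataclass
class Config:
    """Analysis thresholds.  Defaults follow the study design they encode.

    control_max_age
        Upper age (months) of the young wild-type reference group used to
        normalise both component scores.
    screen_alpha
        Two-sided p threshold of the wild-type age-correlation screen that
        decides which behavioural tasks enter the musculoskeletal score.
    rout_Q
        False-discovery rate (percent) of the ROUT outlier removal applied to
        every regression; 0 disables the outlier stage entirely.
    aged_cutoff
        Age (months) above which an animal counts as "old" for the aged-subset
        genotype comparisons.
    min_group_n / min_evaluable_n
        Minimum animals per genotype for an aged-subset t-test, and minimum
        evaluable (detected) samples per genotype for a bacterial group to be
        kept in the association panel.
    """

    control_max_age: float = 6.0
    screen_alpha: float = 0.05
    rout_Q: float = 1.0
    aged_cutoff: float = 10.0
    min_group_n: int = 9
    min_evaluable_n: int = 9
    sig_alpha: float = 0.05
    penetrance_by_genotype: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.screen_alpha < 1:
            raise CohortValidationError(f"screen_alpha must be in (0, 1), got {self.screen_alpha}")
        if not 0 <= self.rout_Q < 100:
            raise CohortValidationError(f"rout_Q must be in [0, 100), got {self.rout_Q}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CohortValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class Cohort:
    """A validated, joined collection of the four record tables.

    ``items``, ``trials``, ``microbes`` and ``curves`` may be empty frames when
    the corresponding file is absent; ``animals`` is always present.
    """

    animals: pd.DataFrame
    items: pd.DataFrame = field(default_factory=pd.DataFrame)
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)
    microbes: pd.DataFrame = field(default_factory=pd.DataFrame)
    curves: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def animal_ids(self) -> list[str]:
        return list(self.animals["animal_id"])

    def animal(self, animal_id: str) -> AnimalRecord:
        row = self.animals.loc[self.animals["animal_id"] == animal_id]
        if row.empty:
            raise KeyError(animal_id)
        r = row.iloc[0]
        return AnimalRecord(
            animal_id=r["animal_id"],
            genotype=Genotype(r["genotype"]),
            sex=Sex(r["sex"]),
            age_months=float(r["age_months"]),
            body_weight_g=float(r["body_weight_g"]),
        )


# ---------------------------------------------------------------------------
# readers

_ANIMAL_COLUMNS = ["animal_id", "genotype", "sex", "age_months", "body_weight_g"]
_TRIAL_OUTCOMES = {"fell", "reached_end", "held_full", "measured"}


def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{name}: missing required columns {missing}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal_id": str}, encoding="utf-8")


def read_animals(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, _ANIMAL_COLUMNS, "animals")
    dupes = df["animal_id"][df["animal_id"].duplicated()].tolist()
    if dupes:
        raise CohortValidationError(f"animals: duplicate animal_id {sorted(set(dupes))}")
    valid_geno = {g.value for g in Genotype}
    valid_sex = {s.value for s in Sex}
    for idx, row in df.iterrows():
        if row["genotype"] not in valid_geno:
            raise CohortValidationError(
                f"animals row {idx} (animal {row['animal_id']!r}): unknown genotype "
                f"{row['genotype']!r}; allowed {sorted(valid_geno)}"
            )
        if row["sex"] not in valid_sex:
            raise CohortValidationError(
                f"animals row {idx} (animal {row['animal_id']!r}): unknown sex "
                f"{row['sex']!r}; allowed {sorted(valid_sex)}"
            )
        # constructing the record runs the range invariants
        AnimalRecord(
            row["animal_id"], Genotype(row["genotype"]), Sex(row["sex"]),
            float(row["age_months"]), float(row["body_weight_g"]),
        )
    return df.reset_index(drop=True)


def read_items(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["animal_id", "item_name"], "items")
    if "score" not in df.columns:
        df["score"] = np.nan
    for idx, row in df.iterrows():
        s = row["score"]
        if pd.notna(s) and float(s) not in ITEM_SCORES:
            raise CohortValidationError(
                f"items row {idx} (animal {row['animal_id']!r}, item {row['item_name']!r}): "
                f"score {s} not in allowed set {{0, 0.5, 1}}"
            )
    return df.reset_index(drop=True)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["animal_id", "task", "trial_index", "outcome", "value"], "trials")
    bad = ~df["outcome"].isin(_TRIAL_OUTCOMES)
    if bad.any():
        idx = int(df.index[bad][0])
        raise CohortValidationError(
            f"trials row {idx}: unknown outcome {df.loc[idx, 'outcome']!r}; "
            f"allowed {sorted(_TRIAL_OUTCOMES)}"
        )
    return df.reset_index(drop=True)


def read_microbes(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["animal_id", "group_name", "kind"], "microbes")
    bad = ~df["kind"].isin({"plate", "qpcr", "value"})
    if bad.any():
        idx = int(df.index[bad][0])
        raise CohortValidationError(
            f"microbes row {idx}: unknown kind {df.loc[idx, 'kind']!r}; "
            "allowed ['plate', 'qpcr', 'value']"
        )
    return df.reset_index(drop=True)


def read_curves(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    _require_columns(df, ["curve_id", "slope", "intercept", "per_gram_factor"], "curves")
    if (df["slope"] >= 0).any():
        idx = int(df.index[df["slope"] >= 0][0])
        raise CohortValidationError(
            f"curves row {idx} (curve {df.loc[idx, 'curve_id']!r}): "
            "standard-curve slope must be negative (Ct per log10 copies)"
        )
    return df


def _check_refs(df: pd.DataFrame, known_ids: set[str], table: str) -> None:
    unknown = set(df["animal_id"]) - known_ids
    if unknown:
        raise CohortValidationError(
            f"{table}: animal_id {sorted(unknown)} not present in animals table"
        )


def read_cohort(
    animals_path: str | Path,
    items_path: str | Path | None = None,
    trials_path: str | Path | None = None,
    microbes_path: str | Path | None = None,
    curves_path: str | Path | None = None,
) -> Cohort:
    """Read and cross-validate a cohort from its CSV tables.

    Optional tables may be ``None`` or missing files; every present row must
    reference a known animal.
    """
    animals = read_animals(animals_path)
    ids = set(animals["animal_id"])

    def _opt(reader, p):
        if p is None or not Path(p).exists():
            return pd.DataFrame()
        return reader(p)

    items = _opt(read_items, items_path)
    trials = _opt(read_trials, trials_path)
    microbes = _opt(read_microbes, microbes_path)
    curves = _opt(read_curves, curves_path)
    for df, name in ((items, "items"), (trials, "trials"), (microbes, "microbes")):
        if not df.empty:
            _check_refs(df, ids, name)
    return Cohort(animals=animals, items=items, trials=trials, microbes=microbes, curves=curves)


def read_cohort_dir(directory: str | Path) -> Cohort:
    """Read a cohort from a directory holding the standard file names."""
    d = Path(directory)
    return read_cohort(
        d / "animals.csv", d / "items.csv", d / "trials.csv",
        d / "microbes.csv", d / "curves.csv",
    )


# ---------------------------------------------------------------------------
# writers

def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.animals.to_csv(d / "animals.csv", index=False)
    for df, name in (
        (cohort.items, "items.csv"),
        (cohort.trials, "trials.csv"),
        (cohort.microbes, "microbes.csv"),
        (cohort.curves, "curves.csv"),
    ):
        if df is not None and not df.empty:
            df.to_csv(d / name, index=False, float_format="%.12g")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write association results to CSV, one row per (measure, axis, genotype).

    Refuses an empty collection: an empty results file is indistinguishable
    from a failed run.
    """
    if results is None or len(results) == 0:
        raise ValueError("refusing to write empty association results")
    results.to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
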