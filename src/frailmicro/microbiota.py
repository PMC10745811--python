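"""Microbiota quantification: viable counts from agar plates and absolute
qPCR abundances, plus panel-level derived quantities.

Plate counts come from faeces suspended in saline at 100 uL per mg of faeces;
a known volume of the suspension is plated and colonies are counted from the
whole plate or a representative area fraction.  qPCR samples carry up to
three replicate Ct values that are converted to copies through a per-target
standard curve (Ct = intercept + slope * log10 copies, slope < 0) and scaled
to bacteria per gram wet weight by a per-target conversion factor.  Samples
whose replicates all failed to amplify are below the detection limit and are
excluded from associations, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import Cohort, Config, Genotype, MicrobeMeasure
from .stats import ttest_unpaired

log = logging.getLogger("frailmicro")

#: suspension recipe: 100 uL of saline per mg faeces -> 0.1 mL per mg
SUSPENSION_ML_PER_MG = 0.1


@dataclass(frozen=True)
class PlateCount:
    """Raw colony count with its plating metadata."""

    animal_id: str
    group_name: str
    colonies: float
    faeces_mass_mg: float
    plated_volume_ml: float
    counted_area_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError(f"colonies must be >= 0, got {self.colonies}")
        if not self.faeces_mass_mg > 0:
            raise ValueError(f"faeces mass must be > 0 mg, got {self.faeces_mass_mg}")
        if not self.plated_volume_ml > 0:
            raise ValueError(f"plated volume must be > 0 mL, got {self.plated_volume_ml}")
        if not 0 < self.counted_area_fraction <= 1:
            raise ValueError(
                f"counted_area_fraction must be in (0, 1], got {self.counted_area_fraction}"
            )


@dataclass(frozen=True)
class StandardCurve:
    """qPCR standard curve: Ct = intercept + slope * log10(copies)."""

    slope: float       # Ct per log10 copies, negative
    intercept: float   # Ct at 1 copy
    per_gram_factor: float  # copies -> bacteria per gram wet weight

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")
        if not self.per_gram_factor > 0:
            raise ValueError(f"per_gram_factor must be > 0, got {self.per_gram_factor}")


@dataclass(frozen=True)
class QpcrMeasure:
    """Replicate Ct values for one target in one sample; ``None`` entries are
    undetermined (no amplification)."""

    animal_id: str
    group_name: str
    ct_values: tuple[Optional[float], ...]
    curve: StandardCurve


def cfu_per_gram(pc: PlateCount) -> MicrobeMeasure:
    """Colony count scaled to CFU per gram of faeces.

    The whole-plate-equivalent count is colonies / counted_area_fraction; the
    suspension totals 0.1 mL per mg of faeces, so the per-gram count is the
    whole-plate count times (total suspension / plated volume) divided by the
    faecal mass in grams.  Zero colonies is a legal measurement of zero, not a
    detection failure.
    """
    total_ml = SUSPENSION_ML_PER_MG * pc.faeces_mass_mg
    whole_plate = pc.colonies / pc.counted_area_fraction
    value = whole_plate * (total_ml / pc.plated_volume_ml) / (pc.faeces_mass_mg / 1000.0)
    return MicrobeMeasure(
        animal_id=pc.animal_id, group_name=pc.group_name,
        value=float(value), unit="cfu_per_g", below_detection=False,
    )


def qpcr_quantify(qm: QpcrMeasure) -> MicrobeMeasure:
    """Mean-of-replicates absolute quantification against the standard curve.

    Per determined replicate, copies = 10 ** ((ct - intercept) / slope); the
    sample value is the replicate mean times the per-gram conversion.  A
    sample with no determined replicate is flagged below detection.
    """
    determined = [c for c in qm.ct_values if c is not None and math.isfinite(c)]
    if not determined:
        log.info(
            "qpcr: animal %s group %s below detection (no replicate amplified)",
            qm.animal_id, qm.group_name,
        )
        return MicrobeMeasure(
            animal_id=qm.animal_id, group_name=qm.group_name,
            value=float("nan"), unit="bacteria_per_g", below_detection=True,
        )
    copies = [10.0 ** ((ct - qm.curve.intercept) / qm.curve.slope) for ct in determined]
    value = float(np.mean(copies)) * qm.curve.per_gram_factor
    return MicrobeMeasure(
        animal_id=qm.animal_id, group_name=qm.group_name,
        value=value, unit="bacteria_per_g", below_detection=False,
    )


def quantify_cohort(cohort: Cohort) -> pd.DataFrame:
    """Convert every raw microbe row of a cohort to a per-gram abundance.

    Returns a long frame with columns animal_id, group_name, value, unit,
    below_detection.  Rows of kind "value" pass through unchanged.
    """
    if cohort.microbes.empty:
        return pd.DataFrame(
            columns=["animal_id", "group_name", "value", "unit", "below_detection"]
        )
    curves = {}
    if not cohort.curves.empty:
        for _, c in cohort.curves.iterrows():
            curves[c["curve_id"]] = StandardCurve(
                slope=float(c["slope"]), intercept=float(c["intercept"]),
                per_gram_factor=float(c["per_gram_factor"]),
            )
    out = []
    for idx, row in cohort.microbes.iterrows():
        kind = row["kind"]
        if kind == "plate":
            m = cfu_per_gram(PlateCount(
                animal_id=row["animal_id"], group_name=row["group_name"],
                colonies=float(row["colonies"]),
                faeces_mass_mg=float(row["faeces_mass_mg"]),
                plated_volume_ml=float(row["plated_volume_ml"]),
                counted_area_fraction=float(row.get("counted_area_fraction", 1.0)),
            ))
        elif kind == "qpcr":
            curve_id = row["curve_id"]
            if curve_id not in curves:
                raise ValueError(
                    f"microbes row {idx}: unknown standard curve {curve_id!r}"
                )
            cts = tuple(
                float(row[c]) if pd.notna(row.get(c)) else None
                for c in ("ct1", "ct2", "ct3")
            )
            m = qpcr_quantify(QpcrMeasure(
                animal_id=row["animal_id"], group_name=row["group_name"],
                ct_values=cts, curve=curves[curve_id],
            ))
        else:  # precomputed value
            below = bool(row.get("below_detection", False))
            m = MicrobeMeasure(
                animal_id=row["animal_id"], group_name=row["group_name"],
                value=float(row["value"]) if not below else float("nan"),
                unit=row["unit"], below_detection=below,
            )
        out.append({
            "animal_id": m.animal_id, "group_name": m.group_name,
            "value": m.value, "unit": m.unit, "below_detection": m.below_detection,
        })
    return pd.DataFrame(out)


def detection_filter(
    measures: pd.DataFrame, animals: pd.DataFrame, min_evaluable_n: int = 9
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop bacterial groups with too few evaluable samples in either genotype.

    A sample is evaluable when it is not below the detection limit.  Returns
    (kept measures, decision table).  ``min_evaluable_n = 0`` disables the
    filter.
    """
    geno = dict(zip(animals["animal_id"], animals["genotype"]))
    decisions = []
    keep_groups = []
    for name, grp in measures.groupby("group_name"):
        ok = grp[~grp["below_detection"]]
        counts = {
            g.value: int((ok["animal_id"].map(geno) == g.value).sum()) for g in Genotype
        }
        kept = all(c >= min_evaluable_n for c in counts.values())
        decisions.append({
            "group_name": name,
            "evaluable_wildtype": counts[Genotype.wildtype.value],
            "evaluable_5xFAD": counts[Genotype.tg5xFAD.value],
            "kept": kept,
        })
        if kept:
            keep_groups.append(name)
        else:
            log.info(
                "detection filter: group %s dropped (evaluable n %s < %d in a genotype)",
                name, counts, min_evaluable_n,
            )
    kept_df = measures[measures["group_name"].isin(keep_groups)].reset_index(drop=True)
    return kept_df, pd.DataFrame(decisions)


def bf_ratio(bacteroidetes: float, firmicutes: float) -> float:
    """Bacteroidetes / Firmicutes abundance ratio."""
    if not firmicutes > 0:
        raise ValueError(f"Firmicutes abundance must be > 0, got {firmicutes}")
    if bacteroidetes < 0:
        raise ValueError(f"Bacteroidetes abundance must be >= 0, got {bacteroidetes}")
    return bacteroidetes / firmicutes


def add_bf_ratio(measures: pd.DataFrame) -> pd.DataFrame:
    """Append a per-animal Bacteroidetes/Firmicutes ratio pseudo-measure.

    Animals where either phylum is missing or below detection, or Firmicutes
    is zero, get no ratio (logged).
    """
    wide = measures[~measures["below_detection"]].pivot_table(
        index="animal_id", columns="group_name", values="value", aggfunc="first"
    )
    rows = []
    if "Bacteroidetes" in wide.columns and "Firmicutes" in wide.columns:
        for aid, row in wide.iterrows():
            b, f = row.get("Bacteroidetes"), row.get("Firmicutes")
            if pd.isna(b) or pd.isna(f) or not f > 0:
                log.info("bf_ratio: animal %s missing a phylum or zero Firmicutes; skipped", aid)
                continue
            rows.append({
                "animal_id": aid, "group_name": "BF_ratio",
                "value": bf_ratio(float(b), float(f)), "unit": "ratio",
                "below_detection": False,
            })
    return pd.concat([measures, pd.DataFrame(rows)], ignore_index=True)


def aged_subset_compare(
    measures: pd.DataFrame,
    animals: pd.DataFrame,
    aged_cutoff: float = 10.0,
    min_group_n: int = 9,
) -> pd.DataFrame:
    """Genotype comparison of each measure in the old (> aged_cutoff months)
    sub-cohort.

    Measures where either genotype has fewer than ``min_group_n`` evaluable
    old animals are skipped (logged).  Each kept row carries the unpaired
    two-sided t-test of the measure between genotypes plus the group mean
    ages and the age t-test p (the groups should not differ in age).
    """
    meta = animals.set_index("animal_id")
    old_ids = set(meta.index[meta["age_months"] > aged_cutoff])
    rows = []
    for name, grp in measures.groupby("group_name"):
        sub = grp[~grp["below_detection"] & grp["animal_id"].isin(old_ids)].dropna(
            subset=["value"]
        )
        by_geno = {
            g.value: sub[sub["animal_id"].map(meta["genotype"]) == g.value]
            for g in Genotype
        }
        ns = {g: len(d) for g, d in by_geno.items()}
        if any(n < min_group_n for n in ns.values()):
            log.info(
                "aged comparison: measure %s skipped (old-animal n %s < %d)",
                name, ns, min_group_n,
            )
            continue
        wt = by_geno[Genotype.wildtype.value]
        tg = by_geno[Genotype.tg5xFAD.value]
        t, p = ttest_unpaired(wt["value"], tg["value"])
        ages_wt = meta.loc[wt["animal_id"], "age_months"]
        ages_tg = meta.loc[tg["animal_id"], "age_months"]
        _, age_p = ttest_unpaired(ages_wt, ages_tg)
        rows.append({
            "group_name": name,
            "n_wildtype": ns[Genotype.wildtype.value],
            "n_5xFAD": ns[Genotype.tg5xFAD.value],
            "mean_wildtype": float(wt["value"].mean()),
            "mean_5xFAD": float(tg["value"].mean()),
            "t": t, "p": p,
            "mean_age_wildtype": float(ages_wt.mean()),
            "mean_age_5xFAD": float(ages_tg.mean()),
            "age_p": age_p,
        })
    return pd.DataFrame(rows)


def aged_subset_from_config(
    measures: pd.DataFrame, animals: pd.DataFrame, config: Config
) -> pd.DataFrame:
    return aged_subset_compare(
        measures, animals, aged_cutoff=config.aged_cutoff, min_group_n=config.min_group_n
    )
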