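"""Physical-constitution scoring.

Each of up to 20 examination items is scored 0 (severe deficit), 0.5 (mild
deficit) or 1 (no deficit).  Two items carry bespoke rules implemented here
(visual placing, hearing); all other items — coat condition, alopecia,
cataracts, adiposity, kyphosis, and so on — are ingested as pre-assigned
scores.

An item's *penetrance* is the fraction of animals affected by it (score 0 or
0.5).  The physical constitution score (Pcs) is the penetrance-weighted mean
item score expressed as a percentage of the young wild-type control mean, so
items nobody is affected by drop out with weight 0 and an animal at the
control mean scores exactly 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Cohort, Config, Genotype, ITEM_SCORES

log = logging.getLogger("frailmicro")


def score_visual_placing(left_successes: int, right_successes: int) -> float:
    """Score the visual placing response from 2 trials per side.

    1 for 4/4 orienting trunk rotations; 0.5 for 3/4 or at least one response
    per side; 0 for no response, a response on one side only, or a single
    response in total.
    """
    for name, v in (("left_successes", left_successes), ("right_successes", right_successes)):
        if v not in (0, 1, 2):
            raise ValueError(f"{name} must be an integer in 0..2, got {v!r}")
    total = left_successes + right_successes
    if total == 4:
        return 1.0
    if total == 3 or (left_successes >= 1 and right_successes >= 1):
        return 0.5
    return 0.0


def score_hearing(responses: int) -> float:
    """Score the click-box hearing test from 3 trials: 1 for 3/3 responses,
    0.5 for 1 or 2, 0 for none."""
    if responses not in (0, 1, 2, 3):
        raise ValueError(f"responses must be an integer in 0..3, got {responses!r}")
    if responses == 3:
        return 1.0
    if responses >= 1:
        return 0.5
    return 0.0


def apply_item_rules(items: pd.DataFrame) -> pd.DataFrame:
    """Fill missing scores from raw trial columns where a bespoke rule exists.

    Rows that already carry a score are left untouched.  Returns a copy with a
    complete, validated ``score`` column.
    """
    out = items.copy()
    for idx, row in out.iterrows():
        if pd.notna(row.get("score")):
            continue
        name = row["item_name"]
        if name == "visual_placing":
            out.loc[idx, "score"] = score_visual_placing(
                int(row["left_successes"]), int(row["right_successes"])
            )
        elif name == "hearing":
            out.loc[idx, "score"] = score_hearing(int(row["responses"]))
        else:
            raise ValueError(
                f"items row {idx} (animal {row['animal_id']!r}): no score and no "
                f"scoring rule for item {name!r}"
            )
    out["score"] = out["score"].astype(float)
    bad = ~out["score"].isin(ITEM_SCORES)
    if bad.any():
        idx = int(out.index[bad][0])
        raise ValueError(
            f"items row {idx}: score {out.loc[idx, 'score']} not in allowed set {{0, 0.5, 1}}"
        )
    return out


def compute_penetrance(
    items: pd.DataFrame,
    item_name: str,
    genotype_filter: str | Genotype | None = None,
    animals: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Fraction (and percent) of animals affected by one item.

    Affected means score < 1, i.e. 0 or 0.5.  By default computed over all
    scored animals regardless of genotype, sex or age; pass
    ``genotype_filter`` (requires ``animals``) to restrict, e.g. for the
    per-genotype incidence heatmap.
    """
    sub = items[items["item_name"] == item_name]
    if genotype_filter is not None:
        if animals is None:
            raise ValueError("genotype_filter requires the animals table")
        gv = Genotype(genotype_filter).value
        ids = set(animals.loc[animals["genotype"] == gv, "animal_id"])
        sub = sub[sub["animal_id"].isin(ids)]
    if sub.empty:
        raise ValueError(f"no observations of item {item_name!r} in scope")
    scores = sub["score"].astype(float)
    frac = float((scores < 1).sum() / len(scores))
    return frac, 100.0 * frac


def penetrance_table(
    items: pd.DataFrame,
    genotype_filter: str | Genotype | None = None,
    animals: pd.DataFrame | None = None,
) -> pd.Series:
    """Penetrance fraction for every observed item (index: item_name)."""
    names = sorted(items["item_name"].unique())
    return pd.Series(
        {n: compute_penetrance(items, n, genotype_filter, animals)[0] for n in names},
        name="fraction_affected",
    )


def penetrance_heatmap(items: pd.DataFrame, animals: pd.DataFrame) -> pd.DataFrame:
    """Percent of animals affected per item and genotype (incidence heatmap)."""
    cols = {}
    for g in Genotype:
        cols[g.value] = pd.Series(
            {
                n: compute_penetrance(items, n, g, animals)[1]
                for n in sorted(items["item_name"].unique())
            }
        )
    return pd.DataFrame(cols)


def pc_raw(animal_items: dict[str, float], penetrance: pd.Series, n_items: int) -> float:
    """Penetrance-weighted mean item score: sum_n f_n * s_n / n_items.

    ``n_items`` is the number of parameters observed, held constant across
    animals within one run; items with penetrance 0 contribute nothing, which
    is how a 20-item panel collapses to the subset actually expressed in the
    colony.
    """
    if n_items <= 0:
        raise ValueError("n_items must be positive")
    total = 0.0
    for name, score in animal_items.items():
        if name not in penetrance.index:
            raise ValueError(f"item {name!r} missing from penetrance table")
        total += float(penetrance[name]) * float(score)
    return total / n_items


def pc_score(animal_raw: float, control_raw_mean: float) -> float:
    """Express an animal's raw weighted mean as percent of the control mean."""
    if not control_raw_mean > 0:
        raise ValueError(
            f"degenerate control group: control raw mean must be > 0, got {control_raw_mean}"
        )
    return 100.0 * animal_raw / control_raw_mean


@dataclass
class PcResult:
    penetrance: pd.Series          # item -> fraction affected
    n_items: int
    control_ids: list[str]
    control_raw_mean: float
    scores: pd.DataFrame           # animal_id, pc_raw, pcs


def compute_pc_scores(cohort: Cohort, config: Config) -> PcResult:
    """Full Pc pipeline: rule application, penetrance, control mean, scores.

    The reference group is every wild-type animal aged at most
    ``config.control_max_age`` months — the sub-cohort assumed not yet to show
    ageing.  Animals with no item observations receive a missing Pcs.
    """
    items = apply_item_rules(cohort.items)
    animals = cohort.animals
    pen = penetrance_table(
        items,
        genotype_filter=None if not config.penetrance_by_genotype else Genotype.wildtype,
        animals=animals,
    )
    n_items = int(items["item_name"].nunique())

    per_animal_raw = {}
    for aid, grp in items.groupby("animal_id"):
        scores = dict(zip(grp["item_name"], grp["score"].astype(float)))
        per_animal_raw[aid] = pc_raw(scores, pen, n_items)

    ctrl = animals[
        (animals["genotype"] == Genotype.wildtype.value)
        & (animals["age_months"] <= config.control_max_age)
    ]
    control_ids = [a for a in ctrl["animal_id"] if a in per_animal_raw]
    if not control_ids:
        raise ValueError(
            "empty control group: no scored wild-type animals aged "
            f"<= {config.control_max_age} months"
        )
    control_raw_mean = float(np.mean([per_animal_raw[a] for a in control_ids]))

    rows = []
    for aid in animals["animal_id"]:
        raw = per_animal_raw.get(aid)
        if raw is None:
            log.info("pc: animal %s has no item observations; Pcs missing", aid)
            rows.append({"animal_id": aid, "pc_raw": np.nan, "pcs": np.nan})
        else:
            rows.append({"animal_id": aid, "pc_raw": raw, "pcs": pc_score(raw, control_raw_mean)})
    return PcResult(
        penetrance=pen, n_items=n_items, control_ids=control_ids,
        control_raw_mean=control_raw_mean, scores=pd.DataFrame(rows),
    )
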