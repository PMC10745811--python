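"""Association analysis: each microbial measure (and the B/F ratio) against
chronological age and against the frailty score, within each genotype.

Per (measure, axis, genotype) cell the pipeline removes regression outliers
with ROUT at the configured Q, then computes the Pearson correlation and the
least-squares fit on the cleaned data; per (measure, axis) it tests equality
of the two genotype slopes with the ANCOVA interaction F-test.  Cells with
too few animals are emitted as missing with a reason, never dropped silently.

The summary renders the cell grid as direction glyphs: an up or down arrow for
a significant positive or negative correlation, "-" for none, and "+" where
the genotype slopes differ significantly — a compact significance table over
the whole panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Config, Genotype
from .stats import DegenerateDataError, linfit_ci, pearson_test, rout_outliers

log = logging.getLogger("frailmicro")

AXES = ("age", "frailty")

#: cosmetic panel order for reports; unknown measures follow alphabetically
PANEL_ORDER = (
    "Akkermansia_muciniphila", "Bifidobacterium", "Bacteroides", "Bacteroidetes",
    "Firmicutes", "Lactobacilli_Enterococci", "Lactobacillaceae",
    "Enterobacteriaceae", "Schaedler", "BF_ratio",
)


@dataclass
class AssociationTable:
    """Long results table plus the slope-difference column, one row per cell."""

    results: pd.DataFrame


def _panel_sort_key(name: str) -> tuple[int, str]:
    try:
        return (PANEL_ORDER.index(name), name)
    except ValueError:
        return (len(PANEL_ORDER), name)


def _axis_values(scores: pd.DataFrame, axis: str) -> pd.Series:
    col = {"age": "age_months", "frailty": "frailty"}[axis]
    return scores.set_index("animal_id")[col]


def correlate_panel(
    measures: pd.DataFrame,
    scores: pd.DataFrame,
    config: Config | None = None,
) -> AssociationTable:
    """Run the full (measure x axis x genotype) correlation panel.

    ``measures`` is the long abundance frame (animal_id, group_name, value,
    unit, below_detection); ``scores`` the per-animal score table carrying
    genotype, age_months and frailty.  Below-detection and missing values are
    excluded per cell, with the exclusion reflected in ``n_used``.
    Deterministic given inputs and config: ROUT is a deterministic procedure.
    """
    config = config or Config()
    geno_of = scores.set_index("animal_id")["genotype"]
    rows = []
    measure_names = sorted(measures["group_name"].unique(), key=_panel_sort_key)
    for name in measure_names:
        grp = measures[measures["group_name"] == name]
        for axis in AXES:
            axis_vals = _axis_values(scores, axis)
            cleaned: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for g in Genotype:
                sub = grp[grp["animal_id"].map(geno_of) == g.value]
                n_total = len(sub)
                sub = sub[~sub["below_detection"]].dropna(subset=["value"])
                x = sub["animal_id"].map(axis_vals)
                ok = x.notna()
                n_missing = n_total - int(ok.sum())
                x = x[ok].to_numpy(dtype=float)
                y = sub.loc[ok, "value"].to_numpy(dtype=float)
                rec = {
                    "measure_name": name, "axis": axis, "genotype": g.value,
                    "n_used": 0, "n_outliers_removed": 0, "n_missing": n_missing,
                    "r": np.nan, "p_r": np.nan, "slope": np.nan, "intercept": np.nan,
                    "slope_se": np.nan, "slope_diff_p": np.nan, "reason": "",
                }
                if x.size < 5:
                    rec["reason"] = f"insufficient n after filtering (n = {x.size})"
                    log.info("panel: %s/%s/%s skipped (%s)", name, axis, g.value, rec["reason"])
                    rows.append(rec)
                    continue
                if config.rout_Q == 0:  # outlier stage disabled
                    flagged, xc, yc = np.array([], dtype=int), x, y
                else:
                    report, xc, yc = rout_outliers(x, y, Q=config.rout_Q)
                    flagged = report.flagged_indices
                for idx in flagged:
                    log.info(
                        "panel: %s/%s/%s outlier removed (x = %g, y = %g)",
                        name, axis, g.value, x[idx], y[idx],
                    )
                try:
                    fit = linfit_ci(xc, yc)
                    r, p_r = fit.r, fit.p_r
                    rec.update(
                        n_used=int(xc.size),
                        n_outliers_removed=int(flagged.size),
                        r=r, p_r=p_r, slope=fit.slope, intercept=fit.intercept,
                        slope_se=fit.slope_se,
                    )
                    cleaned[g.value] = (xc, yc)
                except DegenerateDataError as exc:
                    rec["reason"] = f"degenerate data ({exc})"
                    log.info("panel: %s/%s/%s skipped (%s)", name, axis, g.value, rec["reason"])
                rows.append(rec)
            if len(cleaned) == 2:
                from .stats import compare_slopes

                xa, ya = cleaned[Genotype.wildtype.value]
                xb, yb = cleaned[Genotype.tg5xFAD.value]
                try:
                    _, p_diff = compare_slopes(xa, ya, xb, yb)
                except DegenerateDataError:
                    p_diff = np.nan
                for rec in rows[-2:]:
                    rec["slope_diff_p"] = p_diff
    return AssociationTable(results=pd.DataFrame(rows))


GLYPH_UP, GLYPH_DOWN, GLYPH_NONE, GLYPH_DIFF = "↑", "↓", "-", "+"


def _direction(r: float, p: float, alpha: float) -> str:
    if np.isfinite(p) and p < alpha:
        return GLYPH_UP if r > 0 else GLYPH_DOWN
    return GLYPH_NONE


def summarize(table: AssociationTable, alpha: float = 0.05) -> pd.DataFrame:
    """Render the significance grid, one row per measure.

    Columns: per genotype and axis a direction glyph, plus per axis a "+"
    where the genotype slopes differ at ``alpha``.  Every cell maps to exactly
    one association result.
    """
    res = table.results
    rows = []
    for name in sorted(res["measure_name"].unique(), key=_panel_sort_key):
        sub = res[res["measure_name"] == name]
        rec = {"measure_name": name}
        for g in Genotype:
            for axis in AXES:
                cell = sub[(sub["genotype"] == g.value) & (sub["axis"] == axis)]
                if cell.empty or not np.isfinite(cell.iloc[0]["p_r"]):
                    glyph = GLYPH_NONE
                else:
                    glyph = _direction(cell.iloc[0]["r"], cell.iloc[0]["p_r"], alpha)
                rec[f"{'wt' if g is Genotype.wildtype else '5xFAD'}_{axis}"] = glyph
        for axis in AXES:
            cell = sub[sub["axis"] == axis]
            p_diff = cell["slope_diff_p"].dropna()
            flag = bool(len(p_diff) and p_diff.iloc[0] < alpha)
            rec[f"diff_{axis}"] = GLYPH_DIFF if flag else ""
        rows.append(rec)
    return pd.DataFrame(rows)


def render_summary_markdown(summary: pd.DataFrame) -> str:
    cols = ["measure_name", "wt_age", "wt_frailty", "5xFAD_age", "5xFAD_frailty",
            "diff_age", "diff_frailty"]
    head = "| " + " | ".join(cols) + " |"
    sep = "|" + "|".join("---" for _ in cols) + "|"
    lines = [head, sep]
    for _, row in summary.iterrows():
        lines.append("| " + " | ".join(str(row[c]) if row[c] != "" else " " for c in cols) + " |")
    return "\n".join(lines) + "\n"


def stratify(
    measures: pd.DataFrame,
    scores: pd.DataFrame,
    by: str = "sex",
    config: Config | None = None,
) -> pd.DataFrame:
    """Run the panel separately per stratum of sex, genotype or both.

    Small strata (fewer than 3 usable animals everywhere) are skipped with a
    log line.  For ``by='sex'`` the frame also carries, per (measure, axis,
    genotype), the p-value for equality of the female and male regression
    slopes — the sex-difference question for e.g. frailty-vs-age.
    """
    config = config or Config()
    if by not in ("sex", "genotype", "both"):
        raise ValueError(f"unknown stratification {by!r}")
    strata_cols = {"sex": ["sex"], "genotype": ["genotype"], "both": ["sex", "genotype"]}[by]
    frames = []
    for keys, sub_scores in scores.groupby(strata_cols):
        if isinstance(keys, str):
            keys = (keys,)
        if len(sub_scores) < 3:
            log.info("stratify: stratum %s skipped (n = %d < 3)", keys, len(sub_scores))
            continue
        ids = set(sub_scores["animal_id"])
        sub_measures = measures[measures["animal_id"].isin(ids)]
        tab = correlate_panel(sub_measures, sub_scores, config).results
        for col, val in zip(strata_cols, keys):
            tab[f"stratum_{col}"] = val
        frames.append(tab)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    if by == "sex":
        out = _add_sex_slope_comparison(out, measures, scores, config)
    return out


def _add_sex_slope_comparison(
    results: pd.DataFrame, measures: pd.DataFrame, scores: pd.DataFrame, config: Config
) -> pd.DataFrame:
    from .stats import compare_slopes

    results = results.copy()
    results["sex_slope_diff_p"] = np.nan
    geno_of = scores.set_index("animal_id")["genotype"]
    sex_of = scores.set_index("animal_id")["sex"]
    for (name, axis, geno), _ in results.groupby(["measure_name", "axis", "genotype"]):
        grp = measures[measures["group_name"] == name]
        grp = grp[~grp["below_detection"]].dropna(subset=["value"])
        grp = grp[grp["animal_id"].map(geno_of) == geno]
        axis_vals = _axis_values(scores, axis)
        pieces = {}
        for sex in ("female", "male"):
            sub = grp[grp["animal_id"].map(sex_of) == sex]
            x = sub["animal_id"].map(axis_vals)
            ok = x.notna()
            if ok.sum() >= 3:
                pieces[sex] = (
                    x[ok].to_numpy(dtype=float),
                    sub.loc[ok, "value"].to_numpy(dtype=float),
                )
        if len(pieces) == 2:
            try:
                _, p = compare_slopes(*pieces["female"], *pieces["male"])
            except DegenerateDataError:
                p = np.nan
            mask = (
                (results["measure_name"] == name)
                & (results["axis"] == axis)
                & (results["genotype"] == geno)
            )
            results.loc[mask, "sex_slope_diff_p"] = p
    return results


def scores_vs_age(scores: pd.DataFrame, config: Config | None = None) -> AssociationTable:
    """Correlate the three scores (Mfs, Pcs, frailty) against age per genotype.

    Reuses the panel machinery by treating each score as a measure, so ROUT
    and the slope-difference test apply identically — this is the analysis
    that shows accelerated frailty accumulation in the transgenic genotype.
    """
    config = config or Config()
    rows = []
    for col in ("mfs", "pcs", "frailty"):
        sub = scores.dropna(subset=[col])
        for _, row in sub.iterrows():
            rows.append({
                "animal_id": row["animal_id"], "group_name": f"score_{col}",
                "value": float(row[col]), "unit": "percent" if col != "frailty" else "score",
                "below_detection": False,
            })
    pseudo = pd.DataFrame(rows)
    tab = correlate_panel(pseudo, scores, config)
    return AssociationTable(results=tab.results[tab.results["axis"] == "age"].reset_index(drop=True))
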