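import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frailmicro.io_model import Genotype
from frailmicro.microbiota import (
    PlateCount,
    QpcrMeasure,
    StandardCurve,
    add_bf_ratio,
    aged_subset_compare,
    bf_ratio,
    cfu_per_gram,
    detection_filter,
    qpcr_quantify,
    quantify_cohort,
)

PERFECT_CURVE = StandardCurve(slope=-3.3219280948873623, intercept=40.0,
                              per_gram_factor=1.0)


class TestPlateCounts:
    def test_hand_computed_cfu_per_gram(self):
        # 50 mg faeces -> 5 mL suspension; 200 colonies from 1 mL plated
        pc = PlateCount("M1", "Enterobacteriaceae", colonies=200,
                        faeces_mass_mg=50.0, plated_volume_ml=1.0)
        m = cfu_per_gram(pc)
        assert m.value == pytest.approx(20000.0)
        assert m.unit == "cfu_per_g"

    def test_zero_colonies_is_a_zero_not_below_detection(self):
        pc = PlateCount("M1", "Lactobacillaceae", colonies=0,
                        faeces_mass_mg=60.0, plated_volume_ml=1.0)
        m = cfu_per_gram(pc)
        assert m.value == 0.0
        assert not m.below_detection

    def test_partial_plate_count_scales_to_whole_plate(self):
        whole = cfu_per_gram(PlateCount("M1", "L", 200, 50.0, 1.0, 1.0))
        quarter = cfu_per_gram(PlateCount("M1", "L", 50, 50.0, 1.0, 0.25))
        assert quarter.value == pytest.approx(whole.value)

    def test_invalid_area_fraction_rejected(self):
        with pytest.raises(ValueError):
            PlateCount("M1", "L", 10, 50.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            PlateCount("M1", "L", 10, 50.0, 1.0, 1.5)

    @given(c=st.floats(min_value=1.0, max_value=100.0))
    @settings(max_examples=25, derandomize=True)
    def test_homogeneity_in_colonies_and_joint_plating_scale(self, c):
        base = cfu_per_gram(PlateCount("M1", "L", 100, 50.0, 0.5, 1.0)).value
        colonies_scaled = cfu_per_gram(PlateCount("M1", "L", 100 * c, 50.0, 0.5, 1.0)).value
        joint_scaled = cfu_per_gram(
            PlateCount("M1", "L", 100 * c, 50.0, 0.5 * c, 1.0)
        ).value
        assert colonies_scaled == pytest.approx(c * base, rel=1e-12)
        assert joint_scaled == pytest.approx(base, rel=1e-12)


class TestQpcr:
    def test_perfect_efficiency_curve_reproduces_powers_of_two(self):
        # 10 cycles before the single-copy anchor = 2^10 copies
        m = qpcr_quantify(QpcrMeasure("M1", "Bacteroides", (30.0,), PERFECT_CURVE))
        assert m.value == pytest.approx(1024.0, rel=1e-9)

    def test_ct_at_intercept_is_one_copy(self):
        m = qpcr_quantify(QpcrMeasure("M1", "Bacteroides", (40.0,), PERFECT_CURVE))
        assert m.value == pytest.approx(1.0, rel=1e-9)

    @given(ct=st.floats(min_value=15.0, max_value=35.0))
    @settings(max_examples=25, derandomize=True)
    def test_one_cycle_earlier_doubles_copies(self, ct):
        lo = qpcr_quantify(QpcrMeasure("M1", "B", (ct,), PERFECT_CURVE)).value
        hi = qpcr_quantify(QpcrMeasure("M1", "B", (ct - 1.0,), PERFECT_CURVE)).value
        assert hi == pytest.approx(2.0 * lo, rel=1e-9)

    def test_replicates_averaged_on_copy_scale(self):
        single = qpcr_quantify(QpcrMeasure("M1", "B", (30.0,), PERFECT_CURVE)).value
        trip = qpcr_quantify(QpcrMeasure("M1", "B", (30.0, 30.0, 30.0), PERFECT_CURVE))
        assert trip.value == pytest.approx(single)

    def test_all_replicates_undetermined_flags_below_detection(self):
        m = qpcr_quantify(QpcrMeasure("M1", "Prevotella", (None, None, None),
                                      PERFECT_CURVE))
        assert m.below_detection

    def test_positive_curve_slope_rejected(self):
        with pytest.raises(ValueError):
            StandardCurve(slope=3.3, intercept=40.0, per_gram_factor=1.0)

    def test_per_gram_factor_scales_result(self):
        c = StandardCurve(slope=-3.3219280948873623, intercept=40.0,
                          per_gram_factor=1e6)
        m = qpcr_quantify(QpcrMeasure("M1", "B", (30.0,), c))
        assert m.value == pytest.approx(1024.0e6, rel=1e-9)


def _measures(groups):
    rows = []
    for name, per_geno in groups.items():
        for geno, (n_ok, n_bd) in per_geno.items():
            prefix = "WT" if geno == "wildtype" else "TG"
            for i in range(n_ok + n_bd):
                rows.append({
                    "animal_id": f"{prefix}{name[:2]}{i}", "group_name": name,
                    "value": 1e9 if i < n_ok else np.nan, "unit": "bacteria_per_g",
                    "below_detection": i >= n_ok,
                })
    return pd.DataFrame(rows)


def _animals_for(measures):
    ids = measures["animal_id"].unique()
    return pd.DataFrame({
        "animal_id": ids,
        "genotype": ["wildtype" if i.startswith("WT") else "5xFAD" for i in ids],
        "sex": ["female"] * len(ids),
        "age_months": [12.0] * len(ids),
        "body_weight_g": [28.0] * len(ids),
    })


class TestDetectionFilter:
    def test_group_below_threshold_in_one_genotype_is_dropped(self):
        m = _measures({"Prevotella": {"wildtype": (3, 37), "5xFAD": (20, 20)}})
        kept, decisions = detection_filter(m, _animals_for(m), min_evaluable_n=9)
        assert kept.empty
        assert not decisions.iloc[0]["kept"]

    def test_group_with_enough_evaluable_everywhere_is_kept(self):
        m = _measures({"Bacteroides": {"wildtype": (21, 19), "5xFAD": (40, 0)}})
        kept, decisions = detection_filter(m, _animals_for(m), min_evaluable_n=9)
        assert decisions.iloc[0]["kept"]
        assert set(kept["group_name"]) == {"Bacteroides"}

    def test_zero_threshold_disables_the_filter(self):
        m = _measures({"Prevotella": {"wildtype": (1, 39), "5xFAD": (0, 40)}})
        kept, _ = detection_filter(m, _animals_for(m), min_evaluable_n=0)
        assert len(kept) == len(m)


class TestBfRatio:
    def test_simple_ratio(self):
        assert bf_ratio(2e9, 1e9) == pytest.approx(2.0)
        assert bf_ratio(5e8, 5e8) == pytest.approx(1.0)

    def test_zero_firmicutes_is_an_error(self):
        with pytest.raises(ValueError):
            bf_ratio(1e9, 0.0)

    def test_add_bf_ratio_skips_animals_missing_a_phylum(self):
        rows = [
            {"animal_id": "A", "group_name": "Bacteroidetes", "value": 2e9,
             "unit": "bacteria_per_g", "below_detection": False},
            {"animal_id": "A", "group_name": "Firmicutes", "value": 1e9,
             "unit": "bacteria_per_g", "below_detection": False},
            {"animal_id": "B", "group_name": "Bacteroidetes", "value": 2e9,
             "unit": "bacteria_per_g", "below_detection": False},
            {"animal_id": "B", "group_name": "Firmicutes", "value": np.nan,
             "unit": "bacteria_per_g", "below_detection": True},
        ]
        out = add_bf_ratio(pd.DataFrame(rows))
        ratios = out[out["group_name"] == "BF_ratio"]
        assert list(ratios["animal_id"]) == ["A"]
        assert ratios.iloc[0]["value"] == pytest.approx(2.0)


class TestAgedSubset:
    def _cohort_measures(self, rng, tg_factor, n=12, noise=0.05):
        rows, animals = [], []
        for geno, prefix, factor in (("wildtype", "WT", 1.0), ("5xFAD", "TG", tg_factor)):
            for i in range(n):
                aid = f"{prefix}{i}"
                animals.append({"animal_id": aid, "genotype": geno, "sex": "female",
                                "age_months": float(rng.uniform(10.5, 15.5)),
                                "body_weight_g": 28.0})
                rows.append({"animal_id": aid, "group_name": "Bacteroides",
                             "value": factor * 1e9 * (1 + rng.normal(0, noise)),
                             "unit": "bacteria_per_g", "below_detection": False})
        return pd.DataFrame(rows), pd.DataFrame(animals)

    def test_planted_transgenic_deficit_detected(self):
        rng = np.random.default_rng(0)
        measures, animals = self._cohort_measures(rng, tg_factor=0.5)
        res = aged_subset_compare(measures, animals, aged_cutoff=10.0, min_group_n=9)
        row = res.iloc[0]
        assert row["p"] < 0.001
        assert row["mean_5xFAD"] < row["mean_wildtype"]
        assert row["age_p"] > 0.0  # group mean ages reported alongside

    def test_small_group_is_skipped(self):
        rng = np.random.default_rng(1)
        measures, animals = self._cohort_measures(rng, tg_factor=0.5, n=8)
        res = aged_subset_compare(measures, animals, aged_cutoff=10.0, min_group_n=9)
        assert res.empty

    def test_young_animals_are_excluded(self):
        rng = np.random.default_rng(2)
        measures, animals = self._cohort_measures(rng, tg_factor=1.0)
        animals.loc[animals.index[:3], "age_months"] = 5.0
        res = aged_subset_compare(measures, animals, aged_cutoff=10.0, min_group_n=9)
        assert res.iloc[0]["n_wildtype"] == 9

    def test_null_rejection_rate_near_alpha(self):
        """Identical genotype distributions reject at roughly the nominal rate."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 400
        for _ in range(reps):
            measures, animals = self._cohort_measures(rng, tg_factor=1.0, noise=0.2)
            res = aged_subset_compare(measures, animals, 10.0, 9)
            hits += res.iloc[0]["p"] < 0.05
        assert 0.02 <= hits / reps <= 0.09


class TestQuantifyCohort:
    def test_plate_qpcr_and_value_rows_unify(self, default_cohort):
        cohort, _ = default_cohort
        measures = quantify_cohort(cohort)
        assert set(measures.columns) == {"animal_id", "group_name", "value", "unit",
                                         "below_detection"}
        units = measures.groupby("group_name")["unit"].first()
        assert units["Lactobacillaceae"] == "cfu_per_g"
        assert units["Bacteroides"] == "bacteria_per_g"
        # the low-abundance targets produce genuine below-detection samples
        bd = measures[measures["below_detection"]]
        assert set(bd["group_name"]) <= {"Prevotella", "Clostridium_coccoides"}
        assert len(bd) > 20

    def test_unknown_curve_reference_is_an_error(self, default_cohort):
        cohort, _ = default_cohort
        broken = cohort.microbes.copy()
        broken.loc[broken["kind"] == "qpcr", "curve_id"] = "curve_missing"
        cohort2 = type(cohort)(animals=cohort.animals, items=cohort.items,
                               trials=cohort.trials, microbes=broken,
                               curves=cohort.curves)
        with pytest.raises(ValueError, match="curve_missing"):
            quantify_cohort(cohort2)
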