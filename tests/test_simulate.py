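import dataclasses

import numpy as np
import pandas as pd
import pytest

from frailmicro.behaviour import aggregate_cohort_trials
from frailmicro.frailty import score_cohort
from frailmicro.io_model import read_cohort_dir, write_cohort
from frailmicro.microbiota import quantify_cohort
from frailmicro.pipeline import associate_cohort
from frailmicro.simulate import (
    GeneratorSpec,
    ItemModel,
    MicrobeModel,
    TaskModel,
    plant_outliers,
    simulate_cohort,
)
from frailmicro.stats import compare_slopes, linfit_ci, pearson_test, rout_outliers


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        for run in ("a", "b"):
            cohort, _ = simulate_cohort(GeneratorSpec(rng_seed=11))
            write_cohort(cohort, tmp_path / run)
        for name in ("animals.csv", "items.csv", "trials.csv", "microbes.csv",
                     "curves.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = simulate_cohort(GeneratorSpec(rng_seed=1))
        b, _ = simulate_cohort(GeneratorSpec(rng_seed=2))
        assert not a.animals["age_months"].equals(b.animals["age_months"])


class TestSpecValidation:
    def test_invalid_spec_lists_offending_fields(self):
        spec = GeneratorSpec(n_per_genotype=0, sex_balance=1.5,
                             outlier_fraction=0.5)
        with pytest.raises(ValueError) as exc:
            spec.validate()
        msg = str(exc.value)
        assert "n_per_genotype" in msg
        assert "sex_balance" in msg
        assert "outlier_fraction" in msg

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = GeneratorSpec(rng_seed=5)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = GeneratorSpec.from_yaml(tmp_path / "spec.yaml")
        assert dataclasses.asdict(back) == dataclasses.asdict(spec)


class TestCohortStructure:
    def test_design_matches_study_layout(self, default_cohort):
        cohort, _ = default_cohort
        counts = cohort.animals.groupby(["genotype", "sex"]).size()
        assert (counts == 20).all()
        ages = cohort.animals["age_months"]
        assert ages.between(3, 16).all()

    def test_trial_values_respect_recording_rails(self, default_cohort):
        cohort, _ = default_cohort
        agg = aggregate_cohort_trials(cohort)
        cage = agg[agg["task"] == "cage_top"]["mean_value"]
        rope = agg[agg["task"] == "tight_rope"]["mean_value"]
        assert cage.between(10, 60).all()
        assert rope.between(10, 120).all()

    def test_simulated_csv_roundtrip_scores_identically(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        write_cohort(cohort, tmp_path / "c")
        back = read_cohort_dir(tmp_path / "c")
        a = score_cohort(cohort).scores
        b = score_cohort(back).scores
        np.testing.assert_allclose(a["frailty"].dropna(), b["frailty"].dropna(),
                                   rtol=1e-9)

    def test_ground_truth_covers_every_animal(self, default_cohort):
        cohort, truth = default_cohort
        assert set(truth["latent_frailty"]) == set(cohort.animals["animal_id"])
        assert all(v > 0 for v in truth["latent_frailty"].values())

    def test_estimated_frailty_tracks_latent_frailty(self, default_cohort,
                                                     default_scores):
        _, truth = default_cohort
        s = default_scores.scores.set_index("animal_id")
        lat = pd.Series(truth["latent_frailty"])
        both = pd.concat([s["frailty"], lat.rename("lat")], axis=1).dropna()
        assert np.corrcoef(both["frailty"], both["lat"])[0, 1] > 0.9


class TestPlantOutliers:
    def _spec(self, fraction, magnitude, seed=0):
        return GeneratorSpec(outlier_fraction=fraction, outlier_magnitude=magnitude,
                             rng_seed=seed)

    def test_fraction_of_qpcr_rows_displaced_and_recovered(self):
        spec = self._spec(0.05, 10.0)
        cohort, truth = simulate_cohort(spec)
        planted = truth["planted_outlier_rows"]
        # 5% of 80 animals -> 4 rows per qPCR group
        per_group = cohort.microbes.loc[planted].groupby("group_name").size()
        assert (per_group == 4).all()

        # the outlier stage recovers planted points for a clean target group
        measures = quantify_cohort(cohort)
        scores = score_cohort(cohort).scores.set_index("animal_id")
        grp = measures[(measures.group_name == "Akkermansia_muciniphila")
                       & ~measures.below_detection]
        ages = scores.loc[grp["animal_id"], "age_months"].to_numpy()
        planted_ids = set(cohort.microbes.loc[planted]
                          .query("group_name == 'Akkermansia_muciniphila'")["animal_id"])
        report, _, _ = rout_outliers(ages, np.log10(grp["value"].to_numpy()), Q=1.0)
        flagged_ids = set(grp["animal_id"].to_numpy()[report.flagged_indices])
        assert planted_ids <= flagged_ids

    def test_zero_fraction_leaves_cohort_unchanged(self):
        a, ta = simulate_cohort(self._spec(0.0, 10.0))
        b, tb = simulate_cohort(GeneratorSpec(rng_seed=0))
        pd.testing.assert_frame_equal(a.microbes, b.microbes)
        assert ta["planted_outlier_rows"] == []

    def test_zero_magnitude_returns_planted_list_without_displacement(self):
        spec = self._spec(0.05, 0.0)
        cohort, truth = simulate_cohort(spec)
        assert truth["planted_outlier_rows"] == []

        # calling the planting step directly with magnitude zero keeps values
        base, _ = simulate_cohort(GeneratorSpec(rng_seed=0))
        spec2 = GeneratorSpec(outlier_fraction=0.05, outlier_magnitude=0.0, rng_seed=0)
        planted_df, idx = plant_outliers(base.microbes, spec2,
                                         np.random.default_rng(0))
        assert len(idx) > 0
        pd.testing.assert_frame_equal(planted_df, base.microbes)

    def test_excessive_fraction_rejected(self):
        with pytest.raises(ValueError, match="outlier_fraction"):
            simulate_cohort(self._spec(0.25, 5.0))


class TestPlantedStructureRecovery:
    def test_frailty_linked_microbe_detected_more_on_frailty_axis(self):
        """A microbe driven by latent frailty (not age) is found more often on
        the frailty axis than on the age axis."""
        f_hits = a_hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cohort, _ = simulate_cohort(GeneratorSpec(rng_seed=1000 + seed))
            scores = score_cohort(cohort).scores.set_index("animal_id")
            measures = quantify_cohort(cohort)
            grp = measures[(measures.group_name == "Schaedler")
                           & ~measures.below_detection]
            wt = grp[grp["animal_id"].str.startswith("WT")]
            vals = wt["value"].to_numpy()
            for axis, bucket in (("age_months", "a"), ("frailty", "f")):
                x = scores.loc[wt["animal_id"], axis].to_numpy()
                ok = np.isfinite(x)
                _, xc, yc = rout_outliers(x[ok], vals[ok], Q=1.0)
                _, p = pearson_test(xc, yc)
                if p < 0.05:
                    if bucket == "f":
                        f_hits += 1
                    else:
                        a_hits += 1
        assert (f_hits - a_hits) / n_seeds >= 0.20

    def test_genotype_decline_modifier_raises_slope_difference_power(self):
        """Power of the frailty-vs-age slope comparison grows with the planted
        transgenic decline modifier."""
        rates = []
        for factor in (0.0, 0.4, 1.0):
            hits = 0
            n_seeds = 25
            for seed in range(n_seeds):
                spec = GeneratorSpec(rng_seed=2000 + seed)
                for task in ("cage_top", "tight_rope", "grip_strength"):
                    spec.tasks[task].tg_age_slope *= factor
                for item in spec.items.values():
                    item.gamma_age *= factor
                cohort, _ = simulate_cohort(spec)
                s = score_cohort(cohort).scores.dropna(subset=["frailty"])
                wt = s[s.genotype == "wildtype"]
                tg = s[s.genotype == "5xFAD"]
                _, p = compare_slopes(wt["age_months"], wt["frailty"],
                                      tg["age_months"], tg["frailty"])
                hits += p < 0.05
            rates.append(hits / n_seeds)
        assert rates[0] < rates[1] < rates[2]

    def test_sex_dependent_decline_surfaces_in_stratified_slopes(self):
        """Planting a male-steeper decline makes the sex slope comparison of
        frailty-vs-age significant in the wild-type stratum."""
        spec = GeneratorSpec(n_per_genotype=100, rng_seed=77)
        # males decline 60% faster than females on every grip task
        for task in ("cage_top", "tight_rope", "grip_strength"):
            spec.tasks[task].sex_age_slope = 0.6 * spec.tasks[task].age_slope
        cohort, _ = simulate_cohort(spec)
        s = score_cohort(cohort).scores.dropna(subset=["mfs"])
        wt = s[s.genotype == "wildtype"]
        f = wt[wt.sex == "female"]
        m = wt[wt.sex == "male"]
        _, p = compare_slopes(f["age_months"], f["mfs"],
                              m["age_months"], m["mfs"])
        assert p < 0.05


class TestEndToEndQualitativePatterns:
    def test_default_cohort_reproduces_headline_patterns(self, default_cohort,
                                                         default_scores):
        cohort, _ = default_cohort
        out = associate_cohort(cohort, default_scores)
        dropped = set(out.detection_decisions.loc[~out.detection_decisions["kept"],
                                                  "group_name"])
        assert {"Prevotella", "Clostridium_coccoides"} <= dropped
        assert "BF_ratio" in set(out.measures["group_name"])
        # aged comparison reports group ages and their t-test
        assert {"mean_age_wildtype", "mean_age_5xFAD", "age_p"} <= set(out.aged.columns)
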