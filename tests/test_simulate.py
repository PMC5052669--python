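import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lncscape as L
from lncscape.simulate import (ConfigError, DEFAULT_CONCEPT_PLAN, transcript_models,
                               write_cohort)


class TestConfigValidation:
    def test_zero_samples_rejected(self):
        with pytest.raises(ConfigError):
            L.CohortConfig(n_tumor=0, n_normal=0).validate()

    def test_zero_transcripts_rejected(self):
        with pytest.raises(ConfigError):
            L.CohortConfig(n_transcripts=0).validate()

    def test_subtype_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="proportions"):
            L.CohortConfig(subtype_proportions={"LumA": 0.5, "Basal": 0.4}).validate()

    def test_de_counts_bounded_by_lncrna_count(self):
        with pytest.raises(ConfigError):
            L.CohortConfig(n_transcripts=100, lncrna_fraction=0.1,
                           n_de_cancer=50).validate()

    def test_bad_ranges_rejected(self):
        with pytest.raises(ConfigError):
            L.CohortConfig(library_size_range=(100, 10)).validate()
        with pytest.raises(ConfigError):
            L.CohortConfig(fold_change=0).validate()


class TestCohortGenerator:
    def test_same_seed_bit_identical(self):
        cfg = L.CohortConfig(n_tumor=30, n_normal=10, n_transcripts=120, seed=5)
        m1, mo1, a1, t1 = L.simulate_cohort(cfg)
        m2, mo2, a2, t2 = L.simulate_cohort(L.CohortConfig(
            n_tumor=30, n_normal=10, n_transcripts=120, seed=5))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(mo1, mo2)
        pd.testing.assert_frame_equal(a1, a2)
        assert t1.to_json() == t2.to_json()

    def test_different_seed_differs(self):
        kw = dict(n_tumor=20, n_normal=10, n_transcripts=60, n_de_cancer=9,
                  n_de_er=6, n_de_overlap=2, n_subtype_markers=2)
        cfg_a = L.CohortConfig(seed=1, **kw)
        cfg_b = L.CohortConfig(seed=2, **kw)
        assert not L.simulate_cohort(cfg_a)[0].values.equals(
            L.simulate_cohort(cfg_b)[0].values)

    def test_null_config_group_means_near_unity(self):
        cfg = L.CohortConfig(n_tumor=100, n_normal=100, n_transcripts=150,
                             n_de_cancer=0, n_de_er=0, n_de_overlap=0,
                             n_subtype_markers=0, lncrna_silent_fraction=0.0,
                             fold_change=1.0, nb_dispersion=0.1,
                             library_size_range=(1e6, 1e6), seed=3)
        matrix, _, ann, _ = L.simulate_cohort(cfg)
        tum = matrix.values.loc[:, (ann["cohort"] == "tumor").to_numpy()].mean(axis=1)
        nor = matrix.values.loc[:, (ann["cohort"] == "normal").to_numpy()].mean(axis=1)
        ratios = (tum + 1) / (nor + 1)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)

    def test_planted_fold_recovered_within_twenty_percent(self):
        cfg = L.CohortConfig(n_tumor=100, n_normal=100, n_transcripts=400,
                             n_de_cancer=100, n_de_er=0, n_de_overlap=0,
                             n_subtype_markers=0,
                             de_cancer_pattern_fractions=(1.0, 0.0, 0.0),
                             fold_change=4.0, nb_dispersion=0.2,
                             library_size_range=(1e6, 1e6), seed=4)
        matrix, _, ann, truth = L.simulate_cohort(cfg)
        planted = sorted(truth.de_cancer_ids)
        tum = matrix.values.loc[planted, (ann["cohort"] == "tumor").to_numpy()]
        nor = matrix.values.loc[planted, (ann["cohort"] == "normal").to_numpy()]
        ratios = tum.mean(axis=1) / nor.mean(axis=1)
        assert np.abs(ratios / 4.0 - 1.0).median() < 0.2

    def test_truths_reference_real_transcripts(self, planted_cohort):
        _, matrix, _, _, truth = planted_cohort
        known = set(matrix.transcript_ids)
        assert set(truth.de_cancer_ids) <= known
        assert set(truth.de_er_ids) <= known
        assert truth.bound_promoter_ids <= known
        assert truth.best_candidate_id in known

    def test_best_candidate_is_er_restricted(self, planted_cohort):
        _, matrix, _, ann, truth = planted_cohort
        fpkm = matrix.to_fpkm()
        x = fpkm.values.loc[truth.best_candidate_id]
        er_pos = (ann["er_status"] == "positive").to_numpy()
        assert np.median(x[er_pos]) > 10
        assert np.median(x[~er_pos]) < 1

    def test_written_cohort_round_trips(self, planted_cohort, tmp_path):
        _, matrix, models, ann, truth = planted_cohort
        paths = write_cohort(tmp_path, matrix, models, ann, truth)
        back = L.read_matrix(paths["matrix"])
        pd.testing.assert_frame_equal(back.values, matrix.values)
        assert "seed" not in paths  # truth JSON carries provenance
        assert (tmp_path / "truth.json").exists()


class TestConceptLibrary:
    def _truth(self, universe, n_target=20, plan=None):
        t = L.SimTruth()
        t.target_correlated_ids = tuple(universe[:n_target])
        t.concept_overlap_plan = plan if plan is not None else {"c": 5}
        return t

    def test_exact_planted_overlaps(self):
        universe = [f"g{i}" for i in range(400)]
        plan = {"c0": 0, "c3": 3, "c10": 10}
        truth = self._truth(universe, n_target=30, plan=plan)
        concepts = L.simulate_concept_library(truth, universe, seed=1, concept_size=40)
        target = set(truth.target_correlated_ids)
        got = {c.name: len(set(c.genes) & target) for c in concepts}
        assert got == plan
        assert all(len(c) == 40 for c in concepts)

    def test_zero_overlap_disjoint_and_full_overlap_subset(self):
        universe = [f"g{i}" for i in range(100)]
        truth = self._truth(universe, n_target=20, plan={"none": 0, "all": 8})
        concepts = {c.name: c for c in
                    L.simulate_concept_library(truth, universe, seed=2, concept_size=8)}
        target = set(truth.target_correlated_ids)
        assert not set(concepts["none"].genes) & target
        assert set(concepts["all"].genes) <= target

    def test_downstream_fisher_or_large_for_planted_overlap(self):
        universe = [f"g{i}" for i in range(20_000)]
        truth = self._truth(universe, n_target=150, plan={"hot": 30})
        (concept,) = L.simulate_concept_library(truth, universe, seed=3,
                                                concept_size=150)
        sig = L.GeneSignature("s", truth.target_correlated_ids, "up")
        assoc = L.fisher_overlap(sig, concept, universe)
        assert assoc.a == 30
        assert assoc.odds_ratio > 10
        assert assoc.p_one_sided < 1e-20

    def test_infeasible_plan_rejected(self):
        universe = [f"g{i}" for i in range(30)]
        truth = self._truth(universe, n_target=5, plan={"c": 10})
        with pytest.raises(ConfigError, match="infeasible"):
            L.simulate_concept_library(truth, universe, seed=0, concept_size=8)

    def test_extra_concepts_get_zero_overlap(self):
        universe = [f"g{i}" for i in range(200)]
        truth = self._truth(universe, n_target=20, plan={"c": 4})
        concepts = L.simulate_concept_library(truth, universe, n_concepts=5,
                                              seed=4, concept_size=10)
        assert len(concepts) == 5
        assert sum(v == 0 for v in truth.concept_overlap_plan.values()) == 4


class TestChipPeaks:
    def test_bound_promoters_all_recovered(self, planted_cohort):
        _, _, models, _, truth = planted_cohort
        peaks = L.simulate_chip_peaks(models, truth, seed=9)
        flags = L.promoter_binding_flags(transcript_models(models), peaks,
                                         upstream_bp=5000, downstream_bp=5000)
        assert set(flags.index[flags]) >= truth.bound_promoter_ids

    def test_empty_bound_set_gives_no_promoter_hits(self, planted_cohort):
        _, _, models, _, _ = planted_cohort
        truth = L.SimTruth()
        peaks = L.simulate_chip_peaks(models, truth, seed=9, n_decoys=50)
        flags = L.promoter_binding_flags(transcript_models(models), peaks)
        assert not flags.any()

    def test_exact_bound_count_by_brute_force(self):
        cfg = L.CohortConfig(n_tumor=20, n_normal=10, n_transcripts=500,
                             n_de_overlap=0, seed=21)
        _, models, _, _ = L.simulate_cohort(cfg)
        truth = L.SimTruth()
        rng = np.random.default_rng(0)
        truth.bound_promoter_ids = set(
            rng.choice(models.index.to_numpy(), 50, replace=False))
        peaks = L.simulate_chip_peaks(models, truth, seed=5)
        tms = transcript_models(models)
        windows = L.promoter_windows(tms, "symmetric", 5000, 5000)
        bound = set()
        for w in windows:  # brute-force interval intersection
            for p in peaks:
                if p.chrom == w.chrom and max(p.start, w.start) < min(p.end, w.end):
                    bound.update(w.name.split(","))
        assert bound == truth.bound_promoter_ids

    def test_decoys_far_from_any_tss(self, planted_cohort):
        _, _, models, _, truth = planted_cohort
        peaks = [p for p in L.simulate_chip_peaks(models, truth, seed=9)
                 if p.name.startswith("peak_decoy")]
        tss = models.groupby("chrom")["tss"].apply(list).to_dict()
        for p in peaks:
            dists = [min(abs(p.start - t), abs(p.end - t)) for t in tss.get(p.chrom, [])]
            assert min(dists) >= 100_000

    def test_peak_wider_than_window_rejected(self, planted_cohort):
        _, _, models, _, truth = planted_cohort
        with pytest.raises(ConfigError):
            L.simulate_chip_peaks(models, truth, peak_width=6000, upstream_bp=5000)


class TestInduction:
    def test_noise_free_ratio_exact(self):
        truth = L.SimTruth(induced_ids={"t1": 3.0, "t2": 1.0})
        table = L.simulate_induction(truth, noise_sd=0.0, seed=0)
        assert table.loc["t1", "fold"] == pytest.approx(3.0)
        assert table.loc["t2", "fold"] == pytest.approx(1.0)

    def test_fold_one_maps_to_category_none(self):
        truth = L.SimTruth(induced_ids={"t": 1.0})
        table = L.simulate_induction(truth, noise_sd=0.0, seed=0)
        assert L.induction_category(table.loc["t", "fold"]) == "none"

    def test_fold_two_maps_to_category_low(self):
        truth = L.SimTruth(induced_ids={"t": 2.0})
        table = L.simulate_induction(truth, noise_sd=0.0, seed=0)
        assert L.induction_category(table.loc["t", "fold"]) == "low"

    def test_tamoxifen_reverts_toward_vehicle(self):
        truth = L.SimTruth(induced_ids={"t": 3.0})
        table = L.simulate_induction(truth, noise_sd=0.0, seed=0)
        row = table.loc["t"]
        assert row["vehicle"] < row["estrogen_tamoxifen"] < row["estrogen"]


class TestSurvivalGenerator:
    def _ann(self, n):
        return pd.DataFrame({"cohort": ["tumor"] * n},
                            index=[f"s{i}" for i in range(n)])

    def test_all_censored_km_constant_at_one(self):
        truth = L.SimTruth(survival_hr=1.0)
        ann = self._ann(40)
        expr = pd.Series(20.0, index=ann.index)
        surv = L.simulate_survival(ann, expr, truth, seed=1, baseline_hazard=1e-9)
        assert surv["event"].sum() == 0
        curve = L.km_estimate(surv["time"], surv["event"])
        assert (curve["survival"] == 1.0).all()

    def test_planted_hazard_separates_groups(self):
        truth = L.SimTruth(survival_hr=3.0)
        ann = self._ann(200)
        expr = pd.Series([20.0] * 100 + [0.5] * 100, index=ann.index)
        surv = L.simulate_survival(ann, expr, truth, seed=2)
        hi = surv[surv["group"] == "high"]
        lo = surv[surv["group"] == "low"]
        chi2, p = L.logrank_test(hi["time"], hi["event"], lo["time"], lo["event"])
        assert p < 0.01

    def test_nonpositive_hr_rejected(self):
        truth = L.SimTruth(survival_hr=0.0)
        ann = self._ann(5)
        with pytest.raises(ConfigError):
            L.simulate_survival(ann, pd.Series(1.0, index=ann.index), truth)


class TestTruthValidation:
    def test_unknown_id_rejected(self):
        truth = L.SimTruth(de_cancer_ids={"ghost": "+"})
        with pytest.raises(ConfigError, match="ghost"):
            truth.validate(["t1", "t2"])

    def test_bad_direction_rejected(self):
        truth = L.SimTruth(de_cancer_ids={"t1": "up"})
        with pytest.raises(ConfigError, match="direction"):
            truth.validate(["t1"])
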