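import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lncscape as L
from lncscape.association import (ConceptStudy, FIGURE_PRESET, METHODS_PRESET,
                                  GeneSignature, best_variant_association,
                                  concept_network, fisher_overlap, preranked_gsea,
                                  read_gmt, spearman_correlations, top_signatures,
                                  write_gmt)


def _matrix_with_target(rng, n_genes=20, n_samples=8):
    target = rng.normal(size=n_samples)
    rows = {"TARGET": np.abs(target) + 5}
    rows["TARGET"] = target - target.min() + 1.0
    for i in range(n_genes):
        rows[f"G{i:03d}"] = rng.normal(size=n_samples) + 3 * rng.random()
    rows["G_SAME"] = rows["TARGET"] * 2.0          # rho = 1
    rows["G_OPP"] = -rows["TARGET"] + 10.0          # rho = -1
    df = pd.DataFrame(rows, index=[f"S{i}" for i in range(n_samples)]).T
    df = df - df.min().min() + 0.01
    tr = pd.DataFrame({"biotype": ["lncRNA"] + ["protein_coding"] * (n_genes + 2),
                       "length_bp": 1000}, index=df.index)
    return L.ExpressionMatrix(df, "FPKM", transcripts=tr)


class TestSpearman:
    def test_identical_and_reversed_genes(self, rng):
        m = _matrix_with_target(rng)
        ranked = spearman_correlations(m, "TARGET")
        ranked = ranked.set_index("gene_id")["rho"]
        assert ranked["G_SAME"] == pytest.approx(1.0)
        assert ranked["G_OPP"] == pytest.approx(-1.0)

    def test_matches_scipy_spearmanr(self, rng):
        m = _matrix_with_target(rng)
        ranked = spearman_correlations(m, "TARGET").set_index("gene_id")["rho"]
        target = m.values.loc["TARGET"]
        for g in ["G000", "G007", "G015", "G_SAME"]:
            expected = stats.spearmanr(m.values.loc[g], target).statistic
            assert ranked[g] == pytest.approx(expected, abs=1e-12)

    def test_constant_target_rejected(self, rng):
        m = _matrix_with_target(rng)
        vals = m.values.copy()
        vals.loc["TARGET"] = 2.0
        m2 = m.copy_with(vals)
        with pytest.raises(ValueError, match="constant"):
            spearman_correlations(m2, "TARGET")

    def test_biotype_filter_and_target_excluded(self, rng):
        m = _matrix_with_target(rng)
        ranked = spearman_correlations(m, "TARGET")
        assert "TARGET" not in set(ranked["gene_id"])
        assert len(ranked) == 22  # protein-coding genes only

    def test_negating_target_swaps_signatures(self, rng):
        m = _matrix_with_target(rng, n_genes=30)
        ranked = spearman_correlations(m, "TARGET")
        pos, neg = top_signatures(ranked, n=5)
        flipped = ranked.copy()
        flipped["rho"] = -flipped["rho"]
        flipped = flipped.sort_values(["rho", "gene_id"], ascending=[False, True])
        pos2, neg2 = top_signatures(flipped.reset_index(drop=True), n=5)
        assert set(pos.genes) == set(neg2.genes)
        assert set(neg.genes) == set(pos2.genes)


class TestTopSignatures:
    def _ranked(self, rhos, ids=None):
        ids = ids or [f"g{i}" for i in range(len(rhos))]
        return pd.DataFrame({"gene_id": ids, "rho": rhos})

    def test_n_one_is_argmax_argmin(self):
        r = self._ranked([0.9, -0.7, 0.2, 0.1])
        pos, neg = top_signatures(r, n=1)
        assert pos.genes == ("g0",) and neg.genes == ("g1",)

    def test_distinct_rhos_give_exact_order_statistics(self, rng):
        rhos = rng.permutation(np.linspace(-1, 1, 20))
        r = self._ranked(list(rhos))
        pos, neg = top_signatures(r, n=4)
        order = r.sort_values("rho", ascending=False)
        assert list(pos.genes) == list(order["gene_id"].head(4))
        assert list(neg.genes) == list(order["gene_id"].tail(4)[::-1])

    def test_boundary_tie_resolved_by_gene_id(self):
        r = self._ranked([0.5, 0.5, 0.5, -0.5], ids=["b", "a", "c", "d"])
        pos, _ = top_signatures(r, n=2)
        assert pos.genes == ("a", "b")

    def test_insufficient_genes_rejected(self):
        with pytest.raises(ValueError):
            top_signatures(self._ranked([0.1, 0.2]), n=2)


def hypergeom_tail_by_enumeration(a, n_sig, n_concept, n_universe):
    """P(X >= a) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(a, min(n_sig, n_concept) + 1):
        total += (math.comb(n_concept, x) * math.comb(n_universe - n_concept, n_sig - x)
                  / math.comb(n_universe, n_sig))
    return total


class TestFisherOverlap:
    def _sig(self, genes, direction="up"):
        return GeneSignature("sig", tuple(genes), direction)

    def test_small_case_matches_enumeration(self):
        universe = [f"u{i}" for i in range(20)]
        sig = self._sig(universe[:5])
        concept = GeneSignature("c", tuple(universe[2:7]))
        assoc = fisher_overlap(sig, concept, universe)
        assert assoc.a == 3
        assert assoc.p_one_sided == pytest.approx(
            hypergeom_tail_by_enumeration(3, 5, 5, 20), rel=1e-10)

    def test_randomized_tables_match_enumeration(self, rng):
        for _ in range(50):
            u = int(rng.integers(8, 30))
            universe = [f"u{i}" for i in range(u)]
            ns, nc = int(rng.integers(1, u)), int(rng.integers(1, u))
            sig = self._sig(list(rng.choice(universe, ns, replace=False)))
            concept = GeneSignature("c", tuple(rng.choice(universe, nc, replace=False)))
            assoc = fisher_overlap(sig, concept, universe)
            assert assoc.p_one_sided == pytest.approx(
                hypergeom_tail_by_enumeration(assoc.a, ns, nc, u), rel=1e-9, abs=1e-12)
            # scipy's one-sided Fisher as a second, independent route
            table = [[assoc.a, assoc.b], [assoc.c, assoc.d]]
            assert assoc.p_one_sided == pytest.approx(
                stats.fisher_exact(table, alternative="greater")[1], rel=1e-7, abs=1e-12)

    def test_zero_overlap_flagged_and_corrected(self):
        universe = [f"u{i}" for i in range(10)]
        assoc = fisher_overlap(self._sig(universe[:3]),
                               GeneSignature("c", tuple(universe[3:6])), universe)
        assert assoc.a == 0 and assoc.zero_cell_corrected
        assert assoc.odds_ratio > 0

    def test_signature_inside_concept_equal_to_universe(self):
        universe = [f"u{i}" for i in range(8)]
        assoc = fisher_overlap(self._sig(universe[:4]),
                               GeneSignature("c", tuple(universe)), universe)
        assert assoc.a == 4 and assoc.p_one_sided == pytest.approx(1.0)

    def test_counts_partition_universe(self, rng):
        universe = [f"u{i}" for i in range(25)]
        sig = self._sig(list(rng.choice(universe, 10, replace=False)))
        concept = GeneSignature("c", tuple(rng.choice(universe, 7, replace=False)))
        assoc = fisher_overlap(sig, concept, universe)
        assert assoc.universe_size == 25

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(self._sig(["x"]), GeneSignature("c", ("u0",)), ["u0"])


class TestBestVariant:
    def test_single_variant_returned_unconditionally(self):
        universe = [f"u{i}" for i in range(40)]
        sig = GeneSignature("s", tuple(universe[:10]), "up")
        study = ConceptStudy("st", {("up", 5): tuple(universe[5:15])})
        assoc = best_variant_association(sig, study, universe, percents=(5,),
                                         directions=("up",))
        assert assoc.chosen_variant == "up_5pct"

    def test_overlap_concentrated_in_top_percent_selected(self):
        universe = [f"u{i}" for i in range(200)]
        sig = GeneSignature("s", tuple(universe[:20]), "up")
        study = ConceptStudy("st", {
            ("up", 1): tuple(universe[:10]),            # 10/10 overlap
            ("up", 5): tuple(universe[10:40]),          # 10/30 overlap
            ("up", 10): tuple(universe[100:160]),       # 0 overlap
        })
        assoc = best_variant_association(sig, study, universe)
        assert assoc.chosen_variant == "up_1pct"
        # exhaustive check: its OR is maximal among all variants
        ors = [fisher_overlap(sig, GeneSignature("v", study.variants[k]),
                              universe).odds_ratio for k in study.variants]
        assert assoc.odds_ratio == pytest.approx(max(ors))

    def test_empty_variants_skipped_with_warning(self):
        universe = [f"u{i}" for i in range(10)]
        sig = GeneSignature("s", tuple(universe[:3]), "up")
        study = ConceptStudy("st", {("up", 1): ()})
        with pytest.warns(UserWarning):
            assert best_variant_association(sig, study, universe,
                                            percents=(1,), directions=("up",)) is None


class TestConceptNetwork:
    def _assoc(self, name, orr, p, sign="positive"):
        return L.ConceptAssociation("sig", name, 10, 10, 10, 70, orr, p, sign=sign)

    def test_thresholds_are_strict(self):
        nodes, edges = concept_network([self._assoc("c1", 5.9, 1e-9)], METHODS_PRESET)
        assert len(edges) == 0
        nodes, edges = concept_network([self._assoc("c2", 6.01, 1e-9)], METHODS_PRESET)
        assert len(edges) == 1

    def test_both_printed_presets(self):
        a = self._assoc("c", 10.0, 1e-3)
        assert len(concept_network([a], METHODS_PRESET)[1]) == 0   # needs p < 1e-6
        a2 = self._assoc("c", 10.0, 1e-5)
        assert len(concept_network([a2], FIGURE_PRESET)[1]) == 1   # p < 1e-4

    def test_negative_threshold_applies_to_negative_sign(self):
        a = self._assoc("c", 5.0, 1e-9, sign="negative")
        assert len(concept_network([a], METHODS_PRESET)[1]) == 1   # neg needs OR > 4
        b = self._assoc("c", 5.0, 1e-9, sign="positive")
        assert len(concept_network([b], METHODS_PRESET)[1]) == 0

    def test_planted_passing_count(self, rng):
        assocs = [self._assoc(f"pass{i}", 8.0 + i, 1e-8) for i in range(5)]
        assocs += [self._assoc(f"fail{i}", 2.0, 1e-8) for i in range(4)]
        _, edges = concept_network(assocs, METHODS_PRESET)
        assert len(edges) == 5
        assert all(t.startswith("pass") for t in edges["target"])

    def test_edge_set_monotone_in_thresholds(self, rng):
        assocs = [self._assoc(f"c{i}", float(rng.uniform(1, 12)),
                              float(10 ** -rng.uniform(2, 9))) for i in range(30)]
        base = set(concept_network(
            assocs, L.association.NetworkPreset(4.0, 3.0, 1e-3))[1]["target"])
        tighter = set(concept_network(
            assocs, L.association.NetworkPreset(6.0, 5.0, 1e-5))[1]["target"])
        assert tighter <= base


class TestPrerankedGsea:
    def _ranked(self, rhos):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(rhos))],
                             "rho": rhos})

    def test_top_k_set_gives_es_one(self):
        ranked = self._ranked(list(np.linspace(1, -1, 30)))
        out = preranked_gsea(ranked, {"top": [f"g{i}" for i in range(5)]},
                             n_permutations=10, seed=0)
        assert out.loc["top", "es"] == pytest.approx(1.0)

    def test_toy_matches_step_oracle(self):
        rhos = [0.9, 0.7, 0.4, 0.1, -0.2, -0.3, -0.6, -0.7, -0.8, -0.95]
        ranked = self._ranked(rhos)
        members = {"g1", "g4", "g7"}
        out = preranked_gsea(ranked, {"toy": sorted(members)}, n_permutations=5, seed=1)
        # independent step-by-step walk over the ranked list
        mask = [g in members for g in ranked["gene_id"]]
        denom = sum(abs(r) for r, m in zip(rhos, mask) if m)
        run, best = 0.0, 0.0
        for r, m in zip(rhos, mask):
            run += abs(r) / denom if m else -1.0 / (10 - 3)
            if abs(run) > abs(best):
                best = run
        assert out.loc["toy", "es"] == pytest.approx(best)

    def test_random_sets_give_unremarkable_p(self, rng):
        rhos = sorted(rng.normal(size=120), reverse=True)
        ranked = self._ranked(list(rhos))
        sets = {f"rand{i}": list(rng.choice(ranked["gene_id"], 15, replace=False))
                for i in range(20)}
        out = preranked_gsea(ranked, sets, n_permutations=200, seed=3)
        # null sets: p should not pile up at the extreme
        assert (out["p_nominal"] < 0.01).mean() <= 0.2

    def test_absent_genes_dropped_with_warning(self):
        ranked = self._ranked([0.5, 0.1, -0.4])
        with pytest.warns(UserWarning):
            out = preranked_gsea(ranked, {"s": ["g0", "missing"]},
                                 n_permutations=5, seed=0)
        assert out.loc["s", "n_genes"] == 1


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        sets = {"setA": ("g1", "g2"), "setB": ("g3",)}
        path = tmp_path / "x.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(path)
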