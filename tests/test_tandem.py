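"""Tandem arrays, Fisher enrichment with adjustments, set algebra."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from allokit.genome import Gene
from allokit.simulate import SimulationConfig, simulate_allopolyploid
from allokit.tandem import (find_tandem_arrays, go_enrichment,
                            lineage_specific_terms, set_overlap_test,
                            tandem_gene_ids)

from oracles import oracle_fisher_2x2_greater, oracle_hypergeom_upper_tail


def _genes(families, chrom="c1"):
    out = []
    for i, fam in enumerate(families):
        out.append(Gene(gene_id=f"{chrom}g{i}", chrom=chrom, start=100 * i,
                        end=100 * i + 6, strand="+", cds="ATGGCA",
                        family=fam, subgenome="A"))
    return out


class TestTandemArrays:
    def test_adjacent_same_family_pair_forms_array(self):
        arrays = find_tandem_arrays(_genes(["F1", "F1"]))
        assert len(arrays) == 1 and arrays[0].size == 2

    def test_gap_threshold_boundary(self):
        families = ["F1"] + [f"x{i}" for i in range(11)] + ["F1"]
        assert find_tandem_arrays(_genes(families), max_gap=10) == []
        arrays = find_tandem_arrays(_genes(families), max_gap=11)
        assert len(arrays) == 1 and arrays[0].size == 2

    def test_arrays_do_not_span_chromosomes(self):
        genes = _genes(["F1"], "c1") + _genes(["F1"], "c2")
        assert find_tandem_arrays(genes) == []

    def test_unordered_input_rejected(self):
        genes = list(reversed(_genes(["F1", "F2"])))
        with pytest.raises(ValueError):
            find_tandem_arrays(genes)

    def test_detection_matches_planted_truth(self):
        cfg = SimulationConfig(n_chromosome_pairs=2, genes_per_chromosome=150,
                               codons_per_gene=30, tandem_rate=0.2,
                               loss_fraction_A=0.0, loss_fraction_D=0.0,
                               seed=40)
        genome, truth = simulate_allopolyploid(cfg)
        ordered = sorted(genome.genes, key=lambda g: (g.chrom, g.start))
        arrays = find_tandem_arrays(ordered, max_gap=10)
        detected = {tuple(a.members) for a in arrays}
        planted = {tuple(ids) for ids in truth.tandem_arrays}
        assert detected == planted

    def test_detection_is_idempotent(self):
        cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=100,
                               codons_per_gene=20, tandem_rate=0.3, seed=41)
        genome, _ = simulate_allopolyploid(cfg)
        ordered = sorted(genome.genes, key=lambda g: (g.chrom, g.start))
        arrays = find_tandem_arrays(ordered, max_gap=10)
        keep = tandem_gene_ids(arrays)
        rerun = find_tandem_arrays([g for g in ordered if g.gene_id in keep],
                                   max_gap=10)
        assert {tuple(a.members) for a in rerun} == {tuple(a.members) for a in arrays}


class TestEnrichment:
    def test_study_equal_population_gives_unit_pvalues(self):
        pop = {f"g{i}" for i in range(100)}
        term_map = {"T1": {f"g{i}" for i in range(30)}}
        df = go_enrichment(pop, pop, term_map)
        assert (df["p_raw"] == 1.0).all()

    def test_raw_p_matches_exhaustive_tail_sum(self):
        pop = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(50)}
        study = {f"g{i}" for i in range(42, 52)}     # 8 of 10 in the term
        df = go_enrichment(study, pop, {"T1": term})
        expected = oracle_hypergeom_upper_tail(8, 1000, 50, 10)
        assert df["p_raw"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_bonferroni_multiplies_and_caps(self):
        pop = {f"g{i}" for i in range(200)}
        term_map = {f"T{t}": {f"g{i}" for i in range(t, t + 40)} for t in range(10)}
        study = {f"g{i}" for i in range(20)}
        df = go_enrichment(study, pop, term_map)
        expect = np.minimum(df["p_raw"] * len(term_map), 1.0)
        assert np.allclose(df["p_bonferroni"], expect)

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(42)
        pop = {f"g{i}" for i in range(500)}
        term_map = {f"T{t}": set(rng.choice(sorted(pop), 40, replace=False))
                    for t in range(25)}
        study = set(rng.choice(sorted(pop), 60, replace=False))
        df = go_enrichment(study, pop, term_map)
        assert (df["p_holm"] <= df["p_bonferroni"] + 1e-15).all()
        for col in ("p_bonferroni", "p_holm", "p_sidak"):
            assert (df[col] >= df["p_raw"] - 1e-15).all()
            assert df[col].between(0, 1).all()

    def test_study_outside_population_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"gX"}, {"g1"}, {})


class TestLineageTerms:
    def test_identical_sets_all_in_full_intersection(self):
        sets = {"L1": {"a", "b"}, "L2": {"a", "b"}}
        part = lineage_specific_terms(sets)
        assert part["L1+L2"] == 2 and part["L1"] == 0 and part["L2"] == 0

    def test_disjoint_sets_are_lineage_specific(self):
        part = lineage_specific_terms({"L1": {"a"}, "L2": {"b"}})
        assert part["L1"] == 1 and part["L2"] == 1 and part["L1+L2"] == 0

    def test_partition_sizes_sum_to_union_for_random_sets(self):
        rng = np.random.default_rng(43)
        universe = [f"t{i}" for i in range(60)]
        sets = {f"L{j}": {t for t in universe if rng.random() < 0.4}
                for j in range(5)}
        part = lineage_specific_terms(sets)
        assert sum(part.values()) == len(set.union(*sets.values()))

    def test_single_lineage_rejected(self):
        with pytest.raises(ValueError):
            lineage_specific_terms({"L1": {"a"}})


class TestSetOverlap:
    def test_subset_gives_unit_fraction(self):
        res = set_overlap_test({"a", "b"}, {"a", "b", "c"}, 10)
        assert res.fraction == 1.0

    def test_p_matches_hypergeometric_oracle(self):
        set1 = {f"g{i}" for i in range(100)}
        set2 = {f"g{i}" for i in range(60, 200)}
        res = set_overlap_test(set1, set2, 10_000)
        expected = oracle_fisher_2x2_greater(40, 60, 100, 9800)
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_null_overlap_p_is_uniform_ish(self):
        rng = np.random.default_rng(44)
        universe = np.arange(10_000)
        ps = []
        for _ in range(200):
            s1 = set(rng.choice(universe, 500, replace=False).tolist())
            s2 = set(rng.choice(universe, 500, replace=False).tolist())
            ps.append(set_overlap_test(s1, s2, 10_000).p_value)
        ps = np.array(ps)
        assert abs(np.median(ps) - 0.5) < 0.15
        assert abs((ps < 0.05).mean() - 0.05) < 0.05

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            set_overlap_test(set(), set(), 0)


@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
       st.integers(0, 30))
def test_fisher_p_invariant_to_transposing_the_table(a, b, c, d):
    p1 = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    p2 = stats.fisher_exact([[a, c], [b, d]], alternative="two-sided")[1]
    assert p1 == pytest.approx(p2, rel=1e-9)
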