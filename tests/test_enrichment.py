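"""Gene classification, hypergeometric enrichment, the paired binomial
comparison, and the time-series term-set algebra."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from goscope import (AnnotationSet, ScopingPolicy, TimeSeriesTermSets,
                     bh_adjust, binomial_improvement_test, build_ancestor_map,
                     classify_de_genes, classify_time_series,
                     compare_enrichments, enrich, expand_annotations,
                     hypergeom_pvalue, parse_obo, read_gaf,
                     time_series_term_sets)
from goscope.enrichment import ClassificationError, EnrichmentResult
from goscope.synth import FixtureSpec, generate_de_table, generate_ontology

import _oracles


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log2FoldChange", "padj"])


class TestClassifyDeGenes:
    def test_signs_and_alpha(self):
        part = classify_de_genes(de_table([
            ("g1", 2.0, 0.005), ("g2", -1.0, 0.05), ("g3", -0.5, 0.001),
        ]), alpha=0.01)
        assert part.positive == {"g1"}
        assert part.negative == {"g3"}
        assert part.all == {"g1", "g3"}

    def test_nan_padj_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            part = classify_de_genes(de_table([
                ("g1", 2.0, float("nan")), ("g2", 1.0, 0.001)]))
        assert part.all == {"g2"}

    def test_zero_fold_change_on_significant_row_raises(self):
        with pytest.raises(ClassificationError):
            classify_de_genes(de_table([("g1", 0.0, 0.001)]))

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            classify_de_genes(de_table([("g1", 1.0, 0.5)]), alpha=1.5)

    def test_fixture_partition_matches_generator_truth(self):
        spec = FixtureSpec(seed=37)
        from goscope.synth import FixtureLedger
        ledger = FixtureLedger()
        (table,) = generate_de_table(spec, ledger, contrasts=1)
        part = classify_de_genes(table, alpha=0.01)
        for gene, (sign, significant) in ledger.de_truth.items():
            if significant:
                assert gene in (part.positive if sign > 0 else part.negative)
            else:
                assert gene not in part.all


class TestClassifyTimeSeries:
    def test_rule_table(self):
        t1 = de_table([("a", 2.0, 0.001), ("b", 1.5, 0.5), ("c", 1.0, 0.001),
                       ("d", -2.0, 0.001)])
        t2 = de_table([("a", 0.1, 0.9), ("b", -1.0, 0.001), ("c", -1.2, 0.001),
                       ("d", -1.0, 0.001)])
        part = classify_time_series(t1, t2, alpha=0.01)
        assert part.categories["early_positive"] == {"a"}
        assert part.categories["late_negative"] == {"b"}
        assert part.categories["transient_positive"] == {"c"}  # first-interval sign
        assert part.categories["consistent_negative"] == {"d"}

    def test_gene_in_one_table_excluded_with_warning(self):
        t1 = de_table([("a", 2.0, 0.001), ("only1", 2.0, 0.001)])
        t2 = de_table([("a", 2.0, 0.001)])
        with pytest.warns(UserWarning, match="excluded"):
            part = classify_time_series(t1, t2)
        assert "only1" not in part.all
        assert part.excluded == 1

    def test_two_contrast_fixture_matches_ledger_categories(self):
        spec = FixtureSpec(seed=43)
        from goscope.synth import FixtureLedger
        ledger = FixtureLedger()
        t1, t2 = generate_de_table(spec, ledger, contrasts=2)
        part = classify_time_series(t1, t2, alpha=0.01)
        for gene, cat in ledger.de_categories.items():
            if cat == "none":
                assert gene not in part.all
            else:
                assert gene in part.categories[cat]


class TestHypergeom:
    def test_zero_successes_is_certain(self):
        assert hypergeom_pvalue(0, 5, 4, 10) == 1.0

    def test_saturated_draw_is_certain(self):
        assert hypergeom_pvalue(3, 3, 3, 3) == 1.0

    def test_exact_combinatorial_value(self):
        # C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_pvalue(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(6, 5, 4, 10)


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_hand_computed_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_empty_list(self):
        assert bh_adjust([]) == []

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=40))
    def test_matches_independent_stepup_oracle(self, pvalues):
        ours = bh_adjust(pvalues)
        theirs = _oracles.bh_stepup(pvalues)
        assert ours == pytest.approx(theirs)
        assert all(a >= p for a, p in zip(ours, pvalues))


class TestEnrich:
    def make_fixture(self, tmp_path, seed=3):
        from goscope.synth import generate_gaf
        spec = FixtureSpec(seed=seed)
        obo, ledger = generate_ontology(spec)
        (tmp_path / "f.obo").write_text(obo)
        (tmp_path / "f.gaf").write_text(generate_gaf(spec, ledger))
        graph = parse_obo(tmp_path / "f.obo")
        ann = AnnotationSet.from_records(read_gaf(tmp_path / "f.gaf"))
        return spec, ledger, graph, ann

    def test_term_annotated_to_whole_universe_has_p_one(self):
        ann = AnnotationSet({f"g{i}": frozenset({"T"}) for i in range(10)},
                            expanded=True)
        res = enrich({"g0", "g1"}, set(ann.genes()), ann)
        assert res.table.loc[res.table.term == "T", "pvalue"].item() == 1.0

    def test_empty_gene_set_and_non_subset_rejected(self):
        ann = AnnotationSet({"g": frozenset({"T"})}, expanded=True)
        with pytest.raises(ValueError):
            enrich(set(), {"g"}, ann)
        with pytest.raises(ValueError):
            enrich({"x"}, {"g"}, ann)

    def test_planted_root_recovered(self, tmp_path):
        _, ledger, graph, ann = self.make_fixture(tmp_path)
        expanded = expand_annotations(
            ann, build_ancestor_map(graph, ScopingPolicy.gocats()))
        res = enrich(set(ledger.signal_genes), expanded.genes(), expanded)
        assert res.padj_of()[ledger.planted_root] <= 0.01

    def test_pvalues_invariant_under_gene_relabelling(self, tmp_path):
        _, ledger, graph, ann = self.make_fixture(tmp_path)
        expanded = expand_annotations(
            ann, build_ancestor_map(graph, ScopingPolicy.gocats()))
        rename = {g: f"X{g}" for g in expanded.genes()}
        relabelled = AnnotationSet(
            {rename[g]: t for g, t in expanded.annotations.items()},
            expanded=True)
        a = enrich(set(ledger.signal_genes), expanded.genes(), expanded)
        b = enrich({rename[g] for g in ledger.signal_genes},
                   relabelled.genes(), relabelled)
        assert sorted(a.table.pvalue) == pytest.approx(sorted(b.table.pvalue))


class TestBinomialImprovementTest:
    def test_single_comparison(self):
        assert binomial_improvement_test(1, 1) == 0.5

    def test_exact_small_tail(self):
        assert binomial_improvement_test(8, 10) == pytest.approx(56 / 1024)

    def test_zero_comparisons_undefined(self):
        with pytest.raises(ValueError):
            binomial_improvement_test(0, 0)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(min_value=1, max_value=30).flatmap(
        lambda n: st.tuples(st.integers(min_value=0, max_value=n), st.just(n))))
    def test_matches_combinatorial_sum_for_small_n(self, kn):
        k, n = kn
        assert binomial_improvement_test(k, n) == pytest.approx(
            _oracles.binom_tail_exact(k, n))

    def test_normal_approximation_same_order_of_magnitude(self):
        from scipy.stats import norm
        n = 400
        for k in (210, 230, 240):
            exact = binomial_improvement_test(k, n)
            z = (k - 0.5 - n / 2) / math.sqrt(n / 4)
            approx = float(norm.sf(z))
            assert abs(math.log10(exact) - math.log10(approx)) < 1.0


class TestCompareEnrichments:
    @staticmethod
    def result(pairs, alpha=0.01):
        terms, padj = zip(*pairs)
        table = pd.DataFrame({
            "term": terms, "k": 1, "K": 1, "n": 1, "N": 1,
            "pvalue": padj, "padj": padj,
            "significant": [p <= alpha for p in padj]})
        return EnrichmentResult(table, alpha)

    def test_counts_match_hand_tally(self):
        ref = self.result([("t1", 0.001), ("t2", 0.005), ("t3", 0.009),
                           ("t4", 0.5)])
        alt = self.result([("t1", 0.0005), ("t2", 0.005), ("t3", 0.02),
                           ("t5", 0.001)])
        cmp_ = compare_enrichments(ref, alt)
        assert cmp_.n_significant_reference == 3
        assert cmp_.n_ties == 1          # t2
        assert cmp_.n_improved == 1      # t1 (t3 got worse)
        assert cmp_.n_compared == 2
        assert cmp_.unique_alternate == {"t5"}
        assert cmp_.unique_reference == {"t3"}
        assert cmp_.n_improved + cmp_.n_not_improved + cmp_.n_ties \
            == cmp_.n_significant_reference

    def test_term_absent_from_alternate_counts_as_not_improved(self):
        ref = self.result([("t1", 0.001), ("t2", 0.001)])
        alt = self.result([("t1", 0.0001)])
        cmp_ = compare_enrichments(ref, alt)
        assert cmp_.n_compared == 2 and cmp_.n_improved == 1

    def test_all_ties_surfaces_undefined_test(self):
        ref = self.result([("t1", 0.001)])
        with pytest.raises(ValueError, match="tied"):
            compare_enrichments(ref, ref)

    def test_random_paired_lists_match_direct_tally(self):
        rng = np.random.default_rng(99)
        terms = [f"t{i}" for i in range(300)]
        ref_p = rng.uniform(0, 0.02, size=300).round(4)
        alt_p = (ref_p * rng.uniform(0.5, 1.5, size=300)).round(4)
        ref = self.result(list(zip(terms, ref_p)))
        alt = self.result(list(zip(terms, alt_p)))
        cmp_ = compare_enrichments(ref, alt)
        sig = [i for i in range(300) if ref_p[i] <= 0.01]
        ties = sum(1 for i in sig if alt_p[i] == ref_p[i])
        improved = sum(1 for i in sig if alt_p[i] < ref_p[i])
        assert cmp_.n_ties == ties and cmp_.n_improved == improved


class TestTimeSeriesTermSets:
    def test_plain_difference_when_transient_empty(self):
        sets = TimeSeriesTermSets(
            early_gocats=frozenset("ABC"), early_no_hp=frozenset("B"),
            late_gocats=frozenset(), late_no_hp=frozenset(),
            transient_no_hp=frozenset(), consistent_no_hp=frozenset("AZ"))
        derived = time_series_term_sets(sets)
        assert derived["early_unique"] == {"A", "C"}
        assert derived["early_supported"] == {"A"}

    def test_toy_algebra(self):
        sets = TimeSeriesTermSets(
            early_gocats=frozenset("ABC"), early_no_hp=frozenset("B"),
            late_gocats=frozenset("PQR"), late_no_hp=frozenset("Q"),
            transient_no_hp=frozenset("CR"), consistent_no_hp=frozenset("APZ"))
        derived = time_series_term_sets(sets)
        assert derived["early_unique"] == {"A"}
        assert derived["early_supported"] == {"A"}
        assert derived["late_unique"] == {"P"}
        assert derived["late_supported"] == {"P"}

    def test_supported_subset_invariants(self):
        sets = TimeSeriesTermSets(
            early_gocats=frozenset("ABCDE"), early_no_hp=frozenset("AB"),
            late_gocats=frozenset("VWXYZ"), late_no_hp=frozenset("VW"),
            transient_no_hp=frozenset("CX"), consistent_no_hp=frozenset("DY"))
        derived = time_series_term_sets(sets)
        assert derived["early_supported"] <= derived["early_unique"]
        assert derived["late_supported"] <= derived["late_unique"]
        assert derived["early_supported_full"] <= (
            sets.early_gocats - sets.early_no_hp)
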