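import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paritysig import enrichment as en
from paritysig import reference_data as ref
from paritysig import synthetic_data as sd
from paritysig.io_config import ValidationError


@pytest.fixture()
def flat_ontology():
    onto = en.Ontology.from_edges(
        [("ROOT", "T1"), ("ROOT", "T2")],
        branch_roots={"other": "ROOT"},
    )
    return onto


class TestHypergeometric:
    def test_exact_tail_by_enumeration(self):
        # universe 10, term 4, selection 5, overlap 4:
        # C(4,4)*C(6,1)/C(10,5) = 6/252
        universe = {f"g{i}" for i in range(10)}
        term = {"g0", "g1", "g2", "g3"}
        selection = {"g0", "g1", "g2", "g3", "g4"}
        p = en.hypergeometric_enrichment(selection, universe, term)
        assert p == pytest.approx(6.0 / 252.0)

    def test_empty_term(self):
        universe = {"a", "b"}
        assert en.hypergeometric_enrichment({"a"}, universe, set()) == 1.0

    def test_selection_equals_universe(self):
        universe = {f"g{i}" for i in range(8)}
        term = {"g0", "g1"}
        assert en.hypergeometric_enrichment(universe, universe, term) == 1.0

    def test_subset_violations_rejected(self):
        with pytest.raises(ValidationError):
            en.hypergeometric_enrichment({"x"}, {"a"}, set())
        with pytest.raises(ValidationError):
            en.hypergeometric_enrichment({"a"}, {"a"}, {"z"})

    def test_matches_scipy_tail_on_random_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_u = int(rng.integers(4, 13))
            universe = {f"g{i}" for i in range(n_u)}
            term = set(rng.choice(sorted(universe), rng.integers(0, n_u), replace=False))
            sel = set(rng.choice(sorted(universe), rng.integers(1, n_u), replace=False))
            p = en.hypergeometric_enrichment(sel, universe, term)
            k = len(sel & term)
            # brute-force enumeration of the tail
            brute = sum(
                stats.hypergeom.pmf(i, n_u, len(term), len(sel))
                for i in range(k, min(len(term), len(sel)) + 1)
            )
            assert p == pytest.approx(max(brute, 0.0) if term else 1.0, abs=1e-9)


class TestConditionalEnrichment:
    def test_parent_conditioned_out_by_significant_child(self):
        onto = en.Ontology.from_edges(
            [("ROOT", "parent"), ("parent", "child")],
            branch_roots={"other": "ROOT"},
        )
        genes = [f"g{i}" for i in range(40)]
        ann = pd.DataFrame(
            [(g, "child") for g in genes[:5]]
            + [(g, "ROOT") for g in genes[5:]],
            columns=["gene", "term"],
        )
        selection = set(genes[:5])
        results = {
            r.term: r
            for r in en.conditional_go_enrichment(
                selection, set(genes), onto, ann, alpha=0.01
            )
        }
        assert results["child"].enriched
        assert not results["parent"].enriched
        assert results["parent"].n_term == 0

    def test_flat_ontology_equals_plain_hypergeometric(self, flat_ontology):
        genes = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(4)
        ann = pd.DataFrame(
            [(g, rng.choice(["T1", "T2"])) for g in genes], columns=["gene", "term"]
        )
        selection = set(genes[:8])
        results = en.conditional_go_enrichment(
            selection, set(genes), flat_ontology, ann, alpha=0.01
        )
        term_genes = en.propagate_annotations(ann, flat_ontology)
        for r in results:
            if r.term == "ROOT":
                continue
            plain = en.hypergeometric_enrichment(
                selection, set(genes), term_genes[r.term]
            )
            assert r.p_value == pytest.approx(plain)

    def test_conditional_equals_plain_without_significant_descendants(self):
        # random DAGs: wherever no descendant is significant, conditioning
        # is vacuous
        rng = np.random.default_rng(5)
        for trial in range(10):
            onto, ann = sd.simulate_toy_ontology(4, 40, seed=100 + trial)
            genes = sorted(set(ann["gene"]))
            selection = set(rng.choice(genes, size=10, replace=False))
            results = en.conditional_go_enrichment(
                selection, set(genes), onto, ann, alpha=0.01
            )
            sig = {r.term for r in results if r.enriched}
            term_genes = en.propagate_annotations(ann, onto)
            for r in results:
                if not onto.descendants(r.term) & sig:
                    plain = en.hypergeometric_enrichment(
                        selection, set(genes), term_genes[r.term] & set(genes)
                    )
                    assert r.p_value == pytest.approx(plain)

    def test_planted_immune_selection(self):
        onto, ann = sd.simulate_toy_ontology(5, 100, seed=42)
        immune_leaves = [t for t in onto.terms if t.startswith("IMM:")]
        term_genes = en.propagate_annotations(ann, onto)
        selection = set().union(*(term_genes[t] for t in immune_leaves))
        universe = set(ann["gene"])
        results = en.conditional_go_enrichment(
            selection, universe, onto, ann, alpha=0.01
        )
        enriched = [r for r in results if r.enriched]
        assert any("immune" in r.broad_category for r in enriched)
        assert not any(
            r.broad_category == "developmental" for r in enriched
        )

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            en.Ontology.from_edges([("A", "B"), ("B", "A")])


class TestRollup:
    def test_single_enriched_immune_term_full_cluster(self):
        onto, _, _ = ref.build_rollup_example()
        genes = ["x1", "x2", "x3"]
        ann = pd.DataFrame([(g, "IMM:001") for g in genes], columns=["gene", "term"])
        enriched = [
            en.EnrichmentResult(
                term="IMM:001",
                n_selection=3,
                n_term=3,
                n_universe=3,
                p_value=0.001,
                enriched=True,
                broad_category="immune",
            )
        ]
        rollup = en.rollup_broad_categories(enriched, {"c": genes}, onto, ann)
        assert rollup.percentage("c", "immune") == 100

    def test_published_percentages(self):
        rollup = ref.category_rollup_example()
        t = rollup.table.set_index("cluster")
        assert t.at["transient", "pct_immune"] == 55
        assert t.at["long_term_changing", "pct_immune"] == 32
        assert t.at["long_term_changing", "pct_developmental"] == 24
        assert t.at["long_term_constant", "pct_developmental"] == 56

    def test_invariant_to_order_and_duplicates(self):
        onto, ann, clusters = ref.build_rollup_example()
        universe = set(ann["gene"])
        cluster = "transient"
        enriched = en.conditional_go_enrichment(
            set(clusters[cluster]), universe, onto, ann, alpha=0.01
        )
        base = en.rollup_broad_categories(
            enriched, {cluster: clusters[cluster]}, onto, ann
        )
        shuffled = list(reversed(clusters[cluster]))
        dup_ann = pd.concat([ann, ann.iloc[:50]], ignore_index=True)
        again = en.rollup_broad_categories(
            enriched, {cluster: shuffled}, onto, dup_ann
        )
        pd.testing.assert_frame_equal(base.table, again.table)

    def test_gene_may_count_in_both_categories(self):
        rollup = ref.category_rollup_example()
        t = rollup.table.set_index("cluster")
        row = t.loc["long_term_changing"]
        # 7 genes enriched both branches: counts overlap
        assert row["n_developmental"] + row["n_immune"] > len(
            set(ref.LONGTERM_CHANGING_DEVELOPMENTAL)
            | set(ref.LONGTERM_CHANGING_IMMUNE)
        )


class TestCategoryAssociation:
    def _rollup(self, counts):
        rows = []
        for i, (imm, dev) in enumerate(counts):
            rows.append(
                {
                    "cluster": f"c{i}",
                    "n_annotated": imm + dev,
                    "n_developmental": dev,
                    "n_immune": imm,
                    "pct_developmental": 0,
                    "pct_immune": 0,
                }
            )
        return en.CategoryRollup(table=pd.DataFrame(rows))

    def test_published_counts_give_p_below_point_001(self):
        chi2, p = en.category_association_test(
            self._rollup([(41, 12), (25, 19), (6, 28)])
        )
        assert p < 0.001

    def test_homogeneous_table_statistic_zero(self):
        chi2, p = en.category_association_test(
            self._rollup([(10, 10), (10, 10), (10, 10)])
        )
        assert chi2 == 0.0
        assert p == 1.0

    def test_identical_proportions(self):
        chi2, p = en.category_association_test(
            self._rollup([(20, 10), (40, 20), (8, 4)])
        )
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            counts = rng.integers(1, 60, size=(3, 2))
            chi2, p = en.category_association_test(
                self._rollup([tuple(row) for row in counts])
            )
            ref_chi2, ref_p, dof, _ = stats.chi2_contingency(
                counts, correction=False
            )
            assert dof == 2
            assert chi2 == pytest.approx(ref_chi2)
            assert p == pytest.approx(ref_p)

    def test_small_expected_uses_seeded_fallback(self):
        a = en.category_association_test(self._rollup([(1, 0), (0, 1), (1, 1)]), seed=1)
        b = en.category_association_test(self._rollup([(1, 0), (0, 1), (1, 1)]), seed=1)
        assert a == b
        assert 0.0 <= a[1] <= 1.0
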