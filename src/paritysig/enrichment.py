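"""Conditional hypergeometric term enrichment over an ontology DAG, with
broad-category rollups and a cross-cluster association test.

Terms are processed leaves-upward; when a term is tested, genes already
attributed to its significant descendants are removed from its gene set, so
a parent explained entirely by one significant child is not re-reported.
Enriched terms are grouped under three designated branch roots
(developmental process, immune response, other) and per-cluster category
percentages are computed against the cluster's GO-annotated gene total.
A gene annotated under both branch roots counts in both categories, so
percentages may sum above 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from paritysig.io_config import ValidationError

logger = logging.getLogger(__name__)

BROAD_CATEGORIES = ("developmental", "immune", "other")


@dataclass
class Ontology:
    """Rooted DAG of terms with three designated branch roots."""

    graph: nx.DiGraph  # edges parent -> child
    names: dict[str, str] = field(default_factory=dict)
    branch_roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValidationError("ontology edges contain a cycle")
        unknown = set(self.branch_roots.values()) - set(self.graph.nodes)
        if unknown:
            raise ValidationError(f"branch root(s) not in ontology: {sorted(unknown)}")

    @classmethod
    def from_edges(
        cls,
        edges,
        names: dict[str, str] | None = None,
        branch_roots: dict[str, str] | None = None,
    ) -> "Ontology":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(graph=g, names=names or {}, branch_roots=branch_roots or {})

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        # graph edges run parent -> child, so ontology ancestors are graph
        # ancestors in networkx's sense
        return nx.ancestors(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)

    def branches_of(self, term: str) -> set[str]:
        """Branch keys whose root contains this term (root itself -> other)."""
        up = self.ancestors(term) | {term}
        hit = {
            key
            for key, root in self.branch_roots.items()
            if key != "other" and root in up
        }
        return hit or {"other"}


def propagate_annotations(
    annotation: pd.DataFrame, ontology: Ontology
) -> dict[str, set[str]]:
    """Gene sets per term, with annotations propagated to all ancestors."""
    term_genes: dict[str, set[str]] = {t: set() for t in ontology.terms}
    for gene, term in zip(annotation["gene"], annotation["term"]):
        if term not in term_genes:
            raise ValidationError(f"annotation references unknown term {term!r}")
        term_genes[term].add(gene)
        for anc in ontology.ancestors(term):
            term_genes[anc].add(gene)
    return term_genes


@dataclass
class EnrichmentResult:
    term: str
    n_selection: int  # genes from the selection hitting the (conditional) term set
    n_term: int  # (conditional) term gene count within the universe
    n_universe: int
    p_value: float
    enriched: bool
    broad_category: str

    def __post_init__(self) -> None:
        if not self.n_selection <= self.n_term <= self.n_universe:
            raise ValidationError("enrichment counts must be nested")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p value outside [0,1]")


@dataclass
class CategoryRollup:
    """Per-cluster broad-category counts and whole-percent shares."""

    table: pd.DataFrame  # cluster, n_annotated, n_developmental, n_immune, pcts

    def percentage(self, cluster: str, category: str) -> int:
        row = self.table.set_index("cluster").loc[cluster]
        return int(row[f"pct_{category}"])


def hypergeometric_enrichment(
    selection: set[str], universe: set[str], term_genes: set[str]
) -> float:
    """Upper-tail probability of at least the observed selection/term overlap."""
    selection, universe, term_genes = set(selection), set(universe), set(term_genes)
    if not selection <= universe:
        raise ValidationError("selection must be a subset of the universe")
    if not term_genes <= universe:
        raise ValidationError("term genes must be a subset of the universe")
    big_k = len(term_genes)
    if big_k == 0:
        return 1.0
    k = len(selection & term_genes)
    return float(stats.hypergeom.sf(k - 1, len(universe), big_k, len(selection)))


def conditional_go_enrichment(
    selection: set[str],
    universe: set[str],
    ontology: Ontology,
    annotation: pd.DataFrame,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Leaves-upward conditional hypergeometric tests over the DAG.

    Returns a result for every term carrying at least one universe gene;
    ``enriched`` flags terms with conditional p < alpha.
    """
    selection, universe = set(selection), set(universe)
    if not selection <= universe:
        raise ValidationError("selection must be a subset of the universe")
    term_genes = propagate_annotations(annotation, ontology)
    term_genes = {t: gs & universe for t, gs in term_genes.items()}

    order = list(reversed(list(nx.topological_sort(ontology.graph))))
    significant: set[str] = set()
    results: list[EnrichmentResult] = []
    for term in order:
        genes = term_genes[term]
        if not genes:
            continue
        claimed: set[str] = set()
        for desc in ontology.descendants(term) & significant:
            claimed |= term_genes[desc]
        effective = genes - claimed
        p = hypergeometric_enrichment(selection, universe, effective)
        enriched = p < alpha
        if enriched:
            significant.add(term)
        branches = ontology.branches_of(term)
        results.append(
            EnrichmentResult(
                term=term,
                n_selection=len(selection & effective),
                n_term=len(effective),
                n_universe=len(universe),
                p_value=p,
                enriched=enriched,
                broad_category=",".join(sorted(branches)),
            )
        )
    return results


def rollup_broad_categories(
    enriched: list[EnrichmentResult],
    cluster_genes: dict[str, list[str]],
    ontology: Ontology,
    annotation: pd.DataFrame,
) -> CategoryRollup:
    """Count, per cluster, genes attributed to enriched terms under each
    branch root.

    A gene counts toward a category iff it is annotated (after ancestor
    propagation) to at least one enriched term under that branch; the
    denominator is the cluster's genes carrying any annotation.  Percentages
    are whole percents, rounded half away from zero.
    """
    term_genes = propagate_annotations(annotation, ontology)
    annotated_genes = set(annotation["gene"])
    enriched_terms = [r.term for r in enriched if r.enriched]
    by_branch: dict[str, set[str]] = {"developmental": set(), "immune": set()}
    for term in enriched_terms:
        for b in ontology.branches_of(term):
            if b in by_branch:
                by_branch[b] |= term_genes[term]

    rows = []
    for cluster, genes in cluster_genes.items():
        genes = set(genes)
        n_annotated = len(genes & annotated_genes)
        n_dev = len(genes & by_branch["developmental"])
        n_imm = len(genes & by_branch["immune"])
        if n_annotated == 0:
            raise ValueError(f"cluster {cluster!r} has no annotated genes")
        rows.append(
            {
                "cluster": cluster,
                "n_annotated": n_annotated,
                "n_developmental": n_dev,
                "n_immune": n_imm,
                "pct_developmental": _round_half_away(100.0 * n_dev / n_annotated),
                "pct_immune": _round_half_away(100.0 * n_imm / n_annotated),
            }
        )
    return CategoryRollup(table=pd.DataFrame(rows))


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def category_association_test(
    rollup: CategoryRollup,
    seed: int = 0,
    n_permutations: int = 20000,
) -> tuple[float, float]:
    """Pearson chi-squared on the clusters x (immune, developmental) counts.

    Falls back to a seeded Monte-Carlo test with fixed margins when any
    expected cell drops below 1.
    """
    counts = rollup.table[["n_immune", "n_developmental"]].to_numpy(dtype=float)
    if counts.shape[1] != 2 or counts.shape[0] < 2:
        raise ValueError("need a clusters x 2 count table")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty count table")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(cells.sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if (expected < 1.0).any():
        logger.warning("expected cell below 1; using Monte-Carlo fallback")
        rng = np.random.default_rng(seed)
        samples = stats.random_table(
            row.ravel().astype(int), col.ravel().astype(int)
        ).rvs(size=n_permutations, random_state=rng)
        stats_null = ((samples - expected) ** 2 / np.where(expected > 0, expected, 1))
        null = stats_null.sum(axis=(1, 2))
        p = float((null >= chi2 - 1e-12).mean())
        return chi2, p
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, p
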