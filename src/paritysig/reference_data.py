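"""Published worked example for the broad-category rollup.

Gene-category lists from a premenopausal breast parity-signature microarray
study: for each temporal cluster of upregulated genes, the gene symbols that
enriched developmental-process and immune-response ontology terms, plus the
per-cluster totals of genes carrying at least one ontology annotation.
Genes may appear in both category lists of a cluster (they enriched both
branches).  These tables drive an end-to-end example of
:func:`paritysig.enrichment.rollup_broad_categories` with known expected
percentages.
"""

from __future__ import annotations

import pandas as pd

from paritysig.enrichment import (
    CategoryRollup,
    Ontology,
    conditional_go_enrichment,
    rollup_broad_categories,
)

TRANSIENT_DEVELOPMENTAL = [
    "ANXA1", "CAMK4", "CD8A", "CD27", "EOMES", "ITK", "JAK3", "LCK",
    "PTPN22", "PTPRC", "SASH3", "THEMIS",
]

TRANSIENT_IMMUNE = [
    "ANXA1", "CAMK4", "CCL5", "CD8A", "CD27", "CD48", "CD96", "CD247",
    "CORO1A", "CST7", "CXCL14", "CXCL9", "EOMES", "FASLG", "FYB", "GZMA",
    "HCST", "IGLC1", "IKZF1", "IL16", "IL7R", "ITGAL", "ITK", "JAK3",
    "KLHL6", "LAT", "LAX1", "LCK", "LCP2", "LY9", "PRKCB", "PTPN22",
    "PTPRC", "SASH3", "SELPLG", "SEMA4D", "SH2D1A", "SLAMF1", "THEMIS",
    "TRAC", "XCL1",
]

LONGTERM_CHANGING_DEVELOPMENTAL = [
    "C3", "CCR2", "CD2", "CXCL10", "DACT1", "DKK3", "EAF2", "EPHA7",
    "FGF1", "FGFR2", "HCLS1", "HLA-DOA", "IL12RB1", "IRF4", "LAMA2",
    "OSR2", "PDGFRA", "SIPA1L1", "SPHK1",
]

LONGTERM_CHANGING_IMMUNE = [
    "APOBEC3G", "BLNK", "C1S", "C3", "CCR2", "CD2", "CD3D", "CD38",
    "CRTAM", "CXCL10", "GPR183", "HLA-DOA", "HLA-DPB1", "IGKC", "IL12RB1",
    "IRF4", "LPXN", "MZB1", "NFATC2", "PAWR", "POU2AF1", "PRKCQ",
    "SAMSN1", "SLAMF7", "TRBC1",
]

LONGTERM_CONSTANT_DEVELOPMENTAL = [
    "BHLHE22", "CCL19", "CCL2", "DCN", "DSC3", "EGR3", "EPHB1", "FHL2",
    "FZD8", "GLI3", "GPR65", "KCNMA1", "KIF5C", "KRT5", "MYLK", "NFASC",
    "PRKCA", "SALL1", "SDC1", "SULF1", "SULF2", "TAGLN", "TREM2", "TYMS",
    "VCAM1", "WIPF3", "XDH", "ZIC1",
]

LONGTERM_CONSTANT_IMMUNE = [
    "CCL2", "CCL19", "GLI3", "HLA-DPA1", "HLA-DRA", "VCAM1",
]

#: published per-cluster totals of genes with at least one ontology annotation
ANNOTATED_TOTALS = {
    "transient": 74,
    "long_term_changing": 79,
    "long_term_constant": 50,
}

CATEGORY_LISTS = {
    "transient": {
        "developmental": TRANSIENT_DEVELOPMENTAL,
        "immune": TRANSIENT_IMMUNE,
    },
    "long_term_changing": {
        "developmental": LONGTERM_CHANGING_DEVELOPMENTAL,
        "immune": LONGTERM_CHANGING_IMMUNE,
    },
    "long_term_constant": {
        "developmental": LONGTERM_CONSTANT_DEVELOPMENTAL,
        "immune": LONGTERM_CONSTANT_IMMUNE,
    },
}

#: published group medians of CD3D-positive cell percentages (parous,
#: nulliparous) from the matching immunohistochemistry substudy
CD3D_MEDIANS = (3.28, 1.62)


def build_rollup_example(
    n_background: int = 300,
) -> tuple[Ontology, pd.DataFrame, dict[str, list[str]]]:
    """Assemble rollup inputs reproducing the published category percentages.

    Builds a minimal ontology (root, three branch roots, one leaf each),
    annotates the listed genes to the developmental / immune leaves and pads
    each cluster with filler genes annotated only under the 'other' branch
    so the per-cluster annotated totals match the published denominators.
    ``n_background`` additional universe-only genes (annotated under
    'other') stand in for the filtered probe universe, so the category
    terms are genuinely enriched within each cluster.
    """
    ontology = Ontology.from_edges(
        [
            ("ROOT", "DEV"),
            ("ROOT", "IMM"),
            ("ROOT", "OTH"),
            ("DEV", "DEV:001"),
            ("IMM", "IMM:001"),
            ("OTH", "OTH:001"),
        ],
        names={
            "ROOT": "biological process",
            "DEV": "developmental process",
            "IMM": "immune response",
            "OTH": "other",
        },
        branch_roots={"developmental": "DEV", "immune": "IMM", "other": "OTH"},
    )
    records: list[tuple[str, str]] = []
    cluster_genes: dict[str, list[str]] = {}
    for cluster, lists in CATEGORY_LISTS.items():
        listed = sorted(set(lists["developmental"]) | set(lists["immune"]))
        n_filler = ANNOTATED_TOTALS[cluster] - len(listed)
        fillers = [f"{cluster}_filler_{i + 1:02d}" for i in range(n_filler)]
        cluster_genes[cluster] = listed + fillers
        records.extend((g, "DEV:001") for g in lists["developmental"])
        records.extend((g, "IMM:001") for g in lists["immune"])
        records.extend((g, "OTH:001") for g in fillers)
    records.extend(
        (f"background_{i + 1:03d}", "OTH:001") for i in range(n_background)
    )
    annotation = pd.DataFrame(records, columns=["gene", "term"])
    return ontology, annotation, cluster_genes


def category_rollup_example(alpha: float = 0.01) -> CategoryRollup:
    """Run the enrichment + rollup pipeline on the published lists.

    Enrichment is computed per cluster (selection = the cluster's genes,
    universe = all genes of the example) and each cluster's rollup row uses
    its own enriched terms.
    """
    ontology, annotation, cluster_genes = build_rollup_example()
    universe = set(annotation["gene"])
    rows = []
    for cluster, genes in cluster_genes.items():
        enriched = conditional_go_enrichment(
            set(genes), universe, ontology, annotation, alpha=alpha
        )
        rollup = rollup_broad_categories(
            enriched, {cluster: genes}, ontology, annotation
        )
        rows.append(rollup.table)
    return CategoryRollup(table=pd.concat(rows, ignore_index=True))
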