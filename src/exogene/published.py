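"""Published prioritized-variant rankings (worked-example data).

The packaged table transcribes the ranked gene/variant list reported by
the PEG cotton-cluster case-only analysis: 36 prioritized variant
entries across 26 genes, each with its enrichment p-value(s), the
subpopulation(s) the variant was enriched in, and the per-gene composite
disease-severity x pesticide-exposure score (averaged over a gene's
entries).  It is used as a fixed worked example for the reporting
machinery; the composite-score column is as printed, not recomputed
(the underlying per-carrier scores are not public).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_rankings", "recount_published_rankings"]


def load_published_rankings() -> pd.DataFrame:
    """Variant-level table: gene, variant, populations, p_value,
    gene_composite (one row per variant; dual-population entries carry
    semicolon-separated populations/p-values)."""
    with resources.files("exogene").joinpath(
        "data/peg_prioritized_variants.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def recount_published_rankings(table: pd.DataFrame | None = None) -> dict:
    """Recompute the headline counts from the published ranking table.

    Everything is derived from the table itself: variant entries, genes,
    multi-variant genes, dual-population entries, and the extrema of the
    per-gene composite column (with the genes attaining them).
    """
    t = load_published_rankings() if table is None else table
    genes = t.groupby("gene")
    n_variants = len(t)
    per_gene = genes.agg(
        n_variants=("variant", "nunique"),
        composite=("gene_composite", "first"),
    ).reset_index()
    dual = t["populations"].str.contains(";")
    imax = per_gene["composite"].idxmax()
    imin = per_gene["composite"].idxmin()
    return {
        "n_variants": int(n_variants),
        "n_genes": int(len(per_gene)),
        "n_multi_variant_genes": int((per_gene["n_variants"] >= 2).sum()),
        "n_dual_population_variants": int(dual.sum()),
        "composite_max": float(per_gene.loc[imax, "composite"]),
        "composite_max_gene": str(per_gene.loc[imax, "gene"]),
        "composite_min": float(per_gene.loc[imin, "composite"]),
        "composite_min_gene": str(per_gene.loc[imin, "gene"]),
    }
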