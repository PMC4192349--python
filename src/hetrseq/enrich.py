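"""Genome-relative functional-category fold enrichment.

For each category c, the fold enrichment of a target-gene set is

    fold(c) = (|hits in c| / |hit genes|) / (|genome genes in c| / |genome genes|)

with a hypergeometric upper-tail p-value attached for rigor (the
underlying comparison is enrichment over a random draw of the same
number of genes from the genome).  Genes may carry several categories;
the hit-fraction denominator is the number of distinct hit genes.  No
multiple-testing correction is applied across categories; p-values are
reported raw.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Set

import pandas as pd
from scipy import stats

COLUMNS = [
    "category",
    "n_hits",
    "n_genome",
    "hit_fraction",
    "genome_fraction",
    "fold",
    "p_value",
]


def hypergeometric_tail(n_genome: int, n_category: int, n_hits: int, k_observed: int) -> float:
    """P(X >= k_observed) for X ~ Hypergeometric(n_genome, n_category,
    n_hits), computed via the survival function in log space."""
    if min(n_genome, n_category, n_hits, k_observed) < 0:
        raise ValueError("counts must be non-negative")
    if n_category > n_genome or n_hits > n_genome:
        raise ValueError("category/draw size exceeds population")
    if k_observed > min(n_category, n_hits):
        raise ValueError("k_observed exceeds min(n_category, n_hits)")
    if k_observed == 0:
        return 1.0
    return float(stats.hypergeom.sf(k_observed - 1, n_genome, n_category, n_hits))


def category_fold_enrichment(
    hit_genes: Iterable[str],
    annotations: Dict[str, Set[str]],
    genome_genes: Iterable[str],
) -> pd.DataFrame:
    """Fold enrichment of every category among the hit genes relative to
    its genome-wide proportion.  Categories absent from the hits are
    reported with fold 0."""
    hits = set(hit_genes)
    genome = set(genome_genes)
    if not hits:
        raise ValueError("empty hit-gene set")
    if not genome:
        raise ValueError("empty genome-gene set")
    stray = hits - genome
    if stray:
        raise ValueError(f"hit genes missing from the genome set: {sorted(stray)[:5]}")
    categories = sorted({c for g in genome for c in annotations.get(g, ())})
    rows = []
    for cat in categories:
        genome_in = {g for g in genome if cat in annotations.get(g, ())}
        hits_in = hits & genome_in
        hit_frac = len(hits_in) / len(hits)
        genome_frac = len(genome_in) / len(genome)
        fold = hit_frac / genome_frac if genome_frac > 0 else 0.0
        p = hypergeometric_tail(len(genome), len(genome_in), len(hits), len(hits_in))
        rows.append(
            {
                "category": cat,
                "n_hits": len(hits_in),
                "n_genome": len(genome_in),
                "hit_fraction": hit_frac,
                "genome_fraction": genome_frac,
                "fold": fold,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows, columns=COLUMNS)
    return table.sort_values("fold", ascending=False, kind="stable").reset_index(drop=True)


def flag_enriched(table: pd.DataFrame, min_fold: float = 3.0) -> List[str]:
    """Categories enriched at least ``min_fold`` over their genome-wide
    proportion (boundary inclusive)."""
    return table.loc[table["fold"] >= min_fold, "category"].tolist()
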