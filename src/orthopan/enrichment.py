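"""GO over-representation testing of a gene set against the pangenome.

Singular enrichment analysis: for each GO term annotated to at least
``min_mapping`` background genes, the one-sided hypergeometric tail
P(X >= k) tests whether the term is over-represented among the subset's
genes, and Benjamini-Yekutieli controls the FDR across tested terms.
The background is the set of pangenome genes carrying at least one GO
term (and the subset is restricted the same way), so untestable genes
never dilute the contingency tables.
"""
from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .classify import CategoryAssignment, Category
from .datatypes import GoAnnotation, OrthogroupMatrix


def enrich(
    subset_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation: GoAnnotation,
    min_mapping: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test GO terms for over-representation in ``subset_genes``.

    Returns one row per tested term with columns term, label, k, n, K,
    N, fold (= (k/n)/(K/N)), p_value, adjusted_p, significant; sorted by
    adjusted_p then term ID.  Terms with K < ``min_mapping`` background
    genes are dropped.
    """
    subset = set(subset_genes)
    background = set(background_genes)
    if not subset:
        raise ValueError("subset gene set is empty")
    offenders = subset - background
    if offenders:
        raise ValueError(
            f"{len(offenders)} subset gene(s) absent from background, "
            f"e.g. {sorted(offenders)[:5]}"
        )
    annotated_bg = annotation.annotated_genes(background)
    if not annotated_bg:
        raise ValueError("annotation covers no background gene")
    annotated_sub = annotation.annotated_genes(subset)
    N, n = len(annotated_bg), len(annotated_sub)

    K_of: Counter[str] = Counter()
    for g in annotated_bg:
        K_of.update(annotation.term_of[g])
    k_of: Counter[str] = Counter()
    for g in annotated_sub:
        k_of.update(annotation.term_of[g])

    rows = []
    for term, K in K_of.items():
        if K < min_mapping:
            continue
        k = k_of.get(term, 0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else 0.0
        label = (annotation.term_names or {}).get(term, "")
        rows.append((term, label, k, n, K, N, fold, p))
    df = pd.DataFrame(
        rows, columns=["term", "label", "k", "n", "K", "N", "fold", "p_value"]
    )
    if df.empty:
        warnings.warn("no GO term met the minimum background mapping; empty table")
        df["adjusted_p"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    reject, adj, _, _ = multipletests(df["p_value"].to_numpy(), alpha=alpha, method="fdr_by")
    df["adjusted_p"] = adj
    df["significant"] = reject
    return df.sort_values(["adjusted_p", "term"], kind="mergesort").reset_index(drop=True)


def category_gene_sets(
    matrix: OrthogroupMatrix, assignment: CategoryAssignment
) -> dict[Category, set[str]]:
    """Union of member-orthogroup gene IDs per pangenome category.

    The pangenome background for enrichment is the union over all
    categories (``matrix.all_gene_ids()``).
    """
    if matrix.gene_ids is None:
        raise ValueError(
            "matrix carries no gene IDs; read the Orthogroups.tsv (gene list) dialect"
        )
    sets: dict[Category, set[str]] = {c: set() for c in Category}
    for og in matrix.orthogroup_ids:
        cat = assignment.category_of[og]
        for cell in matrix.gene_ids.loc[og]:
            sets[cat].update(cell)
    for cat, genes in sets.items():
        if not genes:
            warnings.warn(f"category {cat.value} has no genes; enrichment will be skipped")
    return sets
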