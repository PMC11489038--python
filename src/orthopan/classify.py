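"""Pangenome category assignment from orthogroup presence patterns.

An orthogroup's category is a pure function of which haplomes carry it
and how those haplomes group into accessions.  For an N-haplome panel:

* **core** — present in all N haplomes;
* **soft-core** — present in any combination of N-1 haplomes;
* **accessory** — present in 3..N-2 haplomes, or in exactly 2 haplomes
  of *different* accessions;
* **accession-specific** — present in exactly 2 haplomes of the *same*
  accession;
* **haplome-specific** — present in a single haplome.

The rules were formulated for N=8; for smaller panels where the ranges
collide they are evaluated in the order above on descending presence
size, with soft-core applying only when N-1 >= 3 (so a 2-haplome panel
yields only core and haplome-specific).  A warning is emitted for
panels with N != 8.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import HaplomePanel, OrthogroupMatrix


class Category(str, Enum):
    CORE = "core"
    SOFT_CORE = "soft_core"
    ACCESSORY = "accessory"
    ACCESSION_SPECIFIC = "accession_specific"
    HAPLOME_SPECIFIC = "haplome_specific"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories from narrowest to broadest; adding a haplome to a presence
#: set never moves an orthogroup down this order.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.HAPLOME_SPECIFIC,
    Category.ACCESSION_SPECIFIC,
    Category.ACCESSORY,
    Category.SOFT_CORE,
    Category.CORE,
)

#: Display order (broadest first), matching how compositions are reported.
CATEGORIES: tuple[Category, ...] = tuple(reversed(CATEGORY_ORDER))


@dataclass
class CategoryAssignment:
    """Partition of a matrix's orthogroups into the five categories."""

    category_of: dict[str, Category]
    presence_of: dict[str, frozenset[str]]

    def members(self, category: Category) -> list[str]:
        return [og for og, c in self.category_of.items() if c is category]


def _warn_if_nonstandard(panel: HaplomePanel) -> None:
    if panel.n_haplomes != 8:
        warnings.warn(
            f"category rules were formulated for 8-haplome panels; applying the "
            f"documented generalization to N={panel.n_haplomes}"
        )


def classify_orthogroup(presence: Iterable[str], panel: HaplomePanel) -> Category:
    """Classify a single presence pattern (set of haplome IDs)."""
    pres = frozenset(presence)
    if not pres:
        raise ValueError("presence set is empty")
    unknown = pres - set(panel.haplome_ids)
    if unknown:
        raise ValueError(f"haplome(s) not in panel: {sorted(unknown)}")
    n = panel.n_haplomes
    size = len(pres)
    if size == n:
        return Category.CORE
    if size == n - 1 and n - 1 >= 3:
        return Category.SOFT_CORE
    if 3 <= size <= n - 2:
        return Category.ACCESSORY
    if size == 2:
        a, b = pres
        if panel.accession_of[a] != panel.accession_of[b]:
            return Category.ACCESSORY
        return Category.ACCESSION_SPECIFIC
    return Category.HAPLOME_SPECIFIC


def classify_matrix(matrix: OrthogroupMatrix, panel: HaplomePanel) -> CategoryAssignment:
    """Vectorized classification of every orthogroup in a matrix."""
    matrix.validate_against(panel)
    _warn_if_nonstandard(panel)
    n = panel.n_haplomes
    presence = matrix.presence.to_numpy()
    sizes = presence.sum(axis=1)
    if (sizes == 0).any():  # validate_against already rejects; belt and braces
        raise ValueError("orthogroup with empty presence set")

    acc_ids = panel.accession_ids
    onehot = np.array(
        [[panel.accession_of[h] == a for a in acc_ids] for h in panel.haplome_ids],
        dtype=bool,
    )
    n_accessions = ((presence @ onehot) > 0).sum(axis=1)

    cats = np.empty(len(sizes), dtype=object)
    cats[sizes == 1] = Category.HAPLOME_SPECIFIC
    two = sizes == 2
    cats[two & (n_accessions == 1)] = Category.ACCESSION_SPECIFIC
    cats[two & (n_accessions > 1)] = Category.ACCESSORY
    cats[(sizes >= 3) & (sizes <= n - 2)] = Category.ACCESSORY
    if n - 1 >= 3:
        cats[sizes == n - 1] = Category.SOFT_CORE
    cats[sizes == n] = Category.CORE

    haps = np.array(panel.haplome_ids, dtype=object)
    category_of = dict(zip(matrix.orthogroup_ids, cats))
    presence_of = {
        og: frozenset(haps[row]) for og, row in zip(matrix.orthogroup_ids, presence)
    }
    return CategoryAssignment(category_of, presence_of)


@dataclass
class PangenomeSummary:
    """Per-category orthogroup counts, gene totals, and gene percentages.

    Gene totals count genes in all haplomes (the pangenome gene total is
    the sum over orthogroups of their counts in every haplome), and
    percentages are 100 * gene_count / total, rounded half-up to one
    decimal.
    """

    orthogroup_count: dict[Category, int]
    gene_count: dict[Category, int]
    gene_percent: dict[Category, float]

    @property
    def total_orthogroups(self) -> int:
        return sum(self.orthogroup_count.values())

    @property
    def total_genes(self) -> int:
        return sum(self.gene_count.values())

    @classmethod
    def from_counts(
        cls,
        orthogroup_count: Mapping[Category, int],
        gene_count: Mapping[Category, int],
    ) -> "PangenomeSummary":
        og = {c: int(orthogroup_count.get(c, 0)) for c in CATEGORIES}
        gn = {c: int(gene_count.get(c, 0)) for c in CATEGORIES}
        total = sum(gn.values())
        pct = {
            c: float(
                (Decimal(100 * gn[c]) / Decimal(total)).quantize(
                    Decimal("0.1"), rounding=ROUND_HALF_UP
                )
            )
            if total
            else 0.0
            for c in CATEGORIES
        }
        return cls(og, gn, pct)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": c.value,
                "orthogroup_count": self.orthogroup_count[c],
                "gene_count": self.gene_count[c],
                "gene_percent": self.gene_percent[c],
            }
            for c in CATEGORIES
        ]
        rows.append(
            {
                "category": "pangenome",
                "orthogroup_count": self.total_orthogroups,
                "gene_count": self.total_genes,
                "gene_percent": 100.0 if self.total_genes else 0.0,
            }
        )
        return pd.DataFrame(rows)


def summarize(matrix: OrthogroupMatrix, assignment: CategoryAssignment) -> PangenomeSummary:
    """Aggregate a classified matrix into the category composition table."""
    missing = set(matrix.orthogroup_ids) - set(assignment.category_of)
    if missing:
        raise ValueError(f"orthogroup(s) missing from assignment: {sorted(missing)[:5]}")
    row_totals = matrix.counts.sum(axis=1)
    og_count: dict[Category, int] = {c: 0 for c in CATEGORIES}
    gene_count: dict[Category, int] = {c: 0 for c in CATEGORIES}
    for og in matrix.orthogroup_ids:
        c = assignment.category_of[og]
        og_count[c] += 1
        gene_count[c] += int(row_totals[og])
    return PangenomeSummary.from_counts(og_count, gene_count)


def classification_frame(matrix: OrthogroupMatrix, assignment: CategoryAssignment) -> pd.DataFrame:
    """Per-orthogroup table: ID, presence size, haplome list, category."""
    rows = []
    for og in matrix.orthogroup_ids:
        pres = assignment.presence_of[og]
        ordered = [h for h in matrix.haplome_ids if h in pres]
        rows.append(
            {
                "orthogroup_id": og,
                "n_haplomes": len(pres),
                "haplome_list": ",".join(ordered),
                "category": assignment.category_of[og].value,
            }
        )
    return pd.DataFrame(rows)
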