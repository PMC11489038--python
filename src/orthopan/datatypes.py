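"""Core domain containers shared across the pipeline.

Coordinates are uniformly 0-based half-open throughout the package;
1-based inclusive file formats (GFF3, SyRI) are converted at the I/O
boundary and converted back on writing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

GO_TERM_RE = re.compile(r"^GO:\d{7}$")


class SVType(str, Enum):
    """The four structural-variant classes counted by the analysis."""

    INS = "INS"
    DEL = "DEL"
    INV = "INV"
    TRL = "TRL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class HaplomePanel:
    """The haplome/accession design of the panel under analysis.

    A *haplome* is one haplotype-resolved assembly; each *accession*
    (sampled individual) contributes one or more haplomes.  The study
    design this package was built around is 8 haplomes in 4 accessions
    of 2 haplomes each, but any shape is accepted.
    """

    haplome_ids: tuple[str, ...]
    accession_of: Mapping[str, str]
    species_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.haplome_ids)) != len(self.haplome_ids):
            dupes = sorted({h for h in self.haplome_ids if list(self.haplome_ids).count(h) > 1})
            raise ValueError(f"duplicate haplome ID(s): {', '.join(dupes)}")
        if not self.haplome_ids:
            raise ValueError("panel must contain at least one haplome")
        for hap in self.haplome_ids:
            acc = self.accession_of.get(hap)
            if not acc:
                raise ValueError(f"haplome {hap!r} has no accession assigned")
        extra = set(self.accession_of) - set(self.haplome_ids)
        if extra:
            raise ValueError(f"accession map lists unknown haplome(s): {sorted(extra)}")

    @property
    def n_haplomes(self) -> int:
        return len(self.haplome_ids)

    @property
    def accession_ids(self) -> tuple[str, ...]:
        """Accessions in order of first appearance."""
        seen: dict[str, None] = {}
        for hap in self.haplome_ids:
            seen.setdefault(self.accession_of[hap], None)
        return tuple(seen)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def haplomes_of(self, accession: str) -> tuple[str, ...]:
        return tuple(h for h in self.haplome_ids if self.accession_of[h] == accession)


@dataclass
class OrthogroupMatrix:
    """Orthogroup x haplome gene-count matrix, optionally carrying gene IDs.

    ``counts`` is indexed by orthogroup ID with one integer column per
    haplome.  When present, ``gene_ids`` has the same shape with each
    cell a tuple of gene ID strings whose length equals the count.
    """

    counts: pd.DataFrame
    gene_ids: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate orthogroup ID(s): {dupes}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("gene counts must be nonnegative")
        if self.gene_ids is not None:
            if not self.gene_ids.index.equals(self.counts.index) or not (
                self.gene_ids.columns.equals(self.counts.columns)
            ):
                raise ValueError("gene_ids frame must be aligned with counts")
            lens = self.gene_ids.map(len)
            if not lens.equals(self.counts.astype(int)):
                raise ValueError("gene_ids cell lengths must equal counts")

    @property
    def orthogroup_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def haplome_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_orthogroups(self) -> int:
        return len(self.counts)

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence matrix (count >= 1)."""
        return self.counts > 0

    def validate_against(self, panel: HaplomePanel) -> None:
        if list(self.counts.columns) != list(panel.haplome_ids):
            raise ValueError(
                "matrix haplome axis does not match panel order: "
                f"{list(self.counts.columns)} vs {list(panel.haplome_ids)}"
            )
        empty = self.counts.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"orthogroup(s) with no genes in any haplome: {self.counts.index[empty].tolist()}"
            )

    def all_gene_ids(self) -> set[str]:
        """Union of gene IDs over every orthogroup and haplome."""
        if self.gene_ids is None:
            raise ValueError(
                "matrix carries no gene IDs; read the Orthogroups.tsv (gene list) "
                "dialect rather than GeneCount.tsv"
            )
        out: set[str] = set()
        for cell in self.gene_ids.to_numpy().ravel():
            out.update(cell)
        return out


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval on a reference chromosome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid gene interval {self.chrom}:{self.start}-{self.end} "
                f"(need 0 <= start < end)"
            )
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SVRecord:
    """A typed structural variant placed on the reference (0-based half-open).

    ``length`` is the variant's size in bp, which for insertions exceeds
    the reference span; query-side coordinates are kept when the source
    file provides them.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    sv_type: SVType
    length: int
    haplome_id: str = ""
    query_chrom: str | None = None
    query_start: int | None = None
    query_end: int | None = None

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError(
                f"SV with ref_start > ref_end: {self.ref_chrom}:{self.ref_start}-{self.ref_end}"
            )
        if self.length < 1:
            raise ValueError(f"SV length must be >= 1, got {self.length}")
        if not isinstance(self.sv_type, SVType):
            raise ValueError(f"sv_type must be an SVType, got {self.sv_type!r}")


@dataclass
class GoAnnotation:
    """Gene -> GO term mapping (sets may be empty)."""

    term_of: dict[str, frozenset[str]]
    term_names: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for gene, terms in self.term_of.items():
            for t in terms:
                if not GO_TERM_RE.match(t):
                    raise ValueError(f"malformed GO term {t!r} for gene {gene!r}")

    def terms(self) -> set[str]:
        out: set[str] = set()
        for s in self.term_of.values():
            out |= s
        return out

    def annotated_genes(self, genes: Iterable[str] | None = None) -> set[str]:
        """Genes carrying at least one GO term (optionally restricted)."""
        pool = self.term_of.keys() if genes is None else genes
        return {g for g in pool if self.term_of.get(g)}
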