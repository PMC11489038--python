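"""Readers and writers for every external format the pipeline touches.

Supported inputs: panel config (INI), OrthoFinder ``Orthogroups.tsv`` and
``Orthogroups.GeneCount.tsv`` dialects, GFF3 gene annotations, SyRI-style
SV tables, 4-column BED+type SV tables, chromosome-length TSV (``.fai``
dialect: name and length in the first two columns), and 2-column GO
annotation TSV.  All writers emit TSV with a commented header naming the
tool version and the parameters used.

Internal coordinates are 0-based half-open; GFF3 and SyRI files (1-based
inclusive) are converted on read and restored on write.
"""
from __future__ import annotations

import configparser
import json
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from . import __version__
from .datatypes import (
    GoAnnotation,
    GeneRecord,
    HaplomePanel,
    OrthogroupMatrix,
    SVRecord,
    SVType,
)

#: SyRI annotation code -> SV class.  Codes absent from this table (SYN,
#: DUP, INVDP, NOTAL, SNP, HDR, CPG, CPL, TDM, ...) are skipped and counted.
SYRI_CODE_MAP: dict[str, SVType] = {
    "INS": SVType.INS,
    "DEL": SVType.DEL,
    "INV": SVType.INV,
    "TRANS": SVType.TRL,
    "INVTR": SVType.TRL,
}


def _header_comment(**params: object) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# orthopan v{__version__}" + (f" {items}" if items else "")


# ---------------------------------------------------------------------------
# panel config


def read_panel(path: str | Path) -> HaplomePanel:
    """Read a haplome panel from an INI config.

    The ``[haplomes]`` section maps each haplome ID to its accession ID,
    in panel order; an optional ``[species]`` section maps accession IDs
    to species labels.
    """
    parser = configparser.ConfigParser(strict=True, interpolation=None)
    parser.optionxform = str  # preserve case
    try:
        with open(path) as fh:
            parser.read_file(fh)
    except configparser.DuplicateOptionError as exc:
        raise ValueError(f"duplicate haplome ID in panel config: {exc.option!r}") from exc
    if "haplomes" not in parser:
        raise ValueError(f"panel config {path} lacks a [haplomes] section")
    accession_of: dict[str, str] = {}
    for hap, acc in parser["haplomes"].items():
        if not acc.strip():
            raise ValueError(f"haplome {hap!r} has no accession assigned")
        accession_of[hap] = acc.strip()
    species_of = dict(parser["species"]) if "species" in parser else None
    return HaplomePanel(tuple(accession_of), accession_of, species_of)


def write_panel(panel: HaplomePanel, path: str | Path) -> None:
    lines = [_header_comment(format="panel"), "[haplomes]"]
    lines += [f"{h} = {panel.accession_of[h]}" for h in panel.haplome_ids]
    if panel.species_of:
        lines.append("[species]")
        lines += [f"{a} = {s}" for a, s in panel.species_of.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# orthogroup tables


def _read_tsv_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Split a TSV into a header row and (line_number, fields) data rows."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        raise ValueError(f"{path}: empty file")
    return header, rows


def read_orthogroups(
    path: str | Path,
    panel: HaplomePanel,
    dialect: str = "auto",
) -> OrthogroupMatrix:
    """Parse an OrthoFinder orthogroup table against a panel.

    ``dialect`` is ``"genes"`` (Orthogroups.tsv: comma-separated gene IDs
    per cell), ``"counts"`` (GeneCount.tsv: integer counts, optional
    trailing ``Total`` column cross-checked), or ``"auto"``.  Columns not
    named in the panel are ignored with a warning; orthogroups empty in
    every panel haplome are dropped with a warning.
    """
    if dialect not in {"auto", "genes", "counts"}:
        raise ValueError(f"unknown orthogroup dialect {dialect!r}")
    header, rows = _read_tsv_rows(path)
    id_col, columns = header[0], header[1:]
    missing = [h for h in panel.haplome_ids if h not in columns]
    if missing:
        raise ValueError(f"{path}: missing panel haplome column(s): {missing}")
    extra = [c for c in columns if c not in panel.haplome_ids and c != "Total"]
    if extra:
        warnings.warn(f"{path}: ignoring {len(extra)} non-panel column(s): {extra}")
    col_idx = {c: i + 1 for i, c in enumerate(columns)}

    if dialect == "auto":
        probe = [rows[0][1][col_idx[h]] for h in panel.haplome_ids] if rows else []
        numeric = all(v.strip().isdigit() for v in probe if v.strip())
        dialect = "counts" if ("Total" in columns or (probe and numeric)) else "genes"

    og_ids: list[str] = []
    count_rows: list[list[int]] = []
    gene_rows: list[list[tuple[str, ...]]] = []
    for lineno, fields in rows:
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))
        og = fields[0]
        if dialect == "genes":
            genes = [
                tuple(g.strip() for g in fields[col_idx[h]].split(",") if g.strip())
                for h in panel.haplome_ids
            ]
            counts = [len(g) for g in genes]
            gene_rows.append(genes)
        else:
            try:
                counts = [int(fields[col_idx[h]] or 0) for h in panel.haplome_ids]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer gene count") from exc
            if "Total" in columns:
                total = int(fields[col_idx["Total"]] or 0)
                panel_total = sum(
                    int(fields[col_idx[c]] or 0) for c in columns if c != "Total"
                )
                if total != panel_total:
                    raise ValueError(
                        f"{path}:{lineno}: Total column ({total}) does not match "
                        f"row sum ({panel_total})"
                    )
        og_ids.append(og)
        count_rows.append(counts)

    dupes = [og for og, n in Counter(og_ids).items() if n > 1]
    if dupes:
        raise ValueError(f"{path}: duplicate orthogroup ID(s): {dupes}")

    counts_df = pd.DataFrame(count_rows, index=og_ids, columns=list(panel.haplome_ids))
    counts_df.index.name = id_col
    genes_df = (
        pd.DataFrame(gene_rows, index=og_ids, columns=list(panel.haplome_ids))
        if dialect == "genes"
        else None
    )
    empty = counts_df.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"{path}: dropping {int(empty.sum())} orthogroup(s) empty in every panel haplome"
        )
        counts_df = counts_df.loc[~empty]
        if genes_df is not None:
            genes_df = genes_df.loc[~empty]
    return OrthogroupMatrix(counts_df, genes_df)


def write_orthogroups(matrix: OrthogroupMatrix, path: str | Path) -> None:
    """Write an orthogroup matrix in the dialect it carries.

    With gene IDs present the Orthogroups.tsv (gene list) dialect is
    emitted, otherwise GeneCount.tsv with a Total column.
    """
    with_genes = matrix.gene_ids is not None
    lines = [_header_comment(format="orthogroups", dialect="genes" if with_genes else "counts")]
    haps = matrix.haplome_ids
    if with_genes:
        lines.append("\t".join(["Orthogroup", *haps]))
        for og in matrix.orthogroup_ids:
            cells = [", ".join(matrix.gene_ids.loc[og, h]) for h in haps]
            lines.append("\t".join([og, *cells]))
    else:
        lines.append("\t".join(["Orthogroup", *haps, "Total"]))
        for og, row in matrix.counts.iterrows():
            lines.append("\t".join([og, *map(str, row.tolist()), str(int(row.sum()))]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Extract gene intervals from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.  The gene ID comes from the ``ID=`` attribute; a record
    without one gets a synthesized ID with a warning.
    """
    records: list[GeneRecord] = []
    n_seen = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            n_seen += 1
            if fields[2] != feature_type:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start ({start1}) > end ({end1})")
            feat = feature_from_line(line.rstrip("\n"))
            ids = feat.attributes.get("ID", [])
            if ids:
                gene_id = ids[0]
            else:
                gene_id = f"{feature_type}_{lineno}"
                warnings.warn(f"{path}:{lineno}: feature lacks ID=, synthesized {gene_id!r}")
            records.append(
                GeneRecord(fields[0], start1 - 1, end1, fields[6] if fields[6] in "+-" else ".", gene_id)
            )
    if n_seen and not records:
        warnings.warn(f"{path}: no {feature_type!r} features found among {n_seen} feature lines")
    return records


def write_gff(genes: Sequence[GeneRecord], path: str | Path, feature_type: str = "gene") -> None:
    lines = ["##gff-version 3", _header_comment(format="gff3")]
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    "orthopan",
                    feature_type,
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SV tables


def read_sv_table(
    path: str | Path,
    haplome_id: str,
    dialect: str = "syri",
    extra_code_map: Mapping[str, SVType] | None = None,
) -> list[SVRecord]:
    """Read typed SVs from a SyRI-style TSV or a 4-column BED+type file.

    SyRI annotation codes map INS/DEL/INV as themselves and
    TRANS/INVTR to TRL; all other codes (SYN, DUP, NOTAL, SNP, ...) are
    skipped and summarized in a warning.  ``extra_code_map`` extends the
    mapping, e.g. ``{"DUP": SVType.INS}`` to count duplications.
    Variant length is ``max(reference span, query span if present, 1)``;
    SyRI's 1-based inclusive coordinates become 0-based half-open.
    """
    if dialect not in {"syri", "bed"}:
        raise ValueError(f"unknown SV dialect {dialect!r}")
    code_map = dict(SYRI_CODE_MAP)
    if extra_code_map:
        code_map.update(extra_code_map)

    records: list[SVRecord] = []
    skipped: Counter[str] = Counter()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if dialect == "bed":
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 BED columns")
                chrom, s, e, code = fields[0], fields[1], fields[2], fields[3]
                if code not in code_map:
                    skipped[code] += 1
                    continue
                try:
                    start, end = int(s), int(e)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
                records.append(
                    SVRecord(chrom, start, end, code_map[code], max(end - start, 1), haplome_id)
                )
                continue
            # SyRI dialect: rchrom rstart rend rseq qseq qchrom qstart qend id parent code ...
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >= 11 SyRI columns, got {len(fields)}")
            code = fields[10]
            if code not in code_map:
                skipped[code] += 1
                continue
            try:
                rstart1, rend1 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer reference coordinate") from exc
            ref_span = rend1 - rstart1 + 1
            qchrom = fields[5] if fields[5] not in {"", "-"} else None
            qstart = qend = None
            alt_len = 0
            if fields[6] not in {"", "-"} and fields[7] not in {"", "-"}:
                try:
                    qstart, qend = int(fields[6]), int(fields[7])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer query coordinate") from exc
                alt_len = abs(qend - qstart) + 1
            records.append(
                SVRecord(
                    fields[0],
                    rstart1 - 1,
                    rend1,
                    code_map[code],
                    max(ref_span, alt_len, 1),
                    haplome_id,
                    query_chrom=qchrom,
                    query_start=qstart,
                    query_end=qend,
                )
            )
    if skipped:
        warnings.warn(
            f"{path}: skipped {sum(skipped.values())} non-SV line(s): "
            + ", ".join(f"{c}={n}" for c, n in sorted(skipped.items()))
        )
    return records


def write_sv_table(records: Sequence[SVRecord], path: str | Path) -> None:
    """Write SVs in the SyRI dialect (query span carries insertion length)."""
    inverse = {SVType.INS: "INS", SVType.DEL: "DEL", SVType.INV: "INV", SVType.TRL: "TRANS"}
    lines = [_header_comment(format="syri")]
    for i, r in enumerate(records, start=1):
        if r.query_start is not None and r.query_end is not None:
            qs, qe = str(r.query_start), str(r.query_end)
        elif r.length > r.ref_end - r.ref_start:
            qs, qe = "1", str(r.length)  # encode alt length in the query span
        else:
            qs = qe = "-"
        lines.append(
            "\t".join(
                [
                    r.ref_chrom,
                    str(r.ref_start + 1),
                    str(r.ref_end),
                    "-",
                    "-",
                    r.query_chrom or "-",
                    qs,
                    qe,
                    f"SV{i}",
                    "-",
                    inverse[r.sv_type],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# chromosome lengths, GO annotations, generic writers


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read chromosome lengths from a TSV or ``.fai`` (first two columns)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: nonpositive length for {name}")
            if name in out:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name}")
            out[name] = length
    return out


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    lines = [_header_comment(format="chrom_lengths")]
    lines += [f"{c}\t{l}" for c, l in lengths.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_go(path: str | Path) -> GoAnnotation:
    """Read a 2-column TSV: gene_id, comma-separated GO term IDs."""
    term_of: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            gene = fields[0]
            if gene in term_of:
                raise ValueError(f"{path}:{lineno}: duplicate gene {gene}")
            terms = (
                frozenset(t.strip() for t in fields[1].split(",") if t.strip())
                if len(fields) > 1
                else frozenset()
            )
            term_of[gene] = terms
    return GoAnnotation(term_of)


def write_go(annotation: GoAnnotation, path: str | Path) -> None:
    lines = [_header_comment(format="go_annotation")]
    for gene, terms in annotation.term_of.items():
        lines.append(f"{gene}\t{','.join(sorted(terms))}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False, **params: object) -> None:
    """Write a result DataFrame as TSV with the standard comment header."""
    with open(path, "w") as fh:
        fh.write(_header_comment(**params) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
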