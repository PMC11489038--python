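"""Synthetic data with the statistical structure the analysis assumes.

Generates an orthogroup membership matrix whose categories are known by
construction, gene tracks with tunable spatial clustering, SV tracks
whose per-window intensity is Poisson-coupled to gene density, and GO
annotations with injected category-specific enrichment — everything in
the exact file dialects :mod:`orthopan.io` reads, so every pipeline
stage is testable without external downloads.

One global seed expands into fixed per-stream sub-seeds (membership,
genes, SVs, GO), so adding a generator never perturbs existing streams
and identical configs give byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Category, CategoryAssignment, CATEGORIES
from .datatypes import GeneRecord, GoAnnotation, HaplomePanel, OrthogroupMatrix, SVRecord, SVType
from .hotspots import WindowTrack

_STREAMS = {"membership": 0, "genes": 1, "svs": 2, "go": 3}


def default_panel() -> HaplomePanel:
    """An 8-haplome panel: 4 accessions x 2 haplotype assemblies."""
    accs = ["coronaria", "ioensis", "angustifolia", "fusca"]
    haps = [f"{a}_hap{i}" for a in accs for i in (1, 2)]
    return HaplomePanel(tuple(haps), {h: h.rsplit("_", 1)[0] for h in haps})


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the study's scale on a desk.

    ``category_props`` are orthogroup-level proportions for (core,
    soft-core, accessory, accession-specific, haplome-specific); the
    defaults follow the observed orthogroup composition of an 8-haplome
    crabapple panel.  ``mean_genes_per_haplome`` is the mean of the
    shifted Poisson (1 + Poisson(mean - 1)) gene count per present
    haplome.  ``sv_rate`` is the baseline Poisson SV intensity per
    window and ``beta`` adds ``beta * gene_count`` to it, coupling SV
    density to gene density.
    """

    seed: int = 0
    n_orthogroups: int = 10_000
    category_props: tuple[float, float, float, float, float] = (0.32, 0.10, 0.43, 0.115, 0.035)
    mean_genes_per_haplome: float = 1.1
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {f"chr{i:02d}": 50_000_000 for i in range(1, 17)}
    )
    n_genes: int = 40_000
    gene_cluster_factor: float = 0.5
    gene_cluster_sd: float = 200_000.0
    window_size: int = 400_000
    sv_rate: float = 5.0
    beta: float = 0.0
    sv_type_probs: tuple[float, float, float, float] = (0.42, 0.42, 0.013, 0.147)
    min_sv_length: int = 50
    max_sv_length: int = 100_000
    n_go_terms: int = 50
    go_freq_range: tuple[float, float] = (0.01, 0.05)
    n_injected_terms: int = 1
    injected_fold: float = 5.0

    def __post_init__(self) -> None:
        if abs(sum(self.category_props) - 1.0) > 1e-9 or min(self.category_props) < 0:
            raise ValueError("category_props must be nonnegative and sum to 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if self.sv_rate < 0 or self.beta < 0:
            raise ValueError("SV rates must be nonnegative")
        if self.injected_fold < 1:
            raise ValueError("injected_fold must be >= 1")
        if not 0 <= self.gene_cluster_factor <= 1:
            raise ValueError("gene_cluster_factor must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


def _category_patterns(panel: HaplomePanel) -> dict[Category, list[frozenset[str]]]:
    """All presence patterns valid for each category under the rules."""
    haps = panel.haplome_ids
    n = len(haps)
    acc = panel.accession_of
    patterns: dict[Category, list[frozenset[str]]] = {c: [] for c in CATEGORIES}
    patterns[Category.CORE] = [frozenset(haps)] if n >= 1 else []
    if n - 1 >= 3:
        patterns[Category.SOFT_CORE] = [frozenset(c) for c in combinations(haps, n - 1)]
    acc_pairs = [frozenset(p) for p in combinations(haps, 2) if len({acc[h] for h in p}) == 1]
    cross_pairs = [frozenset(p) for p in combinations(haps, 2) if len({acc[h] for h in p}) == 2]
    patterns[Category.ACCESSORY] = [
        frozenset(c) for size in range(3, n - 1) for c in combinations(haps, size)
    ] + cross_pairs
    patterns[Category.ACCESSION_SPECIFIC] = acc_pairs
    patterns[Category.HAPLOME_SPECIFIC] = [frozenset((h,)) for h in haps]
    return patterns


def gen_membership(
    config: SimConfig, panel: HaplomePanel
) -> tuple[OrthogroupMatrix, CategoryAssignment]:
    """Draw an orthogroup matrix with known per-orthogroup categories.

    Each orthogroup draws its category from ``category_props``, then a
    presence pattern uniformly among the patterns valid for that
    category, then a shifted-Poisson gene count per present haplome.
    Categories are pattern-determined, so the returned assignment is
    exact ground truth for the classifier.
    """
    rng = config.rng("membership")
    patterns = _category_patterns(panel)
    for cat, prop in zip(CATEGORIES, config.category_props):
        if prop > 0 and not patterns[cat]:
            raise ValueError(
                f"category {cat.value} has probability {prop} but no valid presence "
                f"pattern under this panel shape"
            )
    cat_idx = rng.choice(len(CATEGORIES), size=config.n_orthogroups, p=config.category_props)
    haps = list(panel.haplome_ids)
    mean_extra = max(config.mean_genes_per_haplome - 1.0, 0.0)
    gene_counter = {h: 0 for h in haps}

    og_ids, count_rows, gene_rows, category_of, presence_of = [], [], [], {}, {}
    for i, ci in enumerate(cat_idx):
        cat = CATEGORIES[ci]
        pats = patterns[cat]
        pattern = pats[rng.integers(len(pats))]
        og = f"OG{i + 1:07d}"
        counts, genes = [], []
        for h in haps:
            if h in pattern:
                c = 1 + int(rng.poisson(mean_extra))
                ids = []
                for _ in range(c):
                    gene_counter[h] += 1
                    ids.append(f"{h}.g{gene_counter[h]:06d}")
                counts.append(c)
                genes.append(tuple(ids))
            else:
                counts.append(0)
                genes.append(())
        og_ids.append(og)
        count_rows.append(counts)
        gene_rows.append(genes)
        category_of[og] = cat
        presence_of[og] = pattern

    counts_df = pd.DataFrame(count_rows, index=og_ids, columns=haps)
    counts_df.index.name = "Orthogroup"
    genes_df = pd.DataFrame(gene_rows, index=og_ids, columns=haps)
    return OrthogroupMatrix(counts_df, genes_df), CategoryAssignment(category_of, presence_of)


def gen_genes(config: SimConfig) -> list[GeneRecord]:
    """Gene intervals with clustered density along each chromosome.

    Starts come from a mixture of a uniform background and Gaussian
    clusters (mixture weight ``gene_cluster_factor``; cluster centers
    roughly one per 5 Mb); widths are log-normal, clipped to the
    chromosome.  Records are sorted by (chrom, start).
    """
    rng = config.rng("genes")
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    if config.n_genes == 0:
        return []
    probs = lengths / lengths.sum()
    centers = {
        c: rng.uniform(0, config.chrom_lengths[c], size=max(1, config.chrom_lengths[c] // 5_000_000))
        for c in chroms
    }
    chrom_idx = rng.choice(len(chroms), size=config.n_genes, p=probs)
    clustered = rng.random(config.n_genes) < config.gene_cluster_factor
    widths = np.clip(rng.lognormal(np.log(3000.0), 0.6, size=config.n_genes), 200, 50_000)

    records = []
    for i in range(config.n_genes):
        chrom = chroms[chrom_idx[i]]
        L = config.chrom_lengths[chrom]
        if clustered[i]:
            center = centers[chrom][rng.integers(len(centers[chrom]))]
            pos = rng.normal(center, config.gene_cluster_sd)
        else:
            pos = rng.uniform(0, L)
        width = int(min(widths[i], L - 1))
        start = int(np.clip(pos, 0, L - width - 1))
        records.append(
            GeneRecord(chrom, start, start + width, "+" if rng.random() < 0.5 else "-",
                       f"gene{i + 1:06d}")
        )
    records.sort(key=lambda g: (g.chrom, g.start))
    return records


def gen_svs(
    config: SimConfig,
    gene_track: WindowTrack,
    haplome_ids: Sequence[str] = ("sim_hap1", "sim_hap2"),
) -> list[SVRecord]:
    """SVs whose per-window count is Poisson(sv_rate + beta * gene_count).

    Both breakpoints of every SV stay inside its window, so the
    generated breakpoint density per window is exactly twice the Poisson
    draw.  Types follow ``sv_type_probs`` (INS, DEL, INV, TRL; the
    default is InDel-heavy); lengths come from a heavy-tailed mixture
    spanning ``min_sv_length`` to ``max_sv_length``.  Haplome labels are
    assigned round-robin.
    """
    if gene_track.gene_count is None:
        raise ValueError("gene_track must have gene_count filled")
    rng = config.rng("svs")
    types = [SVType.INS, SVType.DEL, SVType.INV, SVType.TRL]
    lam = config.sv_rate + config.beta * np.asarray(gene_track.gene_count, dtype=float)
    n_per_window = rng.poisson(lam)
    records: list[SVRecord] = []
    sv_i = 0
    for (_, win), n_sv in zip(gene_track.windows.iterrows(), n_per_window):
        chrom, wstart, wend = win["chrom"], int(win["start"]), int(win["end"])
        for _ in range(int(n_sv)):
            if rng.random() < 0.85:
                length = int(np.clip(rng.lognormal(np.log(300.0), 1.2),
                                     config.min_sv_length, config.max_sv_length))
            else:
                length = int(10 ** rng.uniform(3, np.log10(config.max_sv_length)))
            length = min(length, wend - wstart)
            sv_type = types[rng.choice(4, p=config.sv_type_probs)]
            start = int(rng.integers(wstart, max(wend - length, wstart) + 1))
            if sv_type is SVType.INS:
                ref_start, ref_end = start, start + 1
                q = (1, length)
            else:
                ref_start, ref_end = start, start + length
                q = (None, None)
            records.append(
                SVRecord(chrom, ref_start, ref_end, sv_type, length,
                         haplome_ids[sv_i % len(haplome_ids)],
                         query_chrom="q" + chrom if q[0] else None,
                         query_start=q[0], query_end=q[1])
            )
            sv_i += 1
    return records


def calibrate_beta(
    target_r: float, gene_counts: np.ndarray, sv_rate: float
) -> float:
    """Coupling coefficient giving a target SV-gene Pearson correlation.

    Under the generator's model S | g ~ Poisson(sv_rate + beta * g),
    Cov(S, g) = beta * Var(g) and Var(S) = sv_rate + beta * E[g] +
    beta^2 * Var(g), so the target correlation r solves a quadratic in
    beta; the positive root is returned.  Uses the empirical moments of
    the supplied per-window gene counts, so clustering is accounted for.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    g = np.asarray(gene_counts, dtype=float)
    m, v = g.mean(), g.var()
    if v == 0:
        raise ValueError("gene counts are constant; coupling cannot set a correlation")
    r2 = target_r**2
    a = v * (1 - r2)
    disc = r2**2 * m**2 + 4 * a * r2 * sv_rate
    return float((r2 * m + np.sqrt(disc)) / (2 * a))


def gen_go(
    gene_ids: Sequence[str],
    config: SimConfig,
    enriched_genes: Sequence[str] | frozenset[str] = frozenset(),
) -> GoAnnotation:
    """Assign GO terms independently per gene, with injected enrichment.

    Each of ``n_go_terms`` terms gets a baseline frequency drawn from
    ``go_freq_range``; the first ``n_injected_terms`` terms are
    over-assigned to ``enriched_genes`` at ``injected_fold`` times their
    baseline (capped at 1).
    """
    if not gene_ids:
        raise ValueError("gene set is empty")
    rng = config.rng("go")
    genes = list(gene_ids)
    n_genes, n_terms = len(genes), config.n_go_terms
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    base = rng.uniform(*config.go_freq_range, size=n_terms)
    probs = np.tile(base, (n_genes, 1))
    if config.n_injected_terms and enriched_genes:
        enriched = set(enriched_genes)
        rows = [i for i, g in enumerate(genes) if g in enriched]
        inj = slice(0, config.n_injected_terms)
        probs[np.ix_(rows, range(config.n_injected_terms))] = np.minimum(
            base[inj] * config.injected_fold, 1.0
        )
    draws = rng.random((n_genes, n_terms)) < probs
    term_arr = np.array(terms, dtype=object)
    term_of = {
        g: frozenset(term_arr[draws[i]]) for i, g in enumerate(genes)
    }
    return GoAnnotation(term_of)


def injected_terms(config: SimConfig) -> list[str]:
    """Term IDs carrying injected enrichment under this config."""
    return [f"GO:{i + 1:07d}" for i in range(config.n_injected_terms)]
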