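# orthopan

Gene family-based pangenome and structural-variant hotspot analysis for
multi-haplome panels.

Haplotype-resolved assemblies make it possible to treat each *haplome*
(one haplotype of a diploid accession) as a genome in its own right.
Given orthogroups inferred across such a panel — e.g. the 8 haplomes of
4 wild crabapple accessions this package was designed around — `orthopan`
answers four questions:

1. **Which gene families are core, and which are dispensable?**
   Each orthogroup is classified from its presence pattern over the N
   haplomes: *core* (all N), *soft-core* (any N−1), *accessory* (3..N−2
   haplomes, or exactly 2 haplomes of *different* accessions),
   *accession-specific* (both haplomes of one accession), and
   *haplome-specific* (a single haplome).
2. **Is the pangenome open or closed?** Pan and core orthogroup counts
   are computed for **all 2^N − 1 genome combinations** and fitted with
   the power law *y = A·x^B + C* (pan) and the exponential
   *y = A·e^(Bx) + C* (core) by Levenberg–Marquardt nonlinear least
   squares.
3. **Where does structural variation concentrate?** Typed SV calls
   (insertions, deletions, inversions, translocations ≥ 50 bp) are
   reduced to breakpoints, binned into 400-kb windows along the
   reference, and the top 5% of windows (tie-inclusive) are called
   hotspots; SV density is correlated with gene density
   (Pearson r, two-sided t-test).
4. **What are the dispensable genes doing?** GO term
   over-representation of a category's gene set against the pangenome
   background, via the one-sided hypergeometric tail
   P(X ≥ k | N, K, n) with Benjamini–Yekutieli FDR control
   (singular-enrichment-analysis style, minimum background mapping 10).

A first-class synthetic-data generator (`orthopan.simulate`) produces
membership matrices with known category ground truth, clustered gene
tracks, SV tracks Poisson-coupled to gene density with a calibratable
correlation, and GO annotations with injected enrichment — in the exact
file dialects the I/O layer reads — so the whole pipeline is testable
without any external downloads.

## Input formats

| Format | Reader | Notes |
| --- | --- | --- |
| panel config (INI) | `io.read_panel` | `[haplomes]` maps haplome → accession, order preserved |
| `Orthogroups.tsv` / `GeneCount.tsv` | `io.read_orthogroups` | OrthoFinder dialects; gene lists or integer counts (`Total` cross-checked) |
| GFF3 | `io.read_gff` | `gene` features; 1-based inclusive → 0-based half-open |
| SyRI TSV | `io.read_sv_table` | columns: ref_chrom, ref_start, ref_end, ref_seq, qry_seq, qry_chrom, qry_start, qry_end, id, parent, code |
| BED4 | `io.read_sv_table(..., dialect="bed")` | chrom, start, end, type |
| chrom lengths | `io.read_chrom_lengths` | TSV or `.fai` (first two columns) |
| GO annotation | `io.read_go` | gene_id TAB comma-separated `GO:` IDs |

SyRI code mapping: `INS→INS`, `DEL→DEL`, `INV→INV`, `TRANS→TRL`,
`INVTR→TRL`; all other codes (SYN, DUP, INVDP, NOTAL, SNP, HDR, ...)
are skipped and counted in a warning.  Duplications can be opted in via
`extra_code_map={"DUP": SVType.INS}`.  Insertion length is taken from
the query span when the reference span is a point.

## Worked example

Entirely synthetic, seeded, and reproducible:

```python
import dataclasses
import orthopan as op

panel = op.default_panel()                     # 8 haplomes, 4 accessions
cfg = op.SimConfig(seed=42, n_orthogroups=2000)
matrix, _ = op.gen_membership(cfg, panel)

assignment = op.classify_matrix(matrix, panel)
print(op.summarize(matrix, assignment).to_frame().to_string(index=False))

points = op.enumerate_subsets(matrix, panel)   # 255 genome combinations
core_fit = op.fit_growth(points, "exponential")
print(f"core y = {core_fit.A:.1f} e^({core_fit.B:.3f} x) + {core_fit.C:.1f}")

acfg = op.AnalysisConfig()                     # 50 bp, 400 kb, top 5%
genes = op.gen_genes(cfg)
track = op.count_genes(genes, op.make_windows(cfg.chrom_lengths, acfg))
beta = op.calibrate_beta(0.53, track.gene_count, cfg.sv_rate)
svs = op.filter_svs(op.gen_svs(dataclasses.replace(cfg, beta=beta), track), acfg)
track = op.count_breakpoints(svs, track)
hotspots = op.call_hotspots(track, acfg, "simulated")
corr = op.correlate_sv_gene(track)
print(f"windows={track.n_windows} hotspots={hotspots.n_hotspots} "
      f"threshold={hotspots.threshold_count} breakpoints, r={corr.r:.2f}")
```

prints

```
          category  orthogroup_count  gene_count  gene_percent
              core               631        5528          48.3
         soft_core               190        1468          12.8
         accessory               883        3877          33.9
accession_specific               231         502           4.4
  haplome_specific                65          68           0.6
         pangenome              2000       11443         100.0
core y = 1153.5 e^(-0.599 x) + 656.1
windows=2000 hotspots=100 threshold=24 breakpoints, r=0.54
```

Reading it: about half the simulated pangenome's genes are core and a
third accessory (the generator's defaults mirror an 8-haplome crabapple
panel); the core genome decays toward an asymptote of ~656 orthogroups
per the exponential fit; 100 of 2000 windows (5%) with ≥ 24 breakpoints
are hotspots; and the SV–gene density correlation recovers the
calibration target of 0.53.

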