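# Methods

## Category rules and their generalization

An orthogroup's category is a pure function of its presence pattern
(the haplomes with gene count ≥ 1) and the panel's haplome→accession
map. For an N-haplome panel the rules are evaluated on descending
presence size:

| presence | category |
| --- | --- |
| N | core |
| N−1 (only when N−1 ≥ 3) | soft-core |
| 3 .. N−2 | accessory |
| 2, different accessions | accessory |
| 2, same accession | accession-specific |
| 1 | haplome-specific |

The rules were formulated for N = 8, where the ranges are disjoint. For
smaller panels they can collide (at N = 2 a singleton is both "N−1" and
"1"); we resolve collisions by restricting soft-core to N−1 ≥ 3, so a
2-haplome panel degenerates to {core, haplome-specific}. A warning is
emitted whenever N ≠ 8. "Accession-specific" requires *exactly* the two
haplomes of one accession — a pattern of 2 same-accession haplomes is
never accessory.

Gene totals count genes over **all** haplomes (the pangenome gene total
is the grand sum of the count matrix), and category gene percentages
are 100·g/total rounded half-up to one decimal — the convention under
which the five published category gene counts (166,477 / 45,391 /
108,627 / 14,706 / 4,886) reproduce the published percentages exactly.

## Pan/core growth modelling

Every non-empty haplome subset contributes one regression point
(2^N − 1 = 255 points at N = 8; no per-k averaging), with pan size the
union support count and core size the intersection support count,
computed by packing each orthogroup's presence row into a bitset.
Enumeration is guarded at N ≤ 20.

The pan curve is y = A·x^B + C and the core curve y = A·e^(Bx) + C,
fitted by Levenberg–Marquardt (`scipy.optimize.least_squares`,
`method="lm"`, xtol 1e−8, ≤ 10,000 evaluations) from three documented
starts each — power law (y_max−y_min, 0.3, y_min), (y₁, 0.5, 0),
(Δy/Δk, 1.0, y_min); exponential (y₁−y_N, −0.3, y_N), (y₁, −0.5, 0),
(y_max, −1.0, y_min) — with the best residual sum of squares winning,
which makes the fit deterministic and start-independent. Zero
amplitudes are nudged to 1 so B is never frozen.

*Identifiability caveat*: when pan growth is close to logarithmic the
power law approaches its B→0 limit, where A and C diverge in opposite
directions while predictions stay stable. `CurveFitResult.predict` is
the reliable contract; individual parameters should only be interpreted
when B is safely away from 0. Constant data is fitted exactly with
non-unique parameters (prediction contract only).

`growth_increments` reports Δpan(k) and Δcore(k) as differences of
*means over all subsets* of sizes k and k−1 (whether published
increments are combination means or a single addition order is not
derivable from their value alone; means are the symmetric choice and
are what exact enumeration supports).

## SV windows, hotspots, correlation

* **Length filter**: "larger than 50 bp" is implemented as length ≥ 50,
  the community convention for SV size thresholds; a strict > reading
  is available (`AnalysisConfig(strict_min_length=True)`). SV length is
  max(reference span, query span, 1), so insertions carry their
  inserted length.
* **Windows**: each chromosome is tiled with ⌈L/w⌉ windows of w =
  400 kb, the terminal window truncated; tiling is exact (widths sum to
  L).
* **Breakpoints**: every SV contributes its two endpoint positions
  (ref_start and ref_end−1) to their containing windows; an SV wholly
  inside a window adds 2. This counts breakpoints rather than
  overlapped bases, so insertions (point events on the reference) still
  contribute 2 to one window.
* **Hotspots**: with n windows, m = ⌈0.05·n⌉ and the threshold is the
  m-th largest breakpoint count; all windows at or above it are flagged
  (tie-inclusive, so ≥ m hotspots; ≥ 1 even for tiny n). The threshold
  is applied genome-wide over all windows, not per chromosome.
  Hotspots are intended to be called per genome, pooling the SVs of
  that accession's haplomes into one count vector; pooling across all
  genomes is the same call on the pooled counts.
* **Gene density**: a gene is assigned to the window containing its
  start, so each gene is counted exactly once and window totals are
  conserved; overlap-based assignment would double-count spanning
  genes.
* **Correlation**: sample Pearson r over windows with the two-sided
  p-value from the t-transform with n−2 df. Constant vectors are
  rejected with an error naming the offending track.

## GO enrichment

One-sided over-representation per term: p = P(X ≥ k | N, K, n) from the
hypergeometric distribution, where the background N is the set of
pangenome genes carrying ≥ 1 GO term and the subset n is restricted the
same way (annotated-only backgrounds keep untestable genes from
diluting the tables). Terms with K < 10 background genes are dropped;
Benjamini–Yekutieli adjusts across tested terms at α = 0.05 —
mirroring agriGO SEA defaults (Fisher/hypergeometric, BY, minimum
mapping 10). Terms are tested exactly as annotated; no ontology-graph
ancestor propagation is performed (no ontology release is assumed).

## Synthetic data generator

The generator defines the package's testable study conditions:

* **Membership** (`gen_membership`): category drawn per orthogroup from
  `category_props` — default (0.32, 0.10, 0.43, 0.115, 0.035), the
  orthogroup-level composition of an 8-haplome crabapple panel — then a
  presence pattern uniform over the patterns valid for that category,
  then per-present-haplome gene counts 1 + Poisson(mean−1) with mean
  1.1 (the observed genes-per-orthogroup-per-haplome ratio of such
  panels is ≈ 1.08). Categories are pattern-determined, so the returned
  assignment is exact ground truth and classifier recovery must be
  100%.
* **Genes** (`gen_genes`): 40,000 genes on 16 × 50 Mb chromosomes
  (2,000 windows of 400 kb — desk-scale but window-count-realistic for
  a ~700 Mb genome). Starts are a mixture of uniform background and
  Gaussian clusters (weight `gene_cluster_factor` = 0.5, cluster sd
  200 kb, ~1 cluster per 5 Mb); at weight 0 the per-window counts are
  Poisson-dispersed (index of dispersion ≈ 1).
* **SVs** (`gen_svs`): per-window count Poisson(λ₀ + β·gene_count),
  λ₀ = 5; both breakpoints stay inside the window, so the generated
  coupling is exact. Types default to an InDel-heavy mix
  (0.42/0.42/0.013/0.147 for INS/DEL/INV/TRL, the relative abundances
  seen in haplome-vs-reference comparisons); lengths come from a
  heavy-tailed mixture (85% log-normal around 300 bp, 15% log-uniform
  1–100 kb), clipped to [50 bp, 100 kb].
* **Coupling calibration** (`calibrate_beta`): under the generator's
  model Cov(S,g) = β·Var(g) and Var(S) = λ₀ + β·E[g] + β²·Var(g), so a
  target correlation r solves a quadratic in β in closed form; the
  empirical moments of the supplied gene counts are used, so gene
  clustering is accounted for. Calibrated at r = 0.53 the estimate over
  2,000 windows lands within ±0.1.
* **GO** (`gen_go`): 50 terms with baseline gene frequencies uniform in
  [0.01, 0.05], assigned independently per gene; injected terms are
  over-assigned at `injected_fold` (default 5) to a designated subset,
  capped at probability 1.

One global seed expands into fixed per-stream `SeedSequence` sub-seeds
(membership/genes/SVs/GO), so identical configs are byte-identical on
disk and adding a generator never perturbs existing streams.

**What passing synthetic tests does not show**: the generator has no
sequence content, no orthology-inference noise (orthogroup membership
is exact by construction), window-independent SV placement (no
segmental-duplication or centromeric structure), and GO terms assigned
independently (no ontology hierarchy or term co-occurrence). Results on
real panels additionally depend on assembly, alignment, and SV-calling
quality upstream of this package. Quantities that require the real
assemblies (real SV totals, per-genome hotspot counts, the observed
r = 0.53, the real pan/core increments) are represented here by seeded
recovery experiments at the stated desk-scale sizes, not reproduced.

## Degenerate inputs and tie-breaks

Empty presence sets, subset genes missing from the enrichment
background, constant correlation vectors, unknown dialects, and
non-integer coordinates are hard errors naming the offender (with line
numbers for file inputs). All-zero SV tracks yield an empty hotspot set
with a warning rather than flagging everything. Matrices with all-empty
rows are repaired on read (dropped with a warning) because OrthoFinder
emits such rows when a panel subset is selected from a larger run.
Enrichment ties are ordered deterministically (adjusted p, then term
ID, stable sort).
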