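import dataclasses

import numpy as np
import pytest

import orthopan as op
from orthopan import io
from orthopan.classify import CATEGORIES, Category
from orthopan.simulate import _category_patterns, injected_terms


def test_membership_categories_are_exact_ground_truth(panel):
    cfg = op.SimConfig(seed=21, n_orthogroups=1000)
    matrix, truth = op.gen_membership(cfg, panel)
    assignment = op.classify_matrix(matrix, panel)
    assert assignment.category_of == truth.category_of
    assert assignment.presence_of == truth.presence_of


def test_membership_proportions_within_binomial_error(panel):
    cfg = op.SimConfig(seed=22, n_orthogroups=5000)
    _, truth = op.gen_membership(cfg, panel)
    n = cfg.n_orthogroups
    for cat, p in zip(CATEGORIES, cfg.category_props):
        observed = sum(c is cat for c in truth.category_of.values()) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se


def test_degenerate_all_core_config(panel):
    cfg = op.SimConfig(seed=23, n_orthogroups=100, category_props=(1, 0, 0, 0, 0))
    matrix, _ = op.gen_membership(cfg, panel)
    assert (matrix.counts > 0).all().all()


def test_unrealizable_category_errors():
    tiny = op.HaplomePanel(("h1", "h2"), {"h1": "a1", "h2": "a2"})
    cfg = op.SimConfig(seed=1, category_props=(0.5, 0.0, 0.0, 0.5, 0.0))
    with pytest.raises(ValueError, match="accession_specific"):
        op.gen_membership(cfg, tiny)


def test_category_patterns_match_rules(panel):
    pats = _category_patterns(panel)
    assert len(pats[Category.CORE]) == 1
    assert len(pats[Category.SOFT_CORE]) == 8
    assert len(pats[Category.ACCESSION_SPECIFIC]) == 4
    assert len(pats[Category.HAPLOME_SPECIFIC]) == 8
    # sizes 3..6 plus cross-accession pairs
    assert len(pats[Category.ACCESSORY]) == 56 + 70 + 56 + 28 + 24
    for cat, patterns in pats.items():
        for p in patterns:
            assert op.classify_orthogroup(p, panel) is cat


def test_gene_generation_bounds_and_count():
    cfg = op.SimConfig(seed=24, n_genes=2000)
    genes = op.gen_genes(cfg)
    assert len(genes) == 2000
    for g in genes:
        assert 0 <= g.start < g.end <= cfg.chrom_lengths[g.chrom]
    assert op.gen_genes(dataclasses.replace(cfg, n_genes=0)) == []


def test_unclustered_genes_are_poisson_dispersed():
    cfg = op.SimConfig(seed=25, gene_cluster_factor=0.0)
    genes = op.gen_genes(cfg)
    track = op.count_genes(genes, op.make_windows(cfg.chrom_lengths, op.AnalysisConfig()))
    dispersion = track.gene_count.var() / track.gene_count.mean()
    assert track.n_windows == 2000
    assert 0.8 <= dispersion <= 1.2


def test_clustered_genes_are_overdispersed():
    cfg = op.SimConfig(seed=25, gene_cluster_factor=0.8)
    genes = op.gen_genes(cfg)
    track = op.count_genes(genes, op.make_windows(cfg.chrom_lengths, op.AnalysisConfig()))
    assert track.gene_count.var() / track.gene_count.mean() > 2


def make_gene_track(cfg):
    genes = op.gen_genes(cfg)
    return op.count_genes(genes, op.make_windows(cfg.chrom_lengths, op.AnalysisConfig()))


def test_uncoupled_svs_are_uncorrelated_with_genes():
    cfg = op.SimConfig(seed=26, beta=0.0)
    track = make_gene_track(cfg)
    svs = op.gen_svs(cfg, track)
    res = op.correlate_sv_gene(op.count_breakpoints(svs, track))
    assert abs(res.r) <= 0.05


def test_generated_sv_lengths_respect_minimum():
    cfg = op.SimConfig(seed=27)
    track = make_gene_track(cfg)
    svs = op.gen_svs(cfg, track)
    assert min(r.length for r in svs) >= 50
    assert op.filter_svs(svs, op.AnalysisConfig()) == svs


def test_calibrate_beta_hits_target_correlation():
    cfg = op.SimConfig(seed=28)
    track = make_gene_track(cfg)
    beta = op.calibrate_beta(0.53, track.gene_count, cfg.sv_rate)
    svs = op.gen_svs(dataclasses.replace(cfg, beta=beta), track)
    res = op.correlate_sv_gene(op.count_breakpoints(svs, track))
    assert abs(res.r - 0.53) <= 0.1


def test_go_null_and_injection(panel):
    cfg = op.SimConfig(seed=29, injected_fold=1.0)
    genes = [f"g{i}" for i in range(3000)]
    ann = op.gen_go(genes, cfg, enriched_genes=genes[:600])
    table = op.enrich(set(genes[:600]), set(genes), ann)
    assert not table["significant"].any()  # fold-1 "injection" is a null
    cfg5 = dataclasses.replace(cfg, injected_fold=5.0)
    ann5 = op.gen_go(genes, cfg5, enriched_genes=genes[:600])
    table5 = op.enrich(set(genes[:600]), set(genes), ann5).set_index("term")
    (term,) = injected_terms(cfg5)
    assert table5.loc[term, "adjusted_p"] < 0.05


def test_empty_term_list_makes_enrich_error_cleanly():
    cfg = op.SimConfig(seed=30, n_go_terms=0)
    genes = [f"g{i}" for i in range(50)]
    ann = op.gen_go(genes, cfg)
    assert ann.terms() == set()
    with pytest.raises(ValueError, match="no background gene"):
        op.enrich(set(genes[:10]), set(genes), ann)


def test_identical_config_gives_byte_identical_files(tmp_path, panel):
    def render(subdir):
        cfg = op.SimConfig(seed=31, n_orthogroups=80, n_genes=500,
                           chrom_lengths={"chr1": 4_000_000})
        out = tmp_path / subdir
        out.mkdir()
        matrix, _ = op.gen_membership(cfg, panel)
        io.write_orthogroups(matrix, out / "og.tsv")
        genes = op.gen_genes(cfg)
        io.write_gff(genes, out / "genes.gff3")
        track = op.count_genes(genes, op.make_windows(cfg.chrom_lengths, op.AnalysisConfig()))
        svs = op.gen_svs(dataclasses.replace(cfg, beta=0.1), track)
        io.write_sv_table(svs, out / "sv.tsv")
        ann = op.gen_go([g.gene_id for g in genes], cfg, enriched_genes=())
        io.write_go(ann, out / "go.tsv")
        io.write_panel(panel, out / "panel.ini")
        io.write_chrom_lengths(cfg.chrom_lengths, out / "lens.tsv")
        return {p.name: p.read_bytes() for p in sorted(out.iterdir())}

    assert render("a") == render("b")


def test_generated_artifacts_roundtrip_through_io(tmp_path, panel):
    cfg = op.SimConfig(seed=32, n_orthogroups=60, n_genes=300,
                       chrom_lengths={"chr1": 4_000_000})
    matrix, _ = op.gen_membership(cfg, panel)
    io.write_orthogroups(matrix, tmp_path / "og.tsv")
    assert io.read_orthogroups(tmp_path / "og.tsv", panel).counts.equals(matrix.counts)

    genes = op.gen_genes(cfg)
    io.write_gff(genes, tmp_path / "g.gff3")
    assert io.read_gff(tmp_path / "g.gff3") == genes

    track = op.count_genes(genes, op.make_windows(cfg.chrom_lengths, op.AnalysisConfig()))
    svs = op.gen_svs(cfg, track, haplome_ids=("hX",))
    io.write_sv_table(svs, tmp_path / "sv.tsv")
    back = io.read_sv_table(tmp_path / "sv.tsv", "hX")
    assert [(r.ref_chrom, r.ref_start, r.ref_end, r.sv_type, r.length) for r in back] == [
        (r.ref_chrom, r.ref_start, r.ref_end, r.sv_type, r.length) for r in svs
    ]

    ann = op.gen_go([g.gene_id for g in genes], cfg)
    io.write_go(ann, tmp_path / "go.tsv")
    assert io.read_go(tmp_path / "go.tsv").term_of == ann.term_of
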