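import math

import numpy as np
import pandas as pd
import pytest

import orthopan as op
from orthopan.hotspots import hotspot_frame


CFG = op.AnalysisConfig()


def track_from_counts(counts, window=400_000):
    n = len(counts)
    track = op.make_windows({"chr1": n * window}, op.AnalysisConfig(window_size=window))
    return op.WindowTrack(track.windows, sv_count=np.asarray(counts, dtype=np.int64))


def sv(start, end, sv_type=op.SVType.DEL, length=None, chrom="chr1"):
    return op.SVRecord(chrom, start, end, sv_type, length or max(end - start, 1), "h1")


# ---------------------------------------------------------------------------
# filtering


def test_filter_svs_length_boundary():
    records = [sv(0, 49), sv(0, 50), sv(0, 51)]
    kept = op.filter_svs(records, CFG)
    assert [r.length for r in kept] == [50, 51]
    strict = op.filter_svs(records, op.AnalysisConfig(strict_min_length=True))
    assert [r.length for r in strict] == [51]
    assert op.filter_svs([], CFG) == []


# ---------------------------------------------------------------------------
# window tiling


@pytest.mark.parametrize(
    "length, expected",
    [
        (1_000_000, [(0, 400_000), (400_000, 800_000), (800_000, 1_000_000)]),
        (300_000, [(0, 300_000)]),
        (800_000, [(0, 400_000), (400_000, 800_000)]),
    ],
)
def test_make_windows_tiling(length, expected):
    track = op.make_windows({"chr1": length}, CFG)
    assert list(zip(track.windows["start"], track.windows["end"])) == expected
    assert (track.windows["end"] - track.windows["start"]).sum() == length


def test_make_windows_multiple_chromosomes_tile_completely():
    lengths = {"chr1": 950_000, "chr2": 400_001}
    track = op.make_windows(lengths, CFG)
    widths = track.windows.groupby("chrom")["end"].max()
    assert widths.to_dict() == lengths
    assert track.n_windows == 3 + 2


# ---------------------------------------------------------------------------
# breakpoint and gene counting


def test_breakpoints_within_one_window_add_two():
    track = op.make_windows({"chr1": 1_200_000}, CFG)
    out = op.count_breakpoints([sv(100, 200)], track)
    assert out.sv_count.tolist() == [2, 0, 0]


def test_breakpoints_split_across_windows():
    track = op.make_windows({"chr1": 1_200_000}, CFG)
    out = op.count_breakpoints([sv(399_999, 400_050)], track)
    assert out.sv_count.tolist() == [1, 1, 0]


def test_breakpoint_conservation_and_skip_log():
    track = op.make_windows({"chr1": 1_200_000}, CFG)
    svs = [sv(0, 1000), sv(500_000, 900_000), sv(10, 20, chrom="chrX")]
    with pytest.warns(UserWarning, match="2 SV breakpoint"):
        out = op.count_breakpoints(svs, track)
    assert out.sv_count.sum() == 2 * 2  # off-track SV contributes nothing
    assert op.count_breakpoints([], track).sv_count.sum() == 0


def test_gene_assignment_by_start_position():
    track = op.make_windows({"chr1": 1_200_000}, CFG)
    genes = [
        op.GeneRecord("chr1", 100, 5_000, "+", "g1"),
        op.GeneRecord("chr1", 400_000, 400_500, "+", "g2"),  # exactly at the boundary
        op.GeneRecord("chr1", 399_000, 450_000, "+", "g3"),  # spans, counted once
    ]
    out = op.count_genes(genes, track)
    assert out.gene_count.tolist() == [2, 1, 0]
    assert op.count_genes([], track).gene_count.sum() == 0


# ---------------------------------------------------------------------------
# hotspot calling


def test_hotspots_five_percent_of_distinct_counts():
    track = track_from_counts(np.arange(100)[::-1])
    hs = op.call_hotspots(track, CFG, "g")
    assert hs.n_hotspots == 5
    assert hs.threshold_count == 95


def test_hotspots_tie_inclusive():
    counts = [9, 8, 8, 8] + [1] * 36
    hs = op.call_hotspots(track_from_counts(counts), CFG, "g")
    assert hs.threshold_count == 8
    assert hs.n_hotspots == 4


def test_hotspots_minimum_one_window():
    counts = [5, 4, 3, 2, 1, 1, 1, 1, 1, 1]
    hs = op.call_hotspots(track_from_counts(counts), CFG, "g")
    assert hs.n_hotspots == 1 and hs.threshold_count == 5


def test_hotspots_all_zero_warns_empty():
    with pytest.warns(UserWarning, match="no hotspots"):
        hs = op.call_hotspots(track_from_counts([0] * 20), CFG, "g")
    assert hs.n_hotspots == 0


def test_hotspots_agree_with_full_sort_oracle():
    rng = np.random.default_rng(42)
    for _ in range(500):
        n = int(rng.integers(5, 300))
        counts = rng.poisson(rng.uniform(0.5, 20), size=n)
        if counts.max() == 0:
            counts[0] = 1
        frac = float(rng.uniform(0.01, 0.3))
        cfg = op.AnalysisConfig(hotspot_fraction=frac)
        hs = op.call_hotspots(track_from_counts(counts), cfg, "g")
        m = math.ceil(frac * n)
        thr = sorted(counts, reverse=True)[m - 1]
        expected = {i for i, c in enumerate(counts) if c >= thr}
        assert set(hs.window_indices) == expected
        assert hs.n_hotspots >= m


def test_raising_fraction_never_removes_hotspots():
    rng = np.random.default_rng(7)
    counts = rng.poisson(8, size=200)
    prev: set[int] = set()
    for frac in (0.02, 0.05, 0.10, 0.25):
        hs = op.call_hotspots(
            track_from_counts(counts), op.AnalysisConfig(hotspot_fraction=frac), "g"
        )
        flagged = set(hs.window_indices)
        assert prev <= flagged
        prev = flagged


def test_hotspot_frame_is_bed_like():
    track = track_from_counts([9, 8, 8, 8] + [1] * 36)
    hs = op.call_hotspots(track, CFG, "malus")
    frame = hotspot_frame(track, hs)
    assert list(frame.columns) == ["chrom", "start", "end", "sv_count", "genome"]
    assert frame["sv_count"].min() == 8 and (frame["genome"] == "malus").all()


# ---------------------------------------------------------------------------
# correlation


def test_perfectly_linear_counts_give_r_of_one():
    track = track_from_counts([1, 2, 3, 4, 5])
    track.gene_count = 2 * track.sv_count
    assert op.correlate_sv_gene(track).r == pytest.approx(1.0)


def test_pearson_hand_example():
    track = track_from_counts([1, 2, 3, 4])
    track.gene_count = np.array([1, 3, 2, 4])
    res = op.correlate_sv_gene(track)
    assert res.r == pytest.approx(0.8)
    assert res.n == 4


def test_constant_vector_errors():
    track = track_from_counts([1, 2, 3, 4])
    track.gene_count = np.array([5, 5, 5, 5])
    with pytest.raises(ValueError, match="gene_count"):
        op.correlate_sv_gene(track)


# ---------------------------------------------------------------------------
# per-type summary


def test_summarize_sv_types_sums():
    records = [
        sv(0, 60, op.SVType.INS, length=60),
        sv(100, 160, op.SVType.INS, length=60),
        sv(0, 10_000, op.SVType.INV),
    ]
    table = op.summarize_sv_types(records).set_index(["haplome_id", "sv_type"])
    assert table.loc[("h1", "INS")].tolist() == [2, 120]
    assert table.loc[("h1", "INV")].tolist() == [1, 10_000]
    assert table.loc[("ALL", "INS")].tolist() == [2, 120]
    assert op.summarize_sv_types([]).empty


def test_summarize_sv_types_haplomes_sum_to_total():
    recs = [
        op.SVRecord("c", 0, 100, op.SVType.DEL, 100, "hapA"),
        op.SVRecord("c", 0, 200, op.SVType.DEL, 200, "hapB"),
    ]
    table = op.summarize_sv_types(recs).set_index(["haplome_id", "sv_type"])
    assert table.loc[("ALL", "DEL"), "n"] == 2
    assert table.loc[("ALL", "DEL"), "total_bp"] == 300
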