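"""Windowed SV breakpoint density, hotspot calling, and gene-density coupling.

The reference is tiled into fixed-width windows (default 400 kb; the
terminal window of each chromosome is truncated).  Each SV contributes
its two breakpoints — the reference start and end positions — to the
windows containing them, and hotspots are the windows whose breakpoint
count falls in the top fraction (default 5%, tie-inclusive) of all
windows.  Gene density per window uses the gene's start position so
each gene is counted exactly once.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneRecord, SVRecord, SVType


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the SV window analysis.

    ``min_sv_length`` (bp) keeps SVs of at least this size; the
    conventional reading of an "SV larger than 50 bp" is length >= 50,
    with ``strict_min_length`` switching to a strict > comparison.
    """

    min_sv_length: int = 50
    window_size: int = 400_000
    hotspot_fraction: float = 0.05
    strict_min_length: bool = False

    def __post_init__(self) -> None:
        if self.min_sv_length <= 0 or self.window_size <= 0:
            raise ValueError("min_sv_length and window_size must be positive")
        if not 0 < self.hotspot_fraction < 1:
            raise ValueError("hotspot_fraction must be in (0, 1)")


@dataclass
class WindowTrack:
    """Fixed-width windows tiling a reference, with per-window counts."""

    windows: pd.DataFrame  # columns chrom, start, end (0-based half-open)
    sv_count: np.ndarray | None = None
    gene_count: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_index(self, chrom: str, pos: int) -> int | None:
        """Index of the window containing ``pos``, or None if off-track."""
        span = self._chrom_spans.get(chrom)
        if span is None:
            return None
        first, length, width = span
        if not 0 <= pos < length:
            return None
        return first + pos // width

    @property
    def _chrom_spans(self) -> dict[str, tuple[int, int, int]]:
        spans: dict[str, tuple[int, int, int]] = {}
        for chrom, grp in self.windows.groupby("chrom", sort=False):
            first = int(grp.index[0])
            length = int(grp["end"].iloc[-1])
            width = int(grp["end"].iloc[0] - grp["start"].iloc[0]) if len(grp) > 1 else length
            # all but the last window have the nominal width
            if len(grp) > 1:
                width = int(grp["start"].iloc[1] - grp["start"].iloc[0])
            spans[chrom] = (first, length, width)
        return spans

    def to_frame(self) -> pd.DataFrame:
        out = self.windows.copy()
        if self.sv_count is not None:
            out["sv_count"] = self.sv_count
        if self.gene_count is not None:
            out["gene_count"] = self.gene_count
        return out


@dataclass
class HotspotSet:
    """Windows flagged as SV hotspots for one genome."""

    window_indices: np.ndarray
    threshold_count: int
    genome_label: str

    @property
    def n_hotspots(self) -> int:
        return len(self.window_indices)


@dataclass
class CorrelationResult:
    """Pearson correlation between SV and gene density over windows."""

    r: float
    p_value: float
    n: int


def filter_svs(records: Sequence[SVRecord], config: AnalysisConfig) -> list[SVRecord]:
    """Keep typed SVs meeting the length threshold, preserving order."""
    keep_types = set(SVType)
    if config.strict_min_length:
        return [r for r in records if r.length > config.min_sv_length and r.sv_type in keep_types]
    return [r for r in records if r.length >= config.min_sv_length and r.sv_type in keep_types]


def make_windows(chrom_lengths: Mapping[str, int], config: AnalysisConfig) -> WindowTrack:
    """Tile each chromosome into ceil(L/w) windows, last one truncated."""
    w = config.window_size
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"nonpositive length for chromosome {chrom}")
        for start in range(0, length, w):
            rows.append((chrom, start, min(start + w, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return WindowTrack(df)


def count_breakpoints(svs: Sequence[SVRecord], track: WindowTrack) -> WindowTrack:
    """Fill ``sv_count`` with the number of SV breakpoints per window.

    Each SV contributes its two breakpoints — positions ``ref_start``
    and ``ref_end - 1`` — to their containing windows; an SV wholly
    inside one window adds 2 to it.  Breakpoints on chromosomes absent
    from the track are skipped and summarized in a warning.
    """
    counts = np.zeros(track.n_windows, dtype=np.int64)
    spans = track._chrom_spans
    skipped = 0
    for sv in svs:
        span = spans.get(sv.ref_chrom)
        if span is None:
            skipped += 2
            continue
        first, length, width = span
        for pos in (sv.ref_start, max(sv.ref_end - 1, sv.ref_start)):
            if 0 <= pos < length:
                counts[first + pos // width] += 1
            else:
                skipped += 1
    if skipped:
        warnings.warn(f"{skipped} SV breakpoint(s) fell outside the window track")
    return replace(track, sv_count=counts)


def count_genes(genes: Sequence[GeneRecord], track: WindowTrack) -> WindowTrack:
    """Fill ``gene_count``: each gene goes to the window holding its start."""
    counts = np.zeros(track.n_windows, dtype=np.int64)
    spans = track._chrom_spans
    skipped = 0
    for g in genes:
        span = spans.get(g.chrom)
        if span is None:
            skipped += 1
            continue
        first, length, width = span
        if 0 <= g.start < length:
            counts[first + g.start // width] += 1
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} gene(s) fell outside the window track")
    return replace(track, gene_count=counts)


def call_hotspots(
    track: WindowTrack, config: AnalysisConfig, genome_label: str = "all"
) -> HotspotSet:
    """Flag the top-fraction windows by SV breakpoint count, tie-inclusive.

    With n windows, ``m = ceil(hotspot_fraction * n)`` and the threshold
    is the m-th largest count; every window at or above it is flagged,
    so ties can push the hotspot count above m.  An all-zero track
    yields an empty set with a warning.
    """
    if track.sv_count is None:
        raise ValueError("sv_count not filled; run count_breakpoints first")
    counts = np.asarray(track.sv_count)
    if counts.max(initial=0) == 0:
        warnings.warn(f"all window SV counts are zero for {genome_label}; no hotspots called")
        return HotspotSet(np.array([], dtype=int), threshold_count=0, genome_label=genome_label)
    m = ceil(config.hotspot_fraction * len(counts))
    threshold = int(np.sort(counts)[::-1][m - 1])
    flagged = np.flatnonzero(counts >= threshold)
    return HotspotSet(flagged, threshold_count=threshold, genome_label=genome_label)


def correlate_sv_gene(track: WindowTrack) -> CorrelationResult:
    """Pearson correlation of SV vs gene density over all windows.

    The two-sided p-value comes from the t-transform with n-2 degrees of
    freedom (``scipy.stats.pearsonr``).
    """
    if track.sv_count is None or track.gene_count is None:
        raise ValueError("both sv_count and gene_count must be filled")
    x = np.asarray(track.sv_count, dtype=float)
    y = np.asarray(track.gene_count, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 windows for a correlation")
    for name, v in (("sv_count", x), ("gene_count", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def summarize_sv_types(records: Sequence[SVRecord]) -> pd.DataFrame:
    """Per haplome x SV type: record count and total bp, plus totals."""
    cols = ["haplome_id", "sv_type", "n", "total_bp"]
    if not records:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "haplome_id": [r.haplome_id for r in records],
            "sv_type": [r.sv_type.value for r in records],
            "length": [r.length for r in records],
        }
    )
    per = (
        df.groupby(["haplome_id", "sv_type"], sort=True)["length"]
        .agg(n="count", total_bp="sum")
        .reset_index()
    )
    totals = (
        df.groupby("sv_type", sort=True)["length"].agg(n="count", total_bp="sum").reset_index()
    )
    totals.insert(0, "haplome_id", "ALL")
    return pd.concat([per, totals], ignore_index=True)[cols]


def hotspot_frame(track: WindowTrack, hotspots: HotspotSet) -> pd.DataFrame:
    """BED-like table of hotspot windows with their breakpoint counts."""
    sub = track.windows.iloc[hotspots.window_indices].copy()
    sub["sv_count"] = np.asarray(track.sv_count)[hotspots.window_indices]
    sub["genome"] = hotspots.genome_label
    return sub.reset_index(drop=True)
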