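"""Interval computations: peak filtering, summit windows, peak-to-gene
association, promoter overlap, fragment filtering and overlap counting.

A small vectorized interval engine (merged-interval prefix sums and
searchsorted counting) backs every operation; all coordinates are 0-based
half-open. Semantics follow bedtools where the analogous tool exists:
``associate_peaks_to_genes`` mirrors ``bedtools closest -t all`` followed by
the gene-body-or-near-TSS filter, and ``count_overlaps`` mirrors
``bedtools multicov`` (>= 1 overlapping base, half-open, a fragment may count
toward several loci).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneRecord, PeakRecord


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval [{self.start}, {self.end}): start must be < end")


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned fragment; length = end - start >= 1."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"fragment [{self.start}, {self.end}): length must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakGeneAssignment:
    """One peak assigned to one gene, with the relation that justified it."""

    peak_index: int
    gene_id: str
    relation: str  # "gene_body" | "promoter_proximal"
    distance: int  # 0 if the peak overlaps the gene body


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into disjoint sorted runs."""
    if not intervals:
        return []
    srt = sorted(intervals)
    merged = [list(srt[0])]
    for s, e in srt[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class _MergedCoverage:
    """Per-chromosome merged intervals with prefix sums of covered bases."""

    def __init__(self, intervals: Iterable[Interval]):
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for iv in intervals:
            by_chrom[iv.chrom].append((iv.start, iv.end))
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            merged = merge_intervals(ivs)
            starts = np.array([s for s, _ in merged])
            ends = np.array([e for _, e in merged])
            prefix = np.concatenate([[0], np.cumsum(ends - starts)])
            self._index[chrom] = (starts, ends, prefix)

    def covered_before(self, chrom: str, pos: int) -> int:
        """Total covered bases in [0, pos)."""
        if chrom not in self._index:
            return 0
        starts, ends, prefix = self._index[chrom]
        i = int(np.searchsorted(starts, pos, side="right"))  # intervals starting < pos
        total = int(prefix[i])
        if i > 0 and ends[i - 1] > pos:  # last one runs past pos
            total -= int(ends[i - 1] - pos)
        return total

    def covered_within(self, chrom: str, start: int, end: int) -> int:
        return self.covered_before(chrom, end) - self.covered_before(chrom, start)


def filter_repeat_overlap(
    peaks: Sequence[PeakRecord],
    masked: Sequence[Interval],
    max_fraction: float = 0.5,
) -> list[PeakRecord]:
    """Drop peaks whose masked-base fraction strictly exceeds ``max_fraction``.

    Masked intervals may overlap; they are merged before coverage is
    computed, so the result is invariant to pre-merging. A peak with exactly
    the threshold fraction is kept (the removal rule is "> 50% overlap").
    """
    cov = _MergedCoverage(masked)
    kept = []
    for peak in peaks:
        masked_bases = cov.covered_within(peak.chrom, peak.start, peak.end)
        if masked_bases <= max_fraction * peak.length:
            kept.append(peak)
    return kept


def summit_flank(
    peaks: Sequence[PeakRecord],
    flank: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Interval]:
    """The ``flank`` bp on either side of each summit: [summit-flank, summit+flank+1),
    clipped to chromosome bounds when sizes are given."""
    out = []
    for i, peak in enumerate(peaks):
        if peak.summit is None:
            name = peak.name or f"{peak.chrom}:{peak.start}-{peak.end} (index {i})"
            raise ValueError(f"peak {name} has no summit")
        start = max(0, peak.summit - flank)
        end = peak.summit + flank + 1
        if chrom_sizes is not None and peak.chrom in chrom_sizes:
            end = min(end, chrom_sizes[peak.chrom])
        out.append(Interval(peak.chrom, start, end))
    return out


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Bases strictly between two half-open intervals; 0 when they overlap or abut."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if a_end <= b_start else a_start - b_end


def _tss_distance(peak_start: int, peak_end: int, tss_base: int) -> int:
    """Base-coordinate distance from the peak's nearest base to the TSS base
    (0 when the TSS base lies inside the peak)."""
    return max(0, peak_start - tss_base, tss_base - (peak_end - 1))


def associate_peaks_to_genes(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneRecord],
    proximal_bp: int = 5000,
) -> list[PeakGeneAssignment]:
    """Assign each peak to its nearest gene(s) on the same chromosome when the
    peak overlaps the gene body or lies within ``proximal_bp`` of the TSS.

    Nearest is by minimal interval gap (0 on overlap); ties emit every tied
    gene. The TSS distance is the gap between the peak interval and the TSS
    base; a boundary distance of exactly ``proximal_bp`` is included.
    """
    by_chrom: dict[str, list[GeneRecord]] = defaultdict(list)
    for gene in genes:
        by_chrom[gene.chrom].append(gene)
    assignments: list[PeakGeneAssignment] = []
    for i, peak in enumerate(peaks):
        cands = by_chrom.get(peak.chrom)
        if not cands:
            continue
        gaps = np.array(
            [_interval_gap(peak.start, peak.end, g.start, g.end) for g in cands]
        )
        best = gaps.min()
        for j in np.nonzero(gaps == best)[0]:
            gene = cands[j]
            overlaps_body = peak.start < gene.end and gene.start < peak.end
            tss_base = gene.start if gene.strand == "+" else gene.end - 1
            tss_dist = _tss_distance(peak.start, peak.end, tss_base)
            if overlaps_body:
                assignments.append(PeakGeneAssignment(i, gene.gene_id, "gene_body", 0))
            elif tss_dist <= proximal_bp:
                assignments.append(
                    PeakGeneAssignment(i, gene.gene_id, "promoter_proximal", tss_dist)
                )
    return assignments


def unique_target_genes(assignments: Iterable[PeakGeneAssignment]) -> set[str]:
    """Deduplicated set of genes with >= 1 assigned peak."""
    return {a.gene_id for a in assignments}


def promoter_intervals(
    genes: Sequence[GeneRecord],
    promoter_bp: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Interval]:
    """Strand-aware promoter windows [TSS-w, TSS) (+) / [TSS, TSS+w) (-),
    clipped at chromosome bounds; empty windows dropped."""
    out = []
    for gene in genes:
        if gene.strand == "+":
            start, end = gene.tss - promoter_bp, gene.tss
        else:
            start, end = gene.tss, gene.tss + promoter_bp
        start = max(0, start)
        if chrom_sizes is not None and gene.chrom in chrom_sizes:
            end = min(end, chrom_sizes[gene.chrom])
        if start < end:
            out.append(Interval(gene.chrom, start, end))
    return out


def promoter_fraction(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneRecord],
    promoter_bp: int = 1000,
) -> float:
    """Fraction of peaks overlapping any strand-aware promoter window."""
    if not peaks:
        return 0.0
    windows = promoter_intervals(genes, promoter_bp)
    by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for w in windows:
        by_chrom[w.chrom].append(w)
    n_in = 0
    for peak in peaks:
        for w in by_chrom.get(peak.chrom, ()):
            if peak.start < w.end and w.start < peak.end:
                n_in += 1
                break
    return n_in / len(peaks)


def fragment_size_filter(
    fragments: Sequence[FragmentRecord], max_len: int = 120
) -> list[FragmentRecord]:
    """Keep fragments strictly shorter than ``max_len`` ("under 120 bp")."""
    return [f for f in fragments if f.length < max_len]


def count_overlaps(
    fragments: Sequence[FragmentRecord], loci: Sequence[Interval]
) -> np.ndarray:
    """Per-locus count of fragments overlapping by >= 1 base (half-open:
    a fragment ending where a locus starts does not overlap)."""
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    frag_chroms: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for f in fragments:
        frag_chroms[f.chrom].append((f.start, f.end))
    for chrom, pairs in frag_chroms.items():
        arr = np.array(pairs)
        starts_by_chrom[chrom] = np.sort(arr[:, 0])
        ends_by_chrom[chrom] = np.sort(arr[:, 1])
    counts = np.zeros(len(loci), dtype=np.int64)
    for i, locus in enumerate(loci):
        if locus.chrom not in starts_by_chrom:
            continue
        starts = starts_by_chrom[locus.chrom]
        ends = ends_by_chrom[locus.chrom]
        n = len(starts)
        # overlap <=> start < locus.end and end > locus.start; the two
        # excluded sets (start >= end_l, end <= start_l) are disjoint
        n_right = n - np.searchsorted(starts, locus.end, side="left")
        n_left = np.searchsorted(ends, locus.start, side="right")
        counts[i] = n - n_right - n_left
    return counts
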