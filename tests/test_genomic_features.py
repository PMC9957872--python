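"""Interval engine vs quadratic per-base brute-force oracles."""

import numpy as np
import pytest

from regboot.genomic_features import (
    FragmentRecord,
    Interval,
    associate_peaks_to_genes,
    count_overlaps,
    filter_repeat_overlap,
    fragment_size_filter,
    merge_intervals,
    promoter_fraction,
    promoter_intervals,
    summit_flank,
    unique_target_genes,
)
from regboot.io_formats import GeneRecord, PeakRecord


# ----------------------------------------------------------------- oracles

def bruteforce_masked_bases(peak, masked):
    covered = set()
    for iv in masked:
        if iv.chrom == peak.chrom:
            covered |= set(range(max(iv.start, peak.start), min(iv.end, peak.end)))
    return len(covered)


def bruteforce_assignments(peaks, genes, proximal_bp):
    out = set()
    for i, p in enumerate(peaks):
        cands = [g for g in genes if g.chrom == p.chrom]
        if not cands:
            continue

        def gap(g):
            if p.start < g.end and g.start < p.end:
                return 0
            return g.start - p.end if p.end <= g.start else p.start - g.end

        best = min(gap(g) for g in cands)
        for g in cands:
            if gap(g) != best:
                continue
            overlaps = p.start < g.end and g.start < p.end
            tss_base = g.start if g.strand == "+" else g.end - 1
            d = max(0, p.start - tss_base, tss_base - (p.end - 1))
            if overlaps:
                out.add((i, g.gene_id, "gene_body", 0))
            elif d <= proximal_bp:
                out.add((i, g.gene_id, "promoter_proximal", d))
    return out


# --------------------------------------------------------- repeat filtering

def test_repeat_overlap_strict_threshold():
    peak = PeakRecord("chr1", 0, 100)
    kept = filter_repeat_overlap([peak], [Interval("chr1", 0, 50)])
    assert kept == [peak]  # exactly 50% -> kept
    assert filter_repeat_overlap([peak], [Interval("chr1", 0, 51)]) == []


def test_repeat_overlap_matches_bruteforce_and_premerge_invariant():
    rng = np.random.default_rng(11)
    for _ in range(200):
        peaks = [
            PeakRecord("chr1", s, s + int(rng.integers(5, 60)))
            for s in rng.integers(0, 500, size=8)
        ]
        masked = [
            Interval("chr1", s, s + int(rng.integers(1, 80)))
            for s in rng.integers(0, 500, size=10)
        ]
        expected = [
            p for p in peaks if bruteforce_masked_bases(p, masked) <= 0.5 * p.length
        ]
        got = filter_repeat_overlap(peaks, masked)
        assert got == expected
        # invariance to pre-merging the masked set
        merged = [
            Interval("chr1", s, e)
            for s, e in merge_intervals([(m.start, m.end) for m in masked])
        ]
        assert filter_repeat_overlap(peaks, merged) == expected


# ------------------------------------------------------------ summit flanks

def test_summit_flank_window_and_clipping():
    peaks = [
        PeakRecord("chr1", 900, 1100, summit=1000),
        PeakRecord("chr1", 0, 40, summit=20),
        PeakRecord("chr1", 5, 10, summit=7),
    ]
    out = summit_flank(peaks, flank=50)
    assert (out[0].start, out[0].end) == (950, 1051)
    assert (out[1].start, out[1].end) == (0, 71)
    zero = summit_flank([peaks[2]], flank=0)
    assert (zero[0].start, zero[0].end) == (7, 8)


def test_summit_flank_requires_summit():
    with pytest.raises(ValueError, match="summit"):
        summit_flank([PeakRecord("chr1", 0, 10)])


# ----------------------------------------------------- peak-gene association

def test_association_boundary_at_exactly_5kb():
    gene = GeneRecord("g", "chr1", 100_000, 105_000, "+")  # TSS base 100000
    at_boundary = PeakRecord("chr1", 94_900, 95_001)  # nearest base 95000, d=5000
    beyond = PeakRecord("chr1", 94_899, 95_000)  # nearest base 94999, d=5001
    hit = associate_peaks_to_genes([at_boundary], [gene])
    assert [(a.gene_id, a.relation, a.distance) for a in hit] == [
        ("g", "promoter_proximal", 5000)
    ]
    assert associate_peaks_to_genes([beyond], [gene]) == []


def test_peak_inside_gene_body():
    gene = GeneRecord("g", "chr1", 1000, 3000, "+")
    peak = PeakRecord("chr1", 1500, 1600)
    (a,) = associate_peaks_to_genes([peak], [gene])
    assert (a.relation, a.distance) == ("gene_body", 0)


def test_association_matches_allpairs_bruteforce():
    rng = np.random.default_rng(12)
    for _ in range(100):
        chroms = ["chr1", "chr2"]
        genes = [
            GeneRecord(
                f"g{j}",
                chroms[int(rng.integers(0, 2))],
                int(s),
                int(s) + int(rng.integers(500, 3000)),
                "+-"[int(rng.integers(0, 2))],
            )
            for j, s in enumerate(rng.integers(0, 50_000, size=10))
        ]
        peaks = [
            PeakRecord(chroms[int(rng.integers(0, 2))], int(s), int(s) + int(rng.integers(50, 400)))
            for s in rng.integers(0, 50_000, size=10)
        ]
        got = {
            (a.peak_index, a.gene_id, a.relation, a.distance)
            for a in associate_peaks_to_genes(peaks, genes, 5000)
        }
        assert got == bruteforce_assignments(peaks, genes, 5000)


def test_unique_target_genes_dedup():
    class A:
        def __init__(self, g):
            self.gene_id = g

    assert unique_target_genes([A("a"), A("a"), A("b")]) == {"a", "b"}
    assert unique_target_genes([]) == set()


# -------------------------------------------------------- promoter fraction

def test_promoter_fraction_limits():
    genes = [GeneRecord("g", "chr1", 5000, 8000, "+")]
    inside = [PeakRecord("chr1", 4500, 4600)]
    assert promoter_fraction(inside, genes) == 1.0
    assert promoter_fraction(inside, []) == 0.0
    assert promoter_fraction([], genes) == 0.0


def test_promoter_fraction_matches_bruteforce():
    rng = np.random.default_rng(13)
    for _ in range(100):
        genes = [
            GeneRecord(f"g{j}", "chr1", int(s), int(s) + 2000, "+-"[j % 2])
            for j, s in enumerate(rng.integers(1500, 30_000, size=6))
        ]
        peaks = [
            PeakRecord("chr1", int(s), int(s) + int(rng.integers(50, 500)))
            for s in rng.integers(0, 35_000, size=12)
        ]
        windows = promoter_intervals(genes, 1000)
        n_in = sum(
            1
            for p in peaks
            if any(p.start < w.end and w.start < p.end for w in windows)
        )
        assert promoter_fraction(peaks, genes, 1000) == pytest.approx(n_in / len(peaks))


# --------------------------------------------------------- fragment filter

def test_fragment_size_filter_is_strict():
    frags = [FragmentRecord("chr1", 0, L) for L in (119, 120, 121)]
    assert [f.length for f in fragment_size_filter(frags)] == [119]
    assert fragment_size_filter([]) == []


def test_fragment_size_filter_matches_naive():
    rng = np.random.default_rng(14)
    frags = [
        FragmentRecord("chr1", int(s), int(s) + int(L))
        for s, L in zip(rng.integers(0, 10_000, 10_000), rng.integers(1, 300, 10_000))
    ]
    assert fragment_size_filter(frags) == [f for f in frags if f.length < 120]


# ---------------------------------------------------------- overlap counts

def test_count_overlaps_halfopen_abutment():
    frag = [FragmentRecord("chr1", 100, 200)]
    loci = [Interval("chr1", 100, 200), Interval("chr1", 200, 300), Interval("chr1", 199, 300)]
    np.testing.assert_array_equal(count_overlaps(frag, loci), [1, 0, 1])


def test_count_overlaps_matches_bruteforce_and_is_additive():
    rng = np.random.default_rng(15)
    frags = [
        FragmentRecord("chr1", int(s), int(s) + int(rng.integers(20, 200)))
        for s in rng.integers(0, 20_000, size=400)
    ]
    loci = [
        Interval("chr1", int(s), int(s) + int(rng.integers(100, 1000)))
        for s in rng.integers(0, 20_000, size=50)
    ]
    brute = np.array(
        [
            sum(1 for f in frags if f.start < l.end and l.start < f.end)
            for l in loci
        ]
    )
    np.testing.assert_array_equal(count_overlaps(frags, loci), brute)
    # additivity over disjoint fragment subsets
    half = len(frags) // 2
    np.testing.assert_array_equal(
        count_overlaps(frags[:half], loci) + count_overlaps(frags[half:], loci),
        brute,
    )
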