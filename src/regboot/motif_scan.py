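"""FIMO-style PWM scanning of strand-aware promoter windows.

A promoter window is the 1 kb immediately upstream of a gene's TSS on the
gene's strand. Windows are scanned on both strands with a log2 log-odds
score; a position is a hit when its score reaches the threshold at which the
background score distribution has tail mass <= alpha (FIMO's occurrence
criterion). The score distribution is computed exactly by dynamic
programming over per-position scores discretized to a fixed grid, so the
threshold and per-hit p-values are exact up to the grid resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import PWM, GeneRecord

DEFAULT_ALPHA = 1e-4
DEFAULT_GRID = 1e-3  # bits per discretization step of the score DP

_CODE = np.full(256, 4, dtype=np.int8)  # everything unrecognized behaves like N
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0 C=1 G=2 T=3, N (or other) = 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return "".join(_RC.get(b, "N") for b in reversed(seq.upper()))


@dataclass(frozen=True)
class PromoterWindow:
    """The window immediately upstream of one gene's TSS (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside a promoter window.

    ``offset`` is the 0-based match start within the window (forward-genome
    coordinates regardless of hit strand); ``pvalue`` is the exact background
    tail mass at the hit's score.
    """

    gene_id: str
    offset: int
    strand: str
    score: float
    pvalue: float


def promoter_windows(
    genes: Sequence[GeneRecord],
    chrom_sizes: Mapping[str, int],
    window_size: int = 1000,
) -> list[PromoterWindow]:
    """Strand-aware upstream windows: [TSS-w, TSS) on +, [TSS, TSS+w) on -.

    Windows are truncated at chromosome boundaries; zero-length results are
    dropped with a warning.
    """
    windows: list[PromoterWindow] = []
    for gene in genes:
        if gene.chrom not in chrom_sizes:
            raise KeyError(f"gene {gene.gene_id}: chromosome {gene.chrom!r} not in chrom_sizes")
        size = chrom_sizes[gene.chrom]
        if gene.strand == "+":
            start, end = gene.tss - window_size, gene.tss
        else:
            start, end = gene.tss, gene.tss + window_size
        start, end = max(0, start), min(size, end)
        if start >= end:
            warnings.warn(
                f"gene {gene.gene_id}: promoter window is empty after truncation; skipped",
                stacklevel=2,
            )
            continue
        windows.append(PromoterWindow(gene.gene_id, gene.chrom, start, end, gene.strand))
    return windows


def _score_matrix(pwm: PWM) -> np.ndarray:
    """w x 5 log-odds matrix; column 4 (N) carries the per-position minimum.

    Zero-probability cells get a large-but-finite penalty so integer
    arithmetic in the DP stays well defined; the penalty is far below any
    usable threshold.
    """
    lo = pwm.log_odds()
    finite_min = lo[np.isfinite(lo)].min() if np.isfinite(lo).any() else 0.0
    penalty = min(finite_min, 0.0) - 100.0
    lo = np.where(np.isfinite(lo), lo, penalty)
    return np.column_stack([lo, lo.min(axis=1)])


def logodds_score(pwm: PWM, window_seq: str) -> float:
    """Log2 log-odds score of one w-mer; N contributes the per-position minimum."""
    if len(window_seq) != pwm.width:
        raise ValueError(
            f"sequence length {len(window_seq)} does not match motif width {pwm.width}"
        )
    sm = _score_matrix(pwm)
    codes = encode(window_seq)
    return float(sm[np.arange(pwm.width), codes].sum())


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact background distribution of the grid-discretized motif score."""

    grid: float
    min_int: int
    probs: np.ndarray  # probs[i] = P(int score == min_int + i)
    int_scores: np.ndarray  # w x 5 per-position integer scores (col 4 = N)

    @property
    def tail(self) -> np.ndarray:
        return np.cumsum(self.probs[::-1])[::-1]

    def pvalue_of_int(self, s: int | np.ndarray) -> np.ndarray:
        """P(background integer score >= s); 1 below the support, 0 above it."""
        tail = self.tail
        idx = np.clip(np.asarray(s) - self.min_int, 0, len(tail))
        return np.append(tail, 0.0)[idx]


def score_distribution(pwm: PWM, grid: float = DEFAULT_GRID) -> ScoreDistribution:
    """Dynamic program over positions: exact PMF of the discretized score."""
    sm = _score_matrix(pwm)
    ints = np.rint(sm / grid).astype(np.int64)
    bg = pwm.background
    probs = np.array([1.0])
    lo = 0
    for i in range(pwm.width):
        step = ints[i, :4]
        new_lo = lo + int(step.min())
        new_hi = lo + len(probs) - 1 + int(step.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = lo + int(step[b]) - new_lo
            new[off : off + len(probs)] += probs * bg[b]
        probs, lo = new, new_lo
    return ScoreDistribution(grid=grid, min_int=lo, probs=probs, int_scores=ints)


def score_threshold(
    pwm: PWM, alpha: float, grid: float = DEFAULT_GRID
) -> tuple[float, float]:
    """Smallest achievable score s with P(score >= s | background) <= alpha.

    Returns ``(threshold_score, exact_tail_mass)``. When even the single best
    word has tail mass > alpha, the returned threshold exceeds the maximum
    achievable score (so scanning yields no hits) and the tail mass is 0.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    dist = score_distribution(pwm, grid)
    achievable = np.nonzero(dist.probs > 0)[0]
    tail = dist.tail
    ok = achievable[tail[achievable] <= alpha]
    if len(ok) == 0:
        return (dist.min_int + achievable[-1] + 1) * grid, 0.0
    best = ok[0]
    return (dist.min_int + best) * grid, float(tail[best])


def _int_window_scores(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Integer score of every w-window of an encoded sequence (vectorized)."""
    w = ints.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(codes, w)
    return ints[np.arange(w), view].sum(axis=1)


def scan_promoters(
    windows: Sequence[PromoterWindow],
    sequences: Mapping[str, str],
    pwm: PWM,
    alpha: float = DEFAULT_ALPHA,
    grid: float = DEFAULT_GRID,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan promoter windows on both strands; emit every position at or above
    the alpha score threshold, sorted by (gene_id, offset, strand).

    Scores are compared on the same integer grid the threshold DP uses, so
    scanning and the threshold's tail mass are mutually exact.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    dist = score_distribution(pwm, grid)
    thr_score, _ = score_threshold(pwm, alpha, grid)
    thr_int = int(np.rint(thr_score / grid))
    sm = _score_matrix(pwm)
    w = pwm.width
    hits: list[MotifHit] = []
    for win in windows:
        if win.chrom not in sequences:
            raise KeyError(f"window for {win.gene_id}: chromosome {win.chrom!r} not in sequences")
        seq = sequences[win.chrom][win.start : win.end].upper()
        if len(seq) < w:
            continue
        codes_f = encode(seq)
        strands = [("+", codes_f)]
        if both_strands:
            strands.append(("-", encode(reverse_complement(seq))))
        for strand, codes in strands:
            int_scores = _int_window_scores(codes, dist.int_scores)
            idx = np.nonzero(int_scores >= thr_int)[0]
            if len(idx) == 0:
                continue
            pvals = dist.pvalue_of_int(int_scores[idx])
            view = np.lib.stride_tricks.sliding_window_view(codes, w)
            real = sm[np.arange(w), view[idx]].sum(axis=1)
            for j, pos in enumerate(idx):
                offset = int(pos) if strand == "+" else len(seq) - w - int(pos)
                hits.append(
                    MotifHit(win.gene_id, offset, strand, float(real[j]), float(pvals[j]))
                )
    hits.sort(key=lambda h: (h.gene_id, h.offset, h.strand))
    return hits


def genes_with_feature(items: Iterable) -> set[str]:
    """Gene ids with at least one motif hit or assigned peak (set semantics)."""
    return {item.gene_id for item in items}
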