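"""Readers, writers and validated domain types for the formats the pipeline touches.

All genomic coordinates are 0-based, half-open ``[start, end)`` (BED
convention) everywhere inside the package; any 1-based dialect is converted
at this boundary. The TSS of a plus-strand gene is its ``start``; for a
minus-strand gene it is its ``end`` (the 0-based position ``end - 1`` is the
first transcribed base, and promoter windows are computed strand-aware from
it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_STRANDS = frozenset("+-")


@dataclass(frozen=True)
class GeneRecord:
    """One gene: coordinates, strand, and the derived TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcriptional start site as a 0-based boundary coordinate."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PeakRecord:
    """One called peak; ``summit`` is an absolute base position when known."""

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak [{self.start}, {self.end}): start must be < end")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak [{self.start}, {self.end}): summit {self.summit} outside interval"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over A,C,G,T with a background distribution.

    ``probs`` has one row per motif position (columns in A,C,G,T order);
    every row sums to 1 after pseudocount regularization.
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"probs must be w x 4 with w >= 1, got shape {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("probs must be nonnegative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM row must sum to 1 within 1e-9")
        if bg.shape != (4,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must be a length-4 probability vector")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self) -> np.ndarray:
        """w x 4 log2 odds matrix versus the background (zero probs -> -inf)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            name=self.name,
        )


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression result for one contrast."""

    gene_id: str
    log2fc: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"gene {self.gene_id}: padj {self.padj} outside [0, 1]")


@dataclass(frozen=True)
class CountMatrix:
    """Loci x samples raw counts plus per-sample spike-in read totals."""

    loci: tuple[str, ...]
    samples: tuple[str, ...]
    counts: np.ndarray
    spike_in: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        spike = np.asarray(self.spike_in)
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "spike_in", spike)
        if counts.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        if spike.shape != (len(self.samples),):
            raise ValueError("spike_in length must equal the number of samples")
        if np.any(counts < 0) or np.any(spike < 0):
            raise ValueError("counts and spike_in must be nonnegative")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[PeakRecord]:
    """Read BED3+ / narrowPeak into PeakRecords, in file order.

    Coordinates are taken verbatim as 0-based half-open. For 10-column
    narrowPeak lines the summit is ``start + column-10 offset`` (an offset of
    -1, meaning "not called", yields no summit).
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            summit = None
            if len(fields) >= 10:
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer summit offset") from exc
                if offset >= 0:
                    summit = start + offset
            try:
                records.append(
                    PeakRecord(fields[0], start, end, summit=summit, score=score, name=name)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_bed(records: Iterable[PeakRecord], path: str | Path) -> None:
    """Write PeakRecords as narrowPeak-flavoured BED (10 columns when any summit set)."""
    records = list(records)
    narrow = any(r.summit is not None for r in records)
    with open(path, "w") as fh:
        for r in records:
            cols = [r.chrom, str(r.start), str(r.end)]
            if narrow:
                cols += [
                    r.name or ".",
                    "0" if r.score is None else format(r.score, "g"),
                    ".", "0", "-1", "-1",
                    str(r.summit - r.start) if r.summit is not None else "-1",
                ]
            elif r.name is not None or r.score is not None:
                cols += [r.name or ".", "0" if r.score is None else format(r.score, "g")]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercased sequence}; names cut at first whitespace."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ParseError(f"{path}: duplicate sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def chrom_sizes(sequences: Mapping[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in sequences.items()}


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a gene annotation TSV with columns gene_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: annotation is missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    return [
        GeneRecord(row.gene_id, row.chrom, int(row.start), int(row.end), row.strand)
        for row in df.itertuples()
    ]


def write_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWM formats
# ---------------------------------------------------------------------------

def _pwm_from_counts(
    counts: np.ndarray, pseudocount: float, background: np.ndarray, name: str
) -> PWM:
    if np.any(counts < 0):
        raise ParseError(f"motif {name!r}: negative matrix entries")
    reg = counts + pseudocount
    totals = reg.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ParseError(f"motif {name!r}: a position has zero total count and zero pseudocount")
    return PWM(probs=reg / totals, background=background, pseudocount=pseudocount, name=name)


def read_pwm(
    path: str | Path, format: str = "jaspar", pseudocount: float = 0.01
) -> PWM:
    """Read a single motif in JASPAR (count rows) or MEME minimal format.

    Counts become probabilities by adding ``pseudocount`` per cell and
    renormalizing each position. Background is uniform unless the MEME header
    supplies one.
    """
    fmt = format.lower()
    if fmt not in ("jaspar", "meme"):
        raise ValueError(f"unknown PWM format {format!r}")
    bio_fmt = "jaspar" if fmt == "jaspar" else "minimal"
    with open(path) as fh:
        try:
            parsed = list(bio_motifs.parse(fh, bio_fmt))
        except Exception as exc:  # biopython raises bare ValueError/KeyError
            raise ParseError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not parsed:
        raise ParseError(f"{path}: no motif found")
    motif = parsed[0]
    counts = np.array([[motif.counts[base][i] for base in "ACGT"]
                       for i in range(motif.length)], dtype=float)
    background = np.full(4, 0.25)
    if fmt == "meme" and getattr(motif, "background", None):
        background = np.array([motif.background[b] for b in "ACGT"], dtype=float)
        background = background / background.sum()
    name = motif.name or getattr(motif, "matrix_id", "") or Path(path).stem
    return _pwm_from_counts(counts, pseudocount, background, name)


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_deg_table(
    path: str | Path,
    contrast: str | None = None,
    gene_col: str = "gene_id",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> list[DEGRecord]:
    """Read a DEG TSV into records; missing padj stays missing, never imputed.

    If the table has a ``contrast`` column and ``contrast`` is given, rows are
    restricted to that contrast first.
    """
    df = pd.read_csv(path, sep="\t", dtype={gene_col: str})
    for col in (gene_col, lfc_col, padj_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if contrast is not None and "contrast" in df.columns:
        df = df[df["contrast"] == contrast]
    if df[gene_col].duplicated().any():
        dup = df.loc[df[gene_col].duplicated(), gene_col].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    records: list[DEGRecord] = []
    for row in df.itertuples():
        padj = getattr(row, padj_col)
        padj = None if pd.isna(padj) else float(padj)
        try:
            records.append(DEGRecord(getattr(row, gene_col), float(getattr(row, lfc_col)), padj))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def read_count_matrix(counts_path: str | Path, spike_path: str | Path) -> CountMatrix:
    """Read a loci x samples counts TSV plus a (sample, spike_reads) TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    spike = pd.read_csv(spike_path, sep="\t", dtype={0: str})
    if spike.shape[1] < 2:
        raise ParseError(f"{spike_path}: expected columns sample, spike_reads")
    spike_map = dict(zip(spike.iloc[:, 0], spike.iloc[:, 1]))
    missing = [s for s in counts.columns if s not in spike_map]
    if missing:
        raise ParseError(f"{spike_path}: no spike-in counts for samples {missing}")
    return CountMatrix(
        loci=tuple(str(i) for i in counts.index),
        samples=tuple(str(c) for c in counts.columns),
        counts=counts.to_numpy(),
        spike_in=np.array([spike_map[s] for s in counts.columns]),
    )


def read_breath_table(path: str | Path) -> pd.DataFrame:
    """Read a per-breath TSV (index, t_insp, t_exp, v_insp, v_exp, length)."""
    df = pd.read_csv(path, sep="\t")
    required = {"t_insp", "t_exp", "v_insp", "v_exp", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: breath table missing columns {sorted(missing)}")
    if (df["length"] <= 0).any():
        raise ParseError(f"{path}: breath lengths must be > 0")
    return df.reset_index(drop=True)
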