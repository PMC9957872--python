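"""DEG partitioning by regulating transcription factor, rescue calls across
genotypes, IP-MS significance filtering, and candidate prioritization.

The partition is exclusive and exhaustive: each DEG is labeled with the one
TF whose target set contains it, "multiple TFs" when two or more do, and
"none" otherwise. A disease-contrast DEG is "rescued" when its adjusted p
rises above 0.05 in the interaction-ablated (corrected) contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import DEGRecord

MULTIPLE = "multiple TFs"
NONE = "none"
PADJ_THRESHOLD = 0.05


@dataclass(frozen=True)
class TFPartition:
    """Exclusive DEG labels with category counts and proportions."""

    labels: dict[str, str]  # gene_id -> category
    counts: dict[str, int]
    proportions: dict[str, float]
    tf_names: tuple[str, ...]


def classify_degs(
    deg_set: Iterable[str], tf_gene_sets: Mapping[str, Iterable[str]]
) -> TFPartition:
    """Label each DEG by the unique TF whose peak-target set contains it,
    "multiple TFs" for >= 2, "none" for 0; order of TF sets is irrelevant."""
    deg_set = set(deg_set)
    if not deg_set:
        raise ValueError("deg_set must be nonempty")
    if not tf_gene_sets:
        raise ValueError("at least one TF gene set is required")
    sets = {name: set(genes) for name, genes in tf_gene_sets.items()}
    tf_names = tuple(sorted(sets))
    labels: dict[str, str] = {}
    for gene in deg_set:
        hits = [name for name in tf_names if gene in sets[name]]
        labels[gene] = hits[0] if len(hits) == 1 else (MULTIPLE if hits else NONE)
    categories = [*tf_names, MULTIPLE, NONE]
    counts = {c: 0 for c in categories}
    for cat in labels.values():
        counts[cat] += 1
    n = len(deg_set)
    proportions = {c: counts[c] / n for c in categories}
    return TFPartition(labels=labels, counts=counts, proportions=proportions, tf_names=tf_names)


@dataclass(frozen=True)
class RescueCall:
    gene_id: str
    status: str  # "rescued" | "not_rescued" | "not_deg" | "indeterminate"


@dataclass(frozen=True)
class RescueResult:
    calls: tuple[RescueCall, ...]
    n_rescued: int
    n_not_rescued: int
    n_indeterminate: int

    @property
    def fraction(self) -> float:
        """Rescued / (rescued + not_rescued) among determinate disease DEGs."""
        denom = self.n_rescued + self.n_not_rescued
        return self.n_rescued / denom if denom else float("nan")


def rescue_calls(
    deg_disease: Sequence[DEGRecord],
    deg_corrected: Sequence[DEGRecord],
    padj_threshold: float = PADJ_THRESHOLD,
) -> RescueResult:
    """Rescued: padj < 0.05 in the disease contrast and padj > 0.05 in the
    corrected contrast. Disease DEGs missing a corrected padj are reported as
    indeterminate and excluded from the rescue fraction rather than silently
    classified."""
    corrected = {rec.gene_id: rec.padj for rec in deg_corrected}
    calls: list[RescueCall] = []
    n_res = n_not = n_ind = 0
    for rec in deg_disease:
        if rec.padj is None or rec.padj >= padj_threshold:
            calls.append(RescueCall(rec.gene_id, "not_deg"))
            continue
        padj_c = corrected.get(rec.gene_id)
        if padj_c is None:
            calls.append(RescueCall(rec.gene_id, "indeterminate"))
            n_ind += 1
        elif padj_c > padj_threshold:
            calls.append(RescueCall(rec.gene_id, "rescued"))
            n_res += 1
        else:
            calls.append(RescueCall(rec.gene_id, "not_rescued"))
            n_not += 1
    return RescueResult(tuple(calls), n_res, n_not, n_ind)


def ip_ms_significant(
    proteins: pd.DataFrame,
    lfc_col: str = "log2fc",
    p_col: str = "pvalue",
    min_abs_lfc: float = 4.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Keep proteins with |log2FC| >= 4 (inclusive) and p < 0.05 (strict)
    versus the preclear control."""
    keep = (proteins[lfc_col].abs() >= min_abs_lfc) & (proteins[p_col] < max_p)
    return proteins.loc[keep].copy()


def prioritize_candidates(
    degs: Sequence[DEGRecord],
    partition: TFPartition,
    expressed: Iterable[str],
    tf: str,
    top_k: int,
    signed: bool = False,
) -> list[str]:
    """Top-k single-TF DEG candidates also expressed in the validation system,
    ranked by |log2FC| (or signed log2FC with ``signed=True``), ties broken
    lexicographically by gene_id."""
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if tf not in partition.tf_names:
        raise ValueError(f"{tf!r} is not a single-TF category of this partition")
    expressed = set(expressed)
    ranked = sorted(
        (
            rec
            for rec in degs
            if partition.labels.get(rec.gene_id) == tf and rec.gene_id in expressed
        ),
        key=lambda rec: (-(rec.log2fc if signed else abs(rec.log2fc)), rec.gene_id),
    )
    return [rec.gene_id for rec in ranked[:top_k]]
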