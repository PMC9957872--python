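"""Spike-in calibration of CUT&RUN count matrices and |log2FC| comparison.

Each sample's counts are scaled by C / (its exogenous E. coli spike-in read
count), making signal comparable across libraries that differ in
amplification or sequencing depth. Per-locus fold changes versus a reference
group are computed on group means with a pseudocount, and two genotypes'
|log2FC| distributions are compared with a Mann-Whitney test (exact
enumeration for small groups).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

CALIBRATION_CONSTANT = 10_000.0
EXACT_MAX_N = 8


@dataclass(frozen=True)
class ScaleFactors:
    """Per-sample calibration factors C / spike_in."""

    factors: np.ndarray
    constant: float
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        factors = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "samples", tuple(self.samples))
        if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
            raise ValueError("scale factors must be finite and > 0")


def spikein_scale_factors(
    spike_in: Sequence[int],
    C: float = CALIBRATION_CONSTANT,
    samples: Sequence[str] = (),
) -> ScaleFactors:
    """factor_i = C / spike_in_i. C cancels in fold changes and only sets the
    units of reported signal."""
    spike = np.asarray(spike_in, dtype=float)
    if np.any(spike == 0):
        bad = [samples[i] if samples else str(i) for i in np.nonzero(spike == 0)[0]]
        raise ValueError(
            f"spike-in count is zero for sample(s) {bad}; exclude these samples "
            "before calibration"
        )
    return ScaleFactors(factors=C / spike, constant=C, samples=tuple(samples))


def normalize_counts(matrix: CountMatrix, factors: ScaleFactors) -> np.ndarray:
    """Scale each sample's column by its calibration factor."""
    if factors.factors.shape != (len(matrix.samples),):
        raise ValueError(
            f"{factors.factors.shape[0]} factors for {len(matrix.samples)} samples"
        )
    return matrix.counts.astype(float) * factors.factors[np.newaxis, :]


def locus_log2fc(
    normalized: np.ndarray,
    samples: Sequence[str],
    group_a: Sequence[str],
    group_ref: Sequence[str],
    loci: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-locus log2((mean_a + pc) / (mean_ref + pc)) and its absolute value.

    Returns a DataFrame indexed by locus with columns mean_a, mean_ref,
    log2fc, abs_log2fc.
    """
    if not group_a or not group_ref:
        raise ValueError("both sample groups must be nonempty")
    index = {s: i for i, s in enumerate(samples)}
    missing = [s for s in [*group_a, *group_ref] if s not in index]
    if missing:
        raise ValueError(f"unknown samples {missing}")
    a_idx = [index[s] for s in group_a]
    r_idx = [index[s] for s in group_ref]
    mean_a = normalized[:, a_idx].mean(axis=1)
    mean_ref = normalized[:, r_idx].mean(axis=1)
    with np.errstate(divide="ignore"):  # pc=0 with a zero mean -> -inf, intended
        log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_ref + pseudocount)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_ref": mean_ref,
            "log2fc": log2fc,
            "abs_log2fc": np.abs(log2fc),
        },
        index=pd.Index(loci if loci is not None else range(len(mean_a)), name="locus"),
    )


def differential_signal(
    matrix: CountMatrix,
    groups: dict[str, Sequence[str]],
    reference: str,
    C: float = CALIBRATION_CONSTANT,
    pseudocount: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Calibrate and compute per-locus log2FC of every non-reference group
    versus ``reference``; returns {group: DiffSignal table}."""
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in groups")
    factors = spikein_scale_factors(matrix.spike_in, C, matrix.samples)
    normalized = normalize_counts(matrix, factors)
    return {
        name: locus_log2fc(
            normalized, matrix.samples, members, groups[reference],
            loci=matrix.loci, pseudocount=pseudocount,
        )
        for name, members in groups.items()
        if name != reference
    }


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a > b) pairs + half-credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Both groups of size <= 8: exact enumeration of all C(n+m, n) group
    labelings of the pooled values (correct under ties), with two-sided
    p = min(1, 2 * min(P(U <= u), P(U >= u))). Larger groups: tie-corrected
    normal approximation (scipy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both vectors must be nonempty")
    u_obs = _u_statistic(a, b)
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        n = a.size
        idx_all = np.arange(pooled.size)
        u_vals = np.array(
            [
                _u_statistic(pooled[list(comb)], pooled[np.setdiff1d(idx_all, comb)])
                for comb in itertools.combinations(idx_all, n)
            ]
        )
        eps = 1e-9
        cdf = np.mean(u_vals <= u_obs + eps)
        sf = np.mean(u_vals >= u_obs - eps)
        return u_obs, float(min(1.0, 2.0 * min(cdf, sf)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def abs_log2fc_compare(
    table_a: Sequence[float] | pd.DataFrame, table_b: Sequence[float] | pd.DataFrame
) -> tuple[float, float]:
    """Compare two genotypes' per-locus |log2FC| magnitudes (two-sided
    Mann-Whitney); accepts DiffSignal tables or plain vectors."""
    if isinstance(table_a, pd.DataFrame):
        table_a = table_a["abs_log2fc"].to_numpy()
    if isinstance(table_b, pd.DataFrame):
        table_b = table_b["abs_log2fc"].to_numpy()
    return mann_whitney(table_a, table_b)
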