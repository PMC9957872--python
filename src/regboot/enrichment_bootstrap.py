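"""Resampling enrichment of a gene feature (motif or peak) in a DEG set.

The observed statistic is the fraction of DEGs carrying the feature. The
null resamples, 10,000 times by default, a random set of the same number of
non-differentially-expressed genes and records the feature fraction of each
draw; the empirical p-value is (r+1)/(n+1) where r counts null fractions
strictly greater than the observed one. This is the standard
never-exactly-zero empirical p-value; its floor is 1/(n+1).

Each repetition draws its gene set uniformly without replacement, so the
number of feature genes in a draw is exactly hypergeometric; the sampler
draws that count directly, which is distribution-identical to materializing
the gene set and far cheaper. Repetitions are independent; the full null
vector is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import DEGRecord

DEFAULT_REPS = 10_000
PADJ_THRESHOLD = 0.05


@dataclass(frozen=True)
class GeneUniverse:
    """Disjoint DEG (padj < 0.05) and non-DEG (padj >= 0.05, present) sets."""

    deg: frozenset[str]
    non_deg: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "deg", frozenset(self.deg))
        object.__setattr__(self, "non_deg", frozenset(self.non_deg))
        if self.deg & self.non_deg:
            raise ValueError("deg and non_deg sets must be disjoint")

    @classmethod
    def from_deg_records(
        cls, records: Iterable[DEGRecord], padj_threshold: float = PADJ_THRESHOLD
    ) -> "GeneUniverse":
        """Split records into DEG/non-DEG; genes with missing padj are excluded
        from both (a non-DEG call requires an adjusted p to exist)."""
        deg, non_deg = set(), set()
        for rec in records:
            if rec.padj is None:
                continue
            (deg if rec.padj < padj_threshold else non_deg).add(rec.gene_id)
        return cls(frozenset(deg), frozenset(non_deg))


@dataclass(frozen=True)
class BootstrapResult:
    """Observed frequency, the resampled null, and the empirical p-value."""

    f_obs: float
    null_freqs: np.ndarray
    r: int
    n: int
    p: float
    seed: int
    n_deg: int = 0
    n_non_deg: int = 0
    n_feature: int = 0

    def summary(self) -> dict:
        q = np.quantile(self.null_freqs, [0.025, 0.25, 0.5, 0.75, 0.975])
        return {
            "f_obs": self.f_obs,
            "r": self.r,
            "n": self.n,
            "p": self.p,
            "seed": self.seed,
            "n_deg": self.n_deg,
            "n_non_deg": self.n_non_deg,
            "n_feature": self.n_feature,
            "null_mean": float(self.null_freqs.mean()),
            "null_sd": float(self.null_freqs.std(ddof=1)) if self.n > 1 else 0.0,
            "null_quantiles": {
                "2.5%": float(q[0]), "25%": float(q[1]), "50%": float(q[2]),
                "75%": float(q[3]), "97.5%": float(q[4]),
            },
        }


def feature_frequency(gene_set: Iterable[str], feature_genes: Iterable[str]) -> float:
    """|gene_set ∩ feature_genes| / |gene_set|."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    return len(gene_set & set(feature_genes)) / len(gene_set)


def bootstrap_null(
    non_deg: Iterable[str],
    feature_genes: Iterable[str],
    k: int,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> np.ndarray:
    """Null feature frequencies of ``reps`` uniform size-k draws (without
    replacement within a draw) from the non-DEG pool; deterministic given seed."""
    non_deg = set(non_deg)
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if not 1 <= k <= len(non_deg):
        raise ValueError(f"k must be in [1, {len(non_deg)}], got {k}")
    n_good = len(non_deg & set(feature_genes))
    n_bad = len(non_deg) - n_good
    rng = np.random.default_rng(seed)
    counts = rng.hypergeometric(n_good, n_bad, k, size=reps)
    return counts / k


def empirical_pvalue(f_obs: float, null_freqs: Sequence[float]) -> tuple[int, float]:
    """r = #{null strictly greater than f_obs}; p = (r+1)/(n+1), exactly rational."""
    null_freqs = np.asarray(null_freqs)
    if null_freqs.size == 0:
        raise ValueError("null_freqs must be nonempty")
    r = int(np.count_nonzero(null_freqs > f_obs))
    return r, (r + 1) / (null_freqs.size + 1)


def run_enrichment(
    universe: GeneUniverse,
    feature_genes: Iterable[str],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    tie: str = "greater",
) -> BootstrapResult:
    """Full procedure: observed DEG feature frequency, size-matched non-DEG
    null, and the (r+1)/(n+1) p-value.

    ``tie='geq'`` counts null values >= f_obs into r (the conservative
    variant); the default strictly-greater rule follows the statistic's
    definition.
    """
    feature_genes = set(feature_genes)
    if not universe.deg:
        raise ValueError("DEG set is empty; nothing to test")
    if len(universe.deg) > len(universe.non_deg):
        raise ValueError(
            f"DEG set ({len(universe.deg)}) larger than the non-DEG pool "
            f"({len(universe.non_deg)}); size-matched null draws are impossible. "
            "Check the padj threshold and the universe definition."
        )
    f_obs = feature_frequency(universe.deg, feature_genes)
    null = bootstrap_null(universe.non_deg, feature_genes, len(universe.deg), reps, seed)
    if tie == "greater":
        r, p = empirical_pvalue(f_obs, null)
    elif tie == "geq":
        r = int(np.count_nonzero(null >= f_obs))
        p = (r + 1) / (null.size + 1)
    else:
        raise ValueError(f"tie must be 'greater' or 'geq', got {tie!r}")
    return BootstrapResult(
        f_obs=f_obs, null_freqs=null, r=r, n=int(null.size), p=p, seed=seed,
        n_deg=len(universe.deg), n_non_deg=len(universe.non_deg),
        n_feature=len(feature_genes),
    )


def hypergeom_pvalue(universe: GeneUniverse, feature_genes: Iterable[str]) -> float:
    """Analytic one-sided depletion-of-null cross-check: probability that a
    uniform draw of |DEG| genes from the whole universe carries at least the
    observed number of feature genes. A sanity cross-check only; the headline
    statistic is the resampling p-value."""
    feature_genes = set(feature_genes)
    k_obs = len(universe.deg & feature_genes)
    pool = universe.deg | universe.non_deg
    n_good = len(pool & feature_genes)
    return float(stats.hypergeom.sf(k_obs - 1, len(pool), n_good, len(universe.deg)))
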