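"""Whole-body plethysmography QC: per-breath exclusions, sliding-window
tachypnea filtering, the inter-breath interval irregularity (IBII) statistic,
and subject-level inclusion.

The pipeline order is fixed: per-breath exclusions first, then the
sliding-window filter on the surviving chronological stream, then the
subject-level minimum-breath check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_T_INSP = 0.025  # s; breaths with shorter inspiration are movement artifacts
MAX_T_EXP = 10.0  # s
MAX_VEXP_RATIO = 2.0  # v_exp more than twice v_insp flags a bad waveform
WINDOW = 200  # breaths
RATE_THRESHOLD = 600.0  # breaths/min; above this a breath counts as "fast"
MAX_FAST_FRACTION = 0.10
MIN_BREATHS = 100  # subject inclusion


@dataclass(frozen=True)
class BreathRecord:
    """One breath as emitted by the acquisition software."""

    index: int
    t_insp: float
    t_exp: float
    v_insp: float
    v_exp: float
    length: float  # total breath duration, seconds

    def __post_init__(self) -> None:
        if min(self.t_insp, self.t_exp, self.v_insp, self.v_exp) < 0:
            raise ValueError(f"breath {self.index}: times and volumes must be >= 0")
        if self.length <= 0:
            raise ValueError(f"breath {self.index}: length must be > 0")


def breaths_to_frame(breaths: list[BreathRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.index, b.t_insp, b.t_exp, b.v_insp, b.v_exp, b.length) for b in breaths],
        columns=["index", "t_insp", "t_exp", "v_insp", "v_exp", "length"],
    )


def filter_breaths(breaths: pd.DataFrame) -> pd.DataFrame:
    """Per-breath exclusions, all strict: inspiratory time under 0.025 s,
    expiratory time over 10 s, or expiratory tidal volume more than twice the
    inspiratory tidal volume."""
    bad = (
        (breaths["t_insp"] < MIN_T_INSP)
        | (breaths["t_exp"] > MAX_T_EXP)
        | (breaths["v_exp"] > MAX_VEXP_RATIO * breaths["v_insp"])
    )
    return breaths.loc[~bad]


def sliding_window_filter(
    breaths: pd.DataFrame,
    window: int = WINDOW,
    rate_threshold: float = RATE_THRESHOLD,
    max_fraction: float = MAX_FAST_FRACTION,
) -> pd.DataFrame:
    """Remove intervals of sustained tachypnea.

    A breath is fast when its instantaneous rate 60/length exceeds
    ``rate_threshold``. Every window of ``window`` consecutive breaths whose
    fast fraction strictly exceeds ``max_fraction`` is flagged, and breaths
    belonging to any flagged window are removed. Streams shorter than the
    window are judged as a single window. Windows slide by one breath.
    """
    n = len(breaths)
    if n == 0:
        return breaths
    fast = (60.0 / breaths["length"].to_numpy()) > rate_threshold
    if n < window:
        if fast.sum() / n > max_fraction:
            return breaths.iloc[0:0]
        return breaths
    # fast counts of all n-window+1 windows via prefix sums
    prefix = np.concatenate([[0], np.cumsum(fast)])
    win_counts = prefix[window:] - prefix[:-window]
    flagged = (win_counts / window) > max_fraction
    remove = np.zeros(n, dtype=bool)
    # breath j is in windows starting at max(0, j-window+1) .. min(j, n-window)
    starts = np.nonzero(flagged)[0]
    for s in starts:
        remove[s : s + window] = True
    return breaths.loc[~remove]


def ibii(breath_lengths) -> np.ndarray:
    """IBII_i = |L[i+1] - L[i]| / L[i] over consecutive breath lengths."""
    lengths = np.asarray(breath_lengths, dtype=float)
    if lengths.size < 2:
        raise ValueError("IBII requires at least 2 breaths")
    if np.any(lengths <= 0):
        raise ValueError("all breath lengths must be > 0")
    return np.abs(np.diff(lengths)) / lengths[:-1]


def subject_inclusion(kept_breaths, minimum: int = MIN_BREATHS) -> bool:
    """A subject is included iff it retains at least ``minimum`` reliable
    breaths after both filters."""
    n = len(kept_breaths) if not isinstance(kept_breaths, int) else kept_breaths
    return n >= minimum


def qc_pipeline(
    breaths: pd.DataFrame,
    window: int = WINDOW,
    rate_threshold: float = RATE_THRESHOLD,
    max_fraction: float = MAX_FAST_FRACTION,
    minimum: int = MIN_BREATHS,
) -> dict:
    """Run the full QC chain and summarize: kept breaths, IBII mean/median,
    and the subject inclusion flag."""
    stage1 = filter_breaths(breaths)
    stage2 = sliding_window_filter(stage1, window, rate_threshold, max_fraction)
    included = subject_inclusion(stage2, minimum)
    lengths = stage2["length"].to_numpy()
    vals = ibii(lengths) if lengths.size >= 2 else np.array([])
    return {
        "n_input": int(len(breaths)),
        "n_after_breath_filter": int(len(stage1)),
        "n_kept": int(len(stage2)),
        "included": bool(included),
        "ibii_mean": float(vals.mean()) if vals.size else float("nan"),
        "ibii_median": float(np.median(vals)) if vals.size else float("nan"),
        "kept": stage2,
    }
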