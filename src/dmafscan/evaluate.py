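"""Replicate-level evaluation metrics: type I error, power, localization.

Power comparisons between permutation-based methods are made at an
*empirical* significance threshold: the alpha-quantile of the null-model
p-value distribution, so that methods with slightly mis-calibrated null
behavior are compared on an equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

#: Window sizes must have at least this many analyzable replicates to be
#: included in power summaries.
DEFAULT_MIN_REPS = 700


@dataclass
class ReplicateOutcome:
    """Per-replicate scan summary for one window size.

    ``window_size`` is an integer number of variants, or the string
    ``"whole"`` for the whole-region (single-window) baseline.
    """

    replicate: int
    model: str
    region: str
    window_size: int | str
    min_corrected_p: float
    detected: bool
    localized: bool

    def __post_init__(self) -> None:
        if self.detected != (self.min_corrected_p < 0.05):
            # detection is defined at alpha = 0.05 in the scan itself
            raise ValueError("detection flag inconsistent with min corrected p")


def type_i_error(
    null_p: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Fraction of null-model p-values below ``alpha``, with an exact
    (Clopper-Pearson) 95% binomial confidence interval."""
    p = np.asarray(null_p, dtype=np.float64)
    if p.size == 0:
        raise ValueError("no null p-values supplied")
    k = int(np.count_nonzero(p < alpha))
    ci = binomtest(k, p.size).proportion_ci(confidence_level=0.95, method="exact")
    return k / p.size, (float(ci.low), float(ci.high))


def empirical_power(
    null_p: np.ndarray, alt_p: np.ndarray, alpha: float = 0.05
) -> float:
    """Power at an empirical type-I-error rate of ``alpha``.

    The threshold is the lower alpha-quantile of the null p-values (the
    ``floor(alpha * n)``-th order statistic); power is the fraction of
    alternative-model p-values at or below it.
    """
    null_p = np.asarray(null_p, dtype=np.float64)
    alt_p = np.asarray(alt_p, dtype=np.float64)
    if null_p.size == 0 or alt_p.size == 0:
        raise ValueError("need nonempty null and alternative p-value vectors")
    k = int(np.floor(alpha * null_p.size))
    if k == 0:
        return 0.0
    threshold = np.sort(null_p)[k - 1]
    return float(np.mean(alt_p <= threshold))


def localization_rate(
    outcomes: list[ReplicateOutcome], window_size: int | str
) -> float:
    """Fraction of replicates (of one window size) whose most significant
    window half-overlapped the causal sub-region."""
    sized = [o for o in outcomes if o.window_size == window_size]
    if not sized:
        raise ValueError(f"no outcomes for window size {window_size!r}")
    return float(np.mean([o.localized for o in sized]))


def summarize_window_sizes(
    outcomes: list[ReplicateOutcome],
    min_reps: int = DEFAULT_MIN_REPS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window-size summary table.

    Window sizes analyzed in fewer than ``min_reps`` replicates are
    excluded (a size can exceed the variant count of some replicates); the
    whole-region baseline, when present, is always reported.  Columns:
    model, region, window_size, n_reps, detection_rate, localization_rate.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    df = pd.DataFrame(
        {
            "model": [o.model for o in outcomes],
            "region": [o.region for o in outcomes],
            "window_size": [o.window_size for o in outcomes],
            "min_corrected_p": [o.min_corrected_p for o in outcomes],
            "localized": [o.localized for o in outcomes],
        }
    )
    out = (
        df.groupby(["model", "region", "window_size"], sort=False)
        .agg(
            n_reps=("min_corrected_p", "size"),
            detection_rate=("min_corrected_p", lambda s: np.mean(s < alpha)),
            localization_rate=("localized", "mean"),
        )
        .reset_index()
    )
    keep = (out["n_reps"] >= min_reps) | (out["window_size"] == "whole")
    return out[keep].reset_index(drop=True)
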