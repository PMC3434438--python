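"""Sliding-window DMAF scan with step-down permutation correction.

A window is a fixed-size run of consecutive analysis variants (counted in
variants, not base pairs).  Every window of a given size is tested with the
DMAF statistic, and family-wise error across the windows of that size is
controlled with a Westfall-Young step-down procedure built from a second,
independent set of shared phenotype permutations:

1. ``B1`` permuted phenotypes give each window its null distribution of
   ``V`` and hence the observed empirical p-value.
2. ``B2`` further permuted phenotypes are each scored against those same
   first-set null distributions, filling an ``m x B2`` p-value matrix ``M``
   (one shared relabeling per column, applied to every window).
3. Observed p-values are ordered ascending; the smallest is compared with
   the column minima of ``M`` (corrected p = fraction of minima at or
   below it), then its row is dropped and the procedure steps down, taking
   a running maximum to keep corrected p-values monotone.

Sharing one permutation per column across windows is what makes the column
minima a valid draw of the minimum p-value under the complete null; no
correction is applied across different window sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_N_PERM,
    TIE_REL_TOL,
    CaseControlFrequencies,
    GenotypeMatrix,
    Phenotype,
    _apply_flavor,
    analysis_variants,
    compute_variant_stats,
    dmaf_weights,
    permuted_case_labels,
)

logger = logging.getLogger("dmafscan")

#: Minimum shift between window starts, in variants.
MIN_WINDOW_STEP = 5

#: Window shift as a fraction of the window length.
STEP_FRACTION = 0.10


@dataclass(frozen=True)
class WindowSpec:
    """Half-open variant-index interval ``[start, stop)`` (0-based)."""

    start: int
    stop: int

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass
class WindowResult:
    """One window's statistic with raw and step-down corrected p-values."""

    window: WindowSpec
    statistic: float
    p_raw: float
    p_corrected: float


@dataclass
class ScanResult:
    """Sliding-window results per window size.

    ``analysis_variants`` holds the original column indices of the
    genotype matrix that form the (filtered) analysis set; window indices
    in ``results`` refer to positions within that set.
    """

    results: dict[int, list[WindowResult]]
    analysis_variants: np.ndarray

    def detected(self, size: int, alpha: float = 0.05) -> bool:
        """True if any window of ``size`` has corrected p below ``alpha``."""
        return any(r.p_corrected < alpha for r in self.results[size])

    def min_corrected_p(self, size: int) -> float:
        return min(r.p_corrected for r in self.results[size])


def window_step(window_size: int) -> int:
    """Window shift: 5 variants or 10% of the window length, whichever is
    greater (10% rounded half-up)."""
    return max(MIN_WINDOW_STEP, int(np.floor(STEP_FRACTION * window_size + 0.5)))


def enumerate_windows(n_variants: int, window_size: int) -> list[WindowSpec]:
    """All window placements of ``window_size`` over ``n_variants`` variants.

    Windows start at 0 and advance by :func:`window_step`; if the stepping
    pattern undershoots the end of the region, one final window anchored at
    ``n_variants - window_size`` is appended so every variant is covered.
    """
    if not 1 <= window_size <= n_variants:
        raise ValueError(
            f"window size {window_size} exceeds the {n_variants} available variants"
        )
    step = window_step(window_size)
    starts = list(range(0, n_variants - window_size + 1, step))
    if starts[-1] + window_size < n_variants:
        starts.append(n_variants - window_size)
    return [WindowSpec(s, s + window_size) for s in starts]


def _window_sums(wd: np.ndarray, windows: list[WindowSpec]) -> np.ndarray:
    """Sum the weighted-difference array over each window via prefix sums.

    ``wd`` has shape ``(J,)`` or ``(J, B)``; returns ``(m,)`` or ``(m, B)``.
    """
    pad = [(1, 0)] + [(0, 0)] * (wd.ndim - 1)
    cs = np.pad(np.cumsum(wd, axis=0), pad)
    starts = np.array([w.start for w in windows])
    stops = np.array([w.stop for w in windows])
    return cs[stops] - cs[starts]


def _observed_pvalues(v1: np.ndarray, v_obs: np.ndarray) -> np.ndarray:
    """Per-window empirical p of the observed statistics against the
    first-set null, ``#{V1 >= V_obs} / B1``, counting float ties as >=."""
    tol = TIE_REL_TOL * (1.0 + np.abs(v_obs))
    return (v1 >= (v_obs - tol)[:, None]).mean(axis=1)


def _second_set_pvalues(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Empirical p of each second-set statistic against the first-set null.

    ``p[i, k] = #{V1[i, :] >= V2[i, k]} / B1``, evaluated row-wise with
    float ties counting as >=.
    """
    m, b1 = v1.shape
    v1_sorted = np.sort(v1, axis=1)
    out = np.empty_like(v2)
    for i in range(m):
        shifted = v2[i] - TIE_REL_TOL * (1.0 + np.abs(v2[i]))
        out[i] = b1 - np.searchsorted(v1_sorted[i], shifted, side="left")
    return out / b1


def build_pvalue_matrix(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    windows: list[WindowSpec],
    flavor: str = "abs",
    B1: int = DEFAULT_N_PERM,
    B2: int = DEFAULT_N_PERM,
    seed: int | None = None,
    variant_set: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed per-window p-values and the permutation p-value matrix ``M``.

    Windows index into ``variant_set`` (default: all polymorphic variants,
    in genomic order).  Both permutation sets consist of phenotype
    relabelings shared across windows; second-set p-values are referenced
    to each window's first-set null distribution.

    Returns
    -------
    p_obs : (m,) observed empirical p per window
    M : (m, B2) p-value matrix
    v_obs : (m,) observed statistics
    """
    if B1 < 1 or B2 < 1:
        raise ValueError("permutation counts B1 and B2 must be at least 1")
    stats = compute_variant_stats(genotypes, phenotype)
    if variant_set is None:
        aset = np.flatnonzero(stats.polymorphic)
    else:
        aset = np.asarray(variant_set)
    w = dmaf_weights(stats, aset)
    engine = CaseControlFrequencies(genotypes, aset)
    rng = np.random.default_rng(seed)

    wd_obs = w * _apply_flavor(engine.diff(phenotype.status), flavor)
    v_obs = _window_sums(wd_obs, windows)

    labels1 = permuted_case_labels(phenotype, B1, rng)
    v1 = _window_sums(w[:, None] * _apply_flavor(engine.diff(labels1), flavor), windows)
    p_obs = _observed_pvalues(v1, v_obs)

    labels2 = permuted_case_labels(phenotype, B2, rng)
    v2 = _window_sums(w[:, None] * _apply_flavor(engine.diff(labels2), flavor), windows)
    M = _second_set_pvalues(v1, v2)
    return p_obs, M, v_obs


def stepdown_correct(observed_p: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Step-down (Westfall-Young) corrected p-values, in window order.

    The observed p-values are sorted ascending and the rows of ``M``
    reordered identically.  The smallest p is compared against the column
    minima of the full matrix; each subsequent p against the column minima
    of the matrix with all previous rows removed, with a running maximum
    enforcing monotonicity.  Because rows are removed in sorted order, the
    successive column minima are suffix minima over the sorted rows.

    Column minima equal to the observed p are counted (``<=``): observed
    and permutation p-values live on the same 1/B grid with an atom at 0,
    and the inclusive count is what keeps the family-wise error rate at
    its nominal level (a strict ``<`` would hand every window that happens
    to reach raw p = 0 a corrected p of 0).
    """
    p = np.asarray(observed_p, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != p.shape[0]:
        raise ValueError("M must have one row per observed p-value")
    b2 = M.shape[1]
    order = np.argsort(p, kind="stable")
    suffix_min = np.minimum.accumulate(M[order][::-1], axis=0)[::-1]
    counts = (suffix_min <= p[order][:, None]).sum(axis=1)
    corrected_sorted = np.maximum.accumulate(counts / b2)
    corrected = np.empty_like(corrected_sorted)
    corrected[order] = corrected_sorted
    return corrected


def sliding_window_scan(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    window_sizes: list[int],
    flavor: str = "abs",
    variant_filter: str = "all",
    rare_threshold: float = 0.05,
    B1: int = DEFAULT_N_PERM,
    B2: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ScanResult:
    """Run the sliding-window DMAF scan for each window size independently.

    The variant filter (``all`` polymorphic, or ``rare`` only) is applied
    before windowing.  The two permutation sets are drawn once and reused
    across window sizes, which keeps replicate scans cheap and means a
    given seed fixes the entire scan.  Sizes larger than the available
    number of analysis variants are skipped with a logged notice.  No
    correction is applied across window sizes.
    """
    stats = compute_variant_stats(genotypes, phenotype)
    aset = analysis_variants(stats, variant_filter, rare_threshold)
    if aset.size == 0:
        raise ValueError("no variants pass the analysis filter")

    w = dmaf_weights(stats, aset)
    engine = CaseControlFrequencies(genotypes, aset)
    rng = np.random.default_rng(seed)

    wd_obs = w * _apply_flavor(engine.diff(phenotype.status), flavor)
    labels1 = permuted_case_labels(phenotype, B1, rng)
    wd1 = w[:, None] * _apply_flavor(engine.diff(labels1), flavor)
    labels2 = permuted_case_labels(phenotype, B2, rng)
    wd2 = w[:, None] * _apply_flavor(engine.diff(labels2), flavor)

    results: dict[int, list[WindowResult]] = {}
    for size in window_sizes:
        if size > aset.size:
            logger.info(
                "window size %d skipped: only %d analysis variants", size, aset.size
            )
            continue
        windows = enumerate_windows(aset.size, size)
        v_obs = _window_sums(wd_obs, windows)
        v1 = _window_sums(wd1, windows)
        v2 = _window_sums(wd2, windows)
        p_obs = _observed_pvalues(v1, v_obs)
        M = _second_set_pvalues(v1, v2)
        corrected = stepdown_correct(p_obs, M)
        results[size] = [
            WindowResult(win, float(v), float(p), float(pc))
            for win, v, p, pc in zip(windows, v_obs, p_obs, corrected)
        ]
    return ScanResult(results=results, analysis_variants=aset)


def localize(
    results: list[WindowResult], causal_range: tuple[int, int]
) -> bool:
    """Did the most significant window(s) land on the causal sub-region?

    Takes the window(s) attaining the minimum corrected p-value (exact
    ties form a set; its extent is the union of their variant indices) and
    returns True iff the overlap with ``causal_range`` (a half-open
    variant-index interval), measured in number of variants, is at least
    half the number of variants in the window or tied set.  Counting
    markers in the union — rather than the min-start-to-max-stop span —
    keeps the criterion meaningful when strong signals produce several
    tied windows with LD-driven stragglers away from the causal cluster.
    An empty causal range (null model) returns False by convention.
    """
    if not results:
        raise ValueError("no window results to localize from")
    lo, hi = causal_range
    if hi <= lo:
        return False
    pmin = min(r.p_corrected for r in results)
    tied = [r for r in results if r.p_corrected == pmin]
    members: set[int] = set()
    for r in tied:
        members.update(range(r.window.start, r.window.stop))
    overlap = sum(1 for i in members if lo <= i < hi)
    return overlap >= 0.5 * len(members)
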