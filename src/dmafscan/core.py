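"""Difference-in-MAF (DMAF) region-based association test.

DMAF aggregates case/control allele-frequency differences across the
variants of a region.  For variant ``j`` with case minor-allele frequency
``X_j`` and control minor-allele frequency ``Y_j``, the per-variant
contribution is a positive function of the difference,

    D_j = |X_j - Y_j|        ("abs" flavor)
    D_j = (X_j - Y_j)**2     ("sq" flavor),

so risk variants (``X_j > Y_j``) and protective variants (``X_j < Y_j``)
contribute symmetrically.  The region statistic is the weighted sum

    V = sum_{j in A} w_j * D_j,

over the analysis set ``A`` (all polymorphic variants, or only the rare
ones), with frequency-based weights

    w_j = 1 / sqrt(n_j * q_j * (1 - q_j)),

where ``q_j`` is the pooled (cases + controls) minor-allele frequency and
``n_j`` the number of subjects with a non-missing genotype.  Rarer alleles
therefore receive larger weight.  Significance is assessed empirically by
permuting case/control labels; ``q_j``, ``n_j`` and ``w_j`` are
phenotype-free and stay fixed across permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("dmafscan")

#: Pooled-MAF threshold below which (inclusive) a variant is called rare.
RARE_MAF_THRESHOLD = 0.05

#: Default number of phenotype permutations for empirical p-values.
DEFAULT_N_PERM = 1000

#: Recognised statistic flavors.
FLAVORS = ("abs", "sq")

MISSING = -1

#: Relative tolerance when comparing permutation statistics: relabelings
#: that are mathematically tied must count as "at least as extreme" even
#: when floating-point summation order perturbs them.
TIE_REL_TOL = 1e-9


def _count_ge(values: np.ndarray, reference: float) -> int:
    """Number of ``values >= reference`` up to floating-point ties."""
    return int(np.count_nonzero(values >= reference - TIE_REL_TOL * (1.0 + abs(reference))))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x variants matrix of diploid minor/alternate-allele counts.

    Parameters
    ----------
    counts
        Integer array of shape ``(n_subjects, n_variants)`` with entries in
        ``{0, 1, 2}``; missing genotypes are coded ``-1``.
    sample_ids, variant_ids
        Unique identifiers, aligned to the rows / columns of ``counts``.
    positions
        Per-variant base-pair coordinate (1-based, VCF convention),
        nondecreasing.
    """

    counts: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.positions = np.asarray(self.positions)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D subjects x variants array")
        n, j = self.counts.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts rows")
        if len(self.variant_ids) != j or len(self.positions) != j:
            raise ValueError("variant metadata length does not match counts columns")
        valid = np.isin(self.counts, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.counts[~valid])
            raise ValueError(f"genotype entries must be in {{-1,0,1,2}}; found {bad}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.variant_ids)) != j:
            raise ValueError("variant_ids are not unique")
        if j > 1 and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be nondecreasing")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]


@dataclass
class Phenotype:
    """Binary case/control labels aligned to a :class:`GenotypeMatrix`.

    ``status[i] == 1`` marks subject ``i`` as a case, ``0`` as a control.
    """

    status: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.ndim != 1:
            raise ValueError("status must be a 1-D vector")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status entries must be 0 (control) or 1 (case)")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("phenotype needs at least one case and one control")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.status) - self.status.sum())


@dataclass
class VariantStats:
    """Per-variant frequency summaries, stored column-wise as arrays.

    All arrays have one entry per variant of the originating matrix.
    ``X``/``Y`` are case/control minor-allele frequencies computed over
    non-missing genotypes within each group; ``q`` is the pooled MAF after
    minor-allele orientation (``q <= 0.5``); ``n`` is the number of subjects
    with a non-missing genotype.  ``flipped`` records variants whose allele
    coding was complemented so that the pooled frequency is the minor one.
    ``polymorphic`` is False for variants that must be excluded from
    analysis: pooled ``q == 0`` or a group with no genotyped subject.
    """

    X: np.ndarray
    Y: np.ndarray
    q: np.ndarray
    n: np.ndarray
    flipped: np.ndarray
    polymorphic: np.ndarray

    def __len__(self) -> int:
        return len(self.q)

    def take(self, indices: np.ndarray) -> "VariantStats":
        """Subset the table to ``indices`` (in the given order)."""
        idx = np.asarray(indices)
        return VariantStats(
            X=self.X[idx],
            Y=self.Y[idx],
            q=self.q[idx],
            n=self.n[idx],
            flipped=self.flipped[idx],
            polymorphic=self.polymorphic[idx],
        )


@dataclass
class TestResult:
    """Outcome of a DMAF permutation test on one variant set."""

    statistic: float
    p_value: float
    n_perm: int
    variant_set: np.ndarray
    flavor: str

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Frequency engine (shared with the sliding-window scan)
# ---------------------------------------------------------------------------


class CaseControlFrequencies:
    """Vectorized case-minus-control allele-frequency differences.

    Precomputes phenotype-free totals for a fixed variant subset so that
    ``X_j - Y_j`` can be evaluated for the observed labels and for whole
    batches of permuted labels with matrix products.  Group frequencies are
    taken over non-missing genotypes; if a label assignment leaves a group
    with no genotyped subject at some variant, that variant's difference is
    set to 0 (no information).
    """

    def __init__(self, genotypes: GenotypeMatrix, variant_set: np.ndarray):
        counts = genotypes.counts[:, np.asarray(variant_set)]
        miss = counts == MISSING
        self._has_missing = bool(miss.any())
        self._g = np.where(miss, 0, counts).astype(np.float64)
        self._tot_allele = self._g.sum(axis=0)  # (J,)
        self._tot_n = (~miss).sum(axis=0).astype(np.float64)  # subjects genotyped
        if self._has_missing:
            self._nonmiss = (~miss).astype(np.float64)

    def diff(self, case_labels: np.ndarray) -> np.ndarray:
        """Return ``X - Y`` for one label vector ``(n,)`` or a batch ``(n, B)``."""
        lab = np.asarray(case_labels, dtype=np.float64)
        one_d = lab.ndim == 1
        if one_d:
            lab = lab[:, None]
        case_allele = self._g.T @ lab  # (J, B)
        if self._has_missing:
            case_n = self._nonmiss.T @ lab
        else:
            case_n = np.broadcast_to(lab.sum(axis=0), case_allele.shape)
        ctrl_allele = self._tot_allele[:, None] - case_allele
        ctrl_n = self._tot_n[:, None] - case_n
        with np.errstate(divide="ignore", invalid="ignore"):
            d = case_allele / (2.0 * case_n) - ctrl_allele / (2.0 * ctrl_n)
        d = np.nan_to_num(d, nan=0.0, posinf=0.0, neginf=0.0)
        return d[:, 0] if one_d else d


def permuted_case_labels(
    phenotype: Phenotype, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_perm`` uniform permutations of the case/control labels.

    Returns an ``(n_subjects, n_perm)`` 0/1 matrix; each column is one
    relabeling with the observed numbers of cases and controls.
    """
    base = np.tile(phenotype.status, (n_perm, 1))
    return rng.permuted(base, axis=1).T


def _apply_flavor(diff: np.ndarray, flavor: str) -> np.ndarray:
    if flavor == "abs":
        return np.abs(diff)
    if flavor == "sq":
        return diff * diff
    raise ValueError(f"flavor must be one of {FLAVORS}, got {flavor!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_variant_stats(
    genotypes: GenotypeMatrix, phenotype: Phenotype
) -> VariantStats:
    """Per-variant case/control minor-allele frequencies.

    Frequencies are computed over non-missing genotypes within each group.
    The minor allele is defined by the pooled frequency: variants whose
    alternate-allele frequency exceeds 0.5 are complemented (``X``, ``Y``
    and ``q`` all refer to the minor allele afterwards).  Monomorphic
    variants (``q == 0``) and variants leaving either group without a
    genotyped subject are flagged ``polymorphic == False`` for upstream
    exclusion rather than raising.
    """
    if genotypes.n_variants == 0:
        raise ValueError("genotype matrix contains no variants")
    if genotypes.n_subjects != len(phenotype.status):
        raise ValueError("phenotype length does not match number of subjects")

    counts = genotypes.counts
    miss = counts == MISSING
    g = np.where(miss, 0, counts).astype(np.float64)
    case = phenotype.status.astype(bool)

    case_allele = g[case].sum(axis=0)
    ctrl_allele = g[~case].sum(axis=0)
    case_n = (~miss[case]).sum(axis=0)
    ctrl_n = (~miss[~case]).sum(axis=0)
    n = case_n + ctrl_n

    with np.errstate(divide="ignore", invalid="ignore"):
        X = case_allele / (2.0 * case_n)
        Y = ctrl_allele / (2.0 * ctrl_n)
        f = (case_allele + ctrl_allele) / (2.0 * n)

    flipped = f > 0.5
    X = np.where(flipped, 1.0 - X, X)
    Y = np.where(flipped, 1.0 - Y, Y)
    q = np.where(flipped, 1.0 - f, f)

    polymorphic = (q > 0) & (case_n > 0) & (ctrl_n > 0)
    X = np.nan_to_num(X, nan=0.0)
    Y = np.nan_to_num(Y, nan=0.0)
    q = np.nan_to_num(q, nan=0.0)

    n_excluded = int((~polymorphic).sum())
    if n_excluded:
        logger.debug("flagged %d variants for exclusion (monomorphic or "
                     "group all-missing)", n_excluded)
    return VariantStats(X=X, Y=Y, q=q, n=n, flipped=flipped, polymorphic=polymorphic)


def dmaf_weights(
    stats: VariantStats, variant_set: np.ndarray | None = None
) -> np.ndarray:
    """Frequency-based weights ``w_j = 1 / sqrt(n_j q_j (1 - q_j))``.

    Parameters
    ----------
    stats
        Per-variant table from :func:`compute_variant_stats`.
    variant_set
        Indices of the variants to weight (default: all).  Every selected
        variant must be polymorphic; a monomorphic variant here means the
        upstream exclusion step was skipped, which is an error.

    Returns
    -------
    Array of strictly positive finite weights aligned to ``variant_set``.
    """
    if variant_set is None:
        sub = stats
    else:
        sub = stats.take(variant_set)
    if np.any(~sub.polymorphic) or np.any(sub.q <= 0) or np.any(sub.q >= 1):
        raise ValueError(
            "monomorphic variant in weight computation; exclude q == 0 variants first"
        )
    return 1.0 / np.sqrt(sub.n * sub.q * (1.0 - sub.q))


def dmaf_statistic(
    stats: VariantStats,
    weights: np.ndarray,
    variant_set: np.ndarray,
    flavor: str = "abs",
) -> float:
    """The DMAF statistic ``V = sum_{j in A} w_j D_j`` for one variant set.

    ``weights`` must be aligned to ``variant_set`` (as returned by
    ``dmaf_weights(stats, variant_set)``).
    """
    idx = np.asarray(variant_set)
    if idx.size == 0:
        raise ValueError("variant_set is empty: nothing to test")
    sub = stats.take(idx)
    if np.any(~sub.polymorphic):
        raise ValueError("variant_set contains non-polymorphic variants")
    if len(weights) != idx.size:
        raise ValueError("weights not aligned to variant_set")
    d = _apply_flavor(sub.X - sub.Y, flavor)
    return float(np.dot(weights, d))


def classify_rare(
    stats: VariantStats, threshold: float = RARE_MAF_THRESHOLD
) -> np.ndarray:
    """Indices of polymorphic variants with pooled MAF ``q <= threshold``."""
    if not 0.0 < threshold <= 0.5:
        raise ValueError("rare-variant MAF threshold must lie in (0, 0.5]")
    return np.flatnonzero(stats.polymorphic & (stats.q <= threshold))


def analysis_variants(
    stats: VariantStats,
    variant_filter: str = "all",
    rare_threshold: float = RARE_MAF_THRESHOLD,
) -> np.ndarray:
    """Resolve the analysis set: all polymorphic variants, or only rare ones."""
    if variant_filter == "all":
        return np.flatnonzero(stats.polymorphic)
    if variant_filter == "rare":
        return classify_rare(stats, rare_threshold)
    raise ValueError(f"variant_filter must be 'all' or 'rare', got {variant_filter!r}")


def permutation_pvalue(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    variant_set: np.ndarray | None = None,
    flavor: str = "abs",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    add_one: bool = False,
) -> TestResult:
    """Empirical DMAF p-value from uniform phenotype permutations.

    The pooled frequencies ``q_j``, counts ``n_j`` and weights ``w_j`` are
    phenotype-free and held fixed; only the group frequencies ``X_j``,
    ``Y_j`` are recomputed per relabeling.  The p-value convention is
    ``p = #{V_perm >= V_obs} / n_perm`` (ties count as extreme); with
    ``add_one=True`` the conservative ``(r + 1) / (n_perm + 1)`` estimator
    is used instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    stats = compute_variant_stats(genotypes, phenotype)
    if variant_set is None:
        idx = np.flatnonzero(stats.polymorphic)
    else:
        idx = np.asarray(variant_set)
        idx = idx[stats.polymorphic[idx]]
    if idx.size == 0:
        raise ValueError("no polymorphic variants left to test")

    w = dmaf_weights(stats, idx)
    engine = CaseControlFrequencies(genotypes, idx)
    v_obs = float(np.dot(w, _apply_flavor(engine.diff(phenotype.status), flavor)))

    rng = np.random.default_rng(seed)
    labels = permuted_case_labels(phenotype, n_perm, rng)
    v_perm = w @ _apply_flavor(engine.diff(labels), flavor)

    hits = _count_ge(v_perm, v_obs)
    if add_one:
        p = (hits + 1) / (n_perm + 1)
    else:
        p = hits / n_perm
    return TestResult(
        statistic=v_obs, p_value=p, n_perm=n_perm, variant_set=idx, flavor=flavor
    )


def skat_q_oracle(
    genotypes: GenotypeMatrix, phenotype: Phenotype, weights: np.ndarray
) -> float:
    """Score-type statistic ``Q = sum_j w_j (g_j' (y - ybar))**2``.

    Verification oracle only: with equal case/control counts and shared
    weights, the "sq" DMAF statistic is proportional to ``Q``
    (``V_sq = Q / n_case**2``), so the two yield identical permutation
    p-values.  Missing genotypes are treated as 0 copies; intended for
    complete-data fixtures.
    """
    g = np.where(genotypes.counts == MISSING, 0, genotypes.counts).astype(np.float64)
    y = phenotype.status.astype(np.float64)
    yc = y - y.mean()
    score = g.T @ yc
    return float(np.dot(np.asarray(weights, dtype=np.float64), score**2))
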