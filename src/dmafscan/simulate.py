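"""Coalescent haplotype pools and case/control phenotype models A-H.

The simulation framework mirrors a classical power-study design for
region-based rare-variant tests:

* A neutral coalescent pool of 100,000 diploid individuals is generated
  for a 50-kb region (mutation rate 1e-8 /bp/generation, effective
  population size 10,000, background recombination 1 cM/Mb, optionally a
  2-kb hotspot at 15 cM/Mb that interrupts LD across the region).
* A disease model designates some rare variants causal, each with a
  MAF-dependent odds ratio; protective effects are the reciprocals of the
  risk effects.
* Disease odds are multiplicative per causal allele copy,
  ``odds_i = c * prod_j OR_j**g_ij`` so that
  ``Pr(case | genotype) = odds_i / (1 + odds_i)`` — the standard logistic
  disease model — with the baseline ``c`` calibrated so the pool
  prevalence hits a target (10%).
* Case/control studies (200 + 200 by default) are repeatedly sampled from
  the realized pool statuses.

Models (``causal MAF`` is the pooled minor-allele frequency in the pool):

===== ============================== ==================== =============
model causal variants                directions           OR schedule
===== ============================== ==================== =============
A     random half of MAF <= 0.05     all risk             whole-region
B     random half of MAF <= 0.04     all risk             whole-region
C     random half of MAF <= 0.06     all risk             whole-region
D     all of MAF <= 0.05             half risk/half prot. whole-region
E     model A set plus one common    all risk             whole-region
      variant with MAF near 0.10
F     model D set plus one common    half/half + 1 risk   whole-region
      variant with MAF near 0.10
G     middle third (by position) of  all risk             sub-region
      MAF <= 0.05
H     same middle third              half risk/half prot. sub-region
null  none                           --                   --
===== ============================== ==================== =============

Whole-region odds ratios for risk alleles are 1.5 (MAF > 0.01), 1.7
(0.001 <= MAF <= 0.01) and 2.0 (MAF < 0.001); the sub-region schedule
uses 1.7 / 2.0 / 2.2 on the same bins.  When a split leaves an odd count,
risk gets the extra variant over protective, and earlier positional
tiers get the extra variant when dividing into thirds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import msprime
import numpy as np
from scipy.optimize import brentq

from .core import GenotypeMatrix, Phenotype

logger = logging.getLogger("dmafscan")

#: cM/Mb -> crossovers per bp per generation.
CM_PER_MB = 1e-8

#: Risk-allele odds ratios by MAF bin (MAF > 0.01, 0.001 <= MAF <= 0.01,
#: MAF < 0.001) for whole-region and sub-region (clustered-causal) models.
OR_SCHEDULES = {"whole": (1.5, 1.7, 2.0), "sub": (1.7, 2.0, 2.2)}

DEFAULT_PREVALENCE = 0.10


# ---------------------------------------------------------------------------
# Region simulation
# ---------------------------------------------------------------------------


@dataclass
class RegionParams:
    """Coalescent parameters for one simulated region.

    ``hotspot`` is an optional ``(start_bp, length_bp, rate_cM_Mb)`` triple;
    by default the 2-kb hotspot used for regions 2 and 3 sits at the region
    midpoint, where it best interrupts LD between the two halves.
    """

    length_bp: float = 50_000.0
    mu: float = 1e-8
    Ne: float = 10_000.0
    rho_background: float = 1.0  # cM/Mb
    hotspot: tuple[float, float, float] | None = None
    n_diploids: int = 100_000

    def __post_init__(self) -> None:
        if min(self.length_bp, self.Ne, self.n_diploids) <= 0:
            raise ValueError("length, Ne and pool size must be positive")
        if self.mu < 0 or self.rho_background < 0:
            raise ValueError("rates must be nonnegative")
        if self.hotspot is not None:
            start, length, rate = self.hotspot
            if not (0 <= start and start + length <= self.length_bp and rate >= 0):
                raise ValueError("hotspot interval must lie within the region")

    @classmethod
    def with_midpoint_hotspot(
        cls, hotspot_length: float = 2_000.0, hotspot_rate: float = 15.0, **kwargs
    ) -> "RegionParams":
        params = cls(**kwargs)
        start = (params.length_bp - hotspot_length) / 2.0
        params.hotspot = (start, hotspot_length, hotspot_rate)
        return params


@dataclass
class RegionPool:
    """Simulated haplotype population for one region.

    ``haplotypes`` is a ``(2 * n_diploids, J)`` 0/1 matrix with allele 1
    the pool-minor allele; consecutive haplotype pairs form diploids.
    Positions are base-pair coordinates (continuous, infinite-sites) and
    ``maf`` the pooled minor-allele frequency of each column.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    maf: np.ndarray
    length_bp: float

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.positions) != len(self.maf):
            raise ValueError("positions/maf must align with haplotype columns")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_diploids(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @cached_property
    def genotypes(self) -> np.ndarray:
        """Diploid minor-allele counts, ``(n_diploids, J)`` int8."""
        if self.n_haplotypes % 2:
            raise ValueError("odd haplotype count: cannot pair into diploids")
        h = self.haplotypes
        return (h[0::2] + h[1::2]).astype(np.int8)


def simulate_region(params: RegionParams, seed: int | None = None) -> RegionPool:
    """Neutral coalescent haplotypes for one region via msprime.

    Uses a continuous (infinite-sites) genome with binary mutations, so
    every site is biallelic with a unique position, matching classical
    ms-style output.  Columns are oriented so allele 1 is the pool-minor
    allele.  Deterministic for a given seed.
    """
    ss = np.random.SeedSequence(seed)
    s_anc, s_mut = (int(c.generate_state(1)[0] % (2**31 - 2)) + 1 for c in ss.spawn(2))

    if params.hotspot is None:
        recomb = params.rho_background * CM_PER_MB
    else:
        start, length, rate = params.hotspot
        edges = [0.0, start, start + length, params.length_bp]
        rates = [params.rho_background * CM_PER_MB, rate * CM_PER_MB,
                 params.rho_background * CM_PER_MB]
        # collapse zero-length flanks (hotspot at region edge)
        pos, rr = [0.0], []
        for lo, hi, r in zip(edges[:-1], edges[1:], rates):
            if hi > lo:
                pos.append(hi)
                rr.append(r)
        recomb = msprime.RateMap(position=pos, rate=rr)

    ts = msprime.sim_ancestry(
        samples=params.n_diploids,
        sequence_length=params.length_bp,
        recombination_rate=recomb,
        population_size=params.Ne,
        random_seed=s_anc,
        discrete_genome=False,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=msprime.BinaryMutationModel(),
        random_seed=s_mut,
        discrete_genome=False,
    )
    if mts.num_sites == 0:
        return RegionPool(
            haplotypes=np.empty((2 * params.n_diploids, 0), dtype=np.int8),
            positions=np.empty(0),
            maf=np.empty(0),
            length_bp=params.length_bp,
        )
    H = mts.genotype_matrix().T.astype(np.int8)  # (2N, J)
    positions = np.array([site.position for site in mts.sites()])
    freq = H.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    H, positions, freq = H[:, poly], positions[poly], freq[poly]
    flip = freq > 0.5
    H[:, flip] = 1 - H[:, flip]
    maf = np.where(flip, 1.0 - freq, freq)
    logger.info("simulated region: %d polymorphic variants over %.0f bp",
                H.shape[1], params.length_bp)
    return RegionPool(haplotypes=H, positions=positions, maf=maf,
                      length_bp=params.length_bp)


# ---------------------------------------------------------------------------
# Disease models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimModel:
    """One of the phenotype-generation models A-H (or the null model)."""

    name: str
    causal_maf_threshold: float = 0.05
    causal_fraction: float = 0.5  # fraction of eligible rare variants causal
    protective_fraction: float = 0.0  # fraction of causal variants protective
    or_schedule: str = "whole"
    sub_region: bool = False
    extra_common_variant: bool = False  # one extra risk variant at MAF ~ 0.10
    prevalence: float = DEFAULT_PREVALENCE

    _TABLE = {
        "A": dict(causal_maf_threshold=0.05, causal_fraction=0.5),
        "B": dict(causal_maf_threshold=0.04, causal_fraction=0.5),
        "C": dict(causal_maf_threshold=0.06, causal_fraction=0.5),
        "D": dict(causal_maf_threshold=0.05, causal_fraction=1.0,
                  protective_fraction=0.5),
        "E": dict(causal_maf_threshold=0.05, causal_fraction=0.5,
                  extra_common_variant=True),
        "F": dict(causal_maf_threshold=0.05, causal_fraction=1.0,
                  protective_fraction=0.5, extra_common_variant=True),
        "G": dict(causal_maf_threshold=0.05, sub_region=True, or_schedule="sub"),
        "H": dict(causal_maf_threshold=0.05, sub_region=True, or_schedule="sub",
                  protective_fraction=0.5),
        "null": dict(causal_fraction=0.0),
    }

    @classmethod
    def from_name(cls, name: str, prevalence: float = DEFAULT_PREVALENCE) -> "SimModel":
        key = name if name == "null" else name.upper()
        if key not in cls._TABLE:
            raise ValueError(f"unknown model {name!r}; expected A-H or 'null'")
        return cls(name=key, prevalence=prevalence, **cls._TABLE[key])

    @classmethod
    def names(cls) -> list[str]:
        return list(cls._TABLE)


@dataclass
class CausalAnnotation:
    """Per-variant causal direction and odds ratio for one pool + model.

    ``direction`` is +1 (risk), -1 (protective) or 0 (neutral);
    ``odds_ratio`` is > 1 for risk, the exact reciprocal for protective at
    the same MAF bin, and 1 for neutral variants.
    """

    direction: np.ndarray
    odds_ratio: np.ndarray

    def __post_init__(self) -> None:
        risk, prot = self.direction > 0, self.direction < 0
        ok = (
            np.all(self.odds_ratio[risk] > 1)
            and np.all(self.odds_ratio[prot] < 1)
            and np.all(self.odds_ratio[self.direction == 0] == 1)
        )
        if not ok:
            raise ValueError("odds ratios inconsistent with causal directions")

    @property
    def causal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.direction != 0)

    @property
    def n_risk(self) -> int:
        return int(np.count_nonzero(self.direction > 0))

    @property
    def n_protective(self) -> int:
        return int(np.count_nonzero(self.direction < 0))


def or_for_variant(maf, direction, schedule: str = "whole"):
    """Odds ratio(s) from the MAF bin, direction and schedule (vectorized).

    Risk ORs by bin: MAF > 0.01 / 0.001 <= MAF <= 0.01 / MAF < 0.001 map to
    (1.5, 1.7, 2.0) for the whole-region schedule and (1.7, 2.0, 2.2) for
    the sub-region schedule.  Protective ORs are the exact reciprocals;
    neutral variants get OR = 1.
    """
    if schedule not in OR_SCHEDULES:
        raise ValueError(f"schedule must be 'whole' or 'sub', got {schedule!r}")
    common, low, rare = OR_SCHEDULES[schedule]
    maf = np.asarray(maf, dtype=np.float64)
    dirn = np.asarray(direction)
    if isinstance(direction, str):
        dirn = np.array({"risk": 1, "protective": -1, "neutral": 0}[direction])
    base = np.where(maf > 0.01, common, np.where(maf >= 0.001, low, rare))
    out = np.where(dirn > 0, base, np.where(dirn < 0, 1.0 / base, 1.0))
    return float(out) if out.ndim == 0 else out


def _split_extra_to_first(total: int, parts: int) -> list[int]:
    """Partition ``total`` into ``parts`` near-equal tiers, extras first."""
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def assign_causal(
    pool: RegionPool, model: SimModel, seed: int | None = None
) -> CausalAnnotation:
    """Designate causal variants and their odds ratios under ``model``.

    Whole-region models (A-F) draw the causal set uniformly at random from
    the eligible rare variants (all of them for D and F); sub-region
    models (G, H) take the positional middle third of the rare variants.
    Risk/protective splits are random halves with risk receiving the extra
    variant on odd counts.  Models E and F additionally make one common
    variant causal: the variant with pooled MAF closest to 0.10 becomes a
    risk variant.  All other common variants are neutral.
    """
    rng = np.random.default_rng(seed)
    direction = np.zeros(pool.n_variants, dtype=np.int8)
    odds = np.ones(pool.n_variants, dtype=np.float64)
    if model.causal_fraction == 0.0 and not model.sub_region:
        return CausalAnnotation(direction=direction, odds_ratio=odds)

    rare = np.flatnonzero(pool.maf <= model.causal_maf_threshold)
    if rare.size < 3:
        raise ValueError(
            f"only {rare.size} rare variants under MAF <= "
            f"{model.causal_maf_threshold}; need at least 3"
        )
    if model.sub_region:
        # positions are sorted, so rank in `rare` is positional rank
        tiers = _split_extra_to_first(rare.size, 3)
        causal = rare[tiers[0] : tiers[0] + tiers[1]]
    else:
        n_causal = (
            rare.size
            if model.causal_fraction == 1.0
            else int(np.ceil(rare.size * model.causal_fraction))
        )
        causal = rng.choice(rare, size=n_causal, replace=False)

    n_risk = int(np.ceil(causal.size * (1.0 - model.protective_fraction)))
    shuffled = rng.permutation(causal)
    direction[shuffled[:n_risk]] = 1
    direction[shuffled[n_risk:]] = -1

    if model.extra_common_variant:
        common = np.flatnonzero(pool.maf > model.causal_maf_threshold)
        if common.size == 0:
            raise ValueError("no common variant available for the MAF~0.10 effect")
        extra = common[np.argmin(np.abs(pool.maf[common] - 0.10))]
        if not 0.05 < pool.maf[extra] <= 0.20:
            logger.warning(
                "extra common causal variant has MAF %.3f (target 0.10)",
                pool.maf[extra],
            )
        direction[extra] = 1

    cz = direction != 0
    odds[cz] = or_for_variant(pool.maf[cz], direction[cz], model.or_schedule)
    return CausalAnnotation(direction=direction, odds_ratio=odds)


# ---------------------------------------------------------------------------
# Risk calibration and study sampling
# ---------------------------------------------------------------------------


def _odds_scores(pool: RegionPool, annotation: CausalAnnotation) -> np.ndarray:
    """Per-individual multiplicative odds score ``prod_j OR_j ** g_ij``."""
    causal = annotation.causal_indices
    if causal.size == 0:
        return np.ones(pool.n_diploids)
    g = pool.genotypes[:, causal].astype(np.float32)
    return np.exp(g @ np.log(annotation.odds_ratio[causal]).astype(np.float32)).astype(
        np.float64
    )


def calibrate_baseline(
    pool: RegionPool,
    annotation: CausalAnnotation,
    prevalence: float = DEFAULT_PREVALENCE,
    tol: float = 1e-6,
) -> float:
    """Baseline odds ``c`` so the pool prevalence equals the target.

    Disease risk follows the standard logistic model: each causal allele
    copy multiplies the disease odds by its odds ratio, so
    ``Pr(case) = c * score / (1 + c * score)``.  The pool-mean probability
    is continuous and strictly increasing in ``c``, and the root is found
    by bracketed bisection (Brent).  With no causal variants every subject
    has probability exactly ``prevalence`` (baseline odds
    ``prevalence / (1 - prevalence)``).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    s = _odds_scores(pool, annotation)
    if np.all(s == 1.0):
        return prevalence / (1.0 - prevalence)

    def excess(c: float) -> float:
        cs = c * s
        return float((cs / (1.0 + cs)).mean() - prevalence)

    hi = 1.0
    while excess(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("target prevalence unreachable")
    c = brentq(excess, 0.0, hi, xtol=1e-14, rtol=1e-15)
    if abs(excess(c)) > tol:
        raise ValueError("prevalence calibration did not converge")
    return float(c)


def case_probabilities(
    pool: RegionPool, annotation: CausalAnnotation, c: float
) -> np.ndarray:
    """Per-individual case probability ``c * score / (1 + c * score)``."""
    cs = c * _odds_scores(pool, annotation)
    return cs / (1.0 + cs)


def sample_case_control(
    pool: RegionPool,
    annotation: CausalAnnotation,
    c: float,
    n_case: int = 200,
    n_ctrl: int = 200,
    seed: int | None = None,
    probabilities: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, Phenotype]:
    """Draw one case/control study from the pool.

    Each pool individual's status is Bernoulli in its case probability;
    the requested numbers of cases and controls are then sampled uniformly
    without replacement from the realized groups.  All pool variants are
    retained in the returned matrix (those monomorphic within the sample
    are flagged and dropped by the test itself).  ``probabilities`` may be
    passed to reuse a precomputed :func:`case_probabilities` vector across
    replicates.
    """
    rng = np.random.default_rng(seed)
    p = case_probabilities(pool, annotation, c) if probabilities is None else probabilities
    status = rng.random(pool.n_diploids) < p
    cases = np.flatnonzero(status)
    ctrls = np.flatnonzero(~status)
    if cases.size < n_case or ctrls.size < n_ctrl:
        raise ValueError(
            f"pool realized {cases.size} cases / {ctrls.size} controls; "
            f"cannot sample {n_case} + {n_ctrl}"
        )
    rows = np.concatenate(
        [rng.choice(cases, n_case, replace=False), rng.choice(ctrls, n_ctrl, replace=False)]
    )
    gm = GenotypeMatrix(
        counts=pool.genotypes[rows].astype(np.int16),
        sample_ids=[f"ind{r}" for r in rows],
        variant_ids=[f"v{j + 1}" for j in range(pool.n_variants)],
        positions=np.floor(pool.positions).astype(np.int64) + 1,
    )
    phen = Phenotype(
        status=np.concatenate([np.ones(n_case, dtype=np.int8), np.zeros(n_ctrl, dtype=np.int8)])
    )
    return gm, phen


def causal_index_range(
    analysis_columns: np.ndarray, annotation: CausalAnnotation
) -> tuple[int, int]:
    """Causal sub-region as a half-open interval in analysis-index space.

    ``analysis_columns`` are the pool/matrix column indices forming the
    analysis set of a scan (in genomic order).  The causal sub-region
    spans from the first to the last causal column; the returned interval
    covers every analysis variant lying within that span, which is the
    coordinate system window localization operates in.
    """
    causal = annotation.causal_indices
    if causal.size == 0:
        return (0, 0)
    cols = np.asarray(analysis_columns)
    lo = int(np.searchsorted(cols, causal.min(), side="left"))
    hi = int(np.searchsorted(cols, causal.max(), side="right"))
    return (lo, hi)


# ---------------------------------------------------------------------------
# Trait-variance summary
# ---------------------------------------------------------------------------


def nagelkerke_r2(genotypes: np.ndarray, status: np.ndarray) -> float:
    """Nagelkerke pseudo-R-squared of a causal-variant set.

    Compares an intercept-only logistic model with one using the given
    genotype columns as predictors:

        R2 = (1 - (L0 / L1) ** (2 / N)) / (1 - L0 ** (2 / N)).

    Under (quasi-)complete separation the ML fit diverges; the value is
    then capped at 1 with a warning.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    g = np.asarray(genotypes, dtype=np.float64)
    if g.ndim != 2 or g.shape[1] == 0:
        raise ValueError("need a 2-D genotype array with at least one causal variant")
    y = np.asarray(status, dtype=np.float64)
    n = len(y)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("phenotype is constant; R2 undefined")

    ll0 = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000).fit(g, y)
    p = np.clip(clf.predict_proba(g)[:, 1], 1e-12, 1 - 1e-12)
    ll1 = float(y @ np.log(p) + (1 - y) @ np.log1p(-p))
    r2 = (1.0 - np.exp(2.0 * (ll0 - ll1) / n)) / (1.0 - np.exp(2.0 * ll0 / n))
    if r2 > 1.0:
        warnings.warn("separation in logistic fit; Nagelkerke R2 capped at 1")
    return float(min(r2, 1.0))
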