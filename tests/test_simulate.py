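"""Tests for the coalescent pool and disease-model simulation framework."""

import numpy as np
import pytest
from scipy.optimize import brentq

from dmafscan import (
    CausalAnnotation,
    Phenotype,
    RegionParams,
    RegionPool,
    SimModel,
    assign_causal,
    calibrate_baseline,
    case_probabilities,
    causal_index_range,
    nagelkerke_r2,
    or_for_variant,
    permutation_pvalue,
    sample_case_control,
    simulate_region,
)


# ---------------------------------------------------------------------------
# Odds-ratio schedules
# ---------------------------------------------------------------------------


def test_or_schedule_bins():
    assert or_for_variant(0.02, "risk", "whole") == 1.5
    assert or_for_variant(0.005, "risk", "whole") == 1.7
    assert or_for_variant(0.0005, "risk", "whole") == 2.0
    assert or_for_variant(0.0005, "risk", "sub") == 2.2
    assert or_for_variant(0.005, "protective", "whole") == pytest.approx(1 / 1.7)
    assert or_for_variant(0.3, "neutral", "whole") == 1.0
    # bin boundaries are inclusive for the middle tier
    assert or_for_variant(0.01, "risk", "whole") == 1.7
    assert or_for_variant(0.001, "risk", "sub") == 2.0
    with pytest.raises(ValueError):
        or_for_variant(0.02, "risk", "bogus")


def test_model_table_consistency():
    for name in ("D", "F", "H"):
        assert SimModel.from_name(name).protective_fraction == 0.5
    for name in ("G", "H"):
        m = SimModel.from_name(name)
        assert m.sub_region and m.or_schedule == "sub"
    assert SimModel.from_name("B").causal_maf_threshold == 0.04
    assert SimModel.from_name("C").causal_maf_threshold == 0.06
    assert SimModel.from_name("E").extra_common_variant
    assert SimModel.from_name("null").causal_fraction == 0.0
    with pytest.raises(ValueError):
        SimModel.from_name("Z")


# ---------------------------------------------------------------------------
# Causal assignment
# ---------------------------------------------------------------------------


def _fabricated_pool(n_rare=200, n_common=60):
    """Pool with a known MAF layout: rare and common variants interleaved,
    one common variant at exactly MAF 0.10."""
    rng = np.random.default_rng(0)
    j = n_rare + n_common
    maf = np.empty(j)
    kinds = np.array([True] * n_rare + [False] * n_common)
    rng.shuffle(kinds)
    maf[kinds] = rng.uniform(0.001, 0.05, n_rare)
    maf[~kinds] = rng.uniform(0.12, 0.45, n_common)
    maf[np.flatnonzero(~kinds)[0]] = 0.10
    return RegionPool(
        haplotypes=np.zeros((2, j), dtype=np.int8),
        positions=np.arange(j, dtype=float),
        maf=maf,
        length_bp=float(j),
    ), kinds


@pytest.mark.parametrize(
    "model,n_risk,n_prot",
    [("A", 100, 0), ("D", 100, 100), ("E", 101, 0), ("F", 101, 100),
     ("G", 67, 0), ("H", 34, 33)],
)
def test_assign_causal_counts(model, n_risk, n_prot):
    """With 200 rare variants the printed per-model causal counts hold
    exactly: A=100 risk, D=100/100, E/F add one common variant, G takes the
    middle third (67), H splits it 34/33."""
    pool, _ = _fabricated_pool()
    ann = assign_causal(pool, SimModel.from_name(model), seed=5)
    assert ann.n_risk == n_risk
    assert ann.n_protective == n_prot


def test_sub_region_models_take_positional_middle_third():
    pool, kinds = _fabricated_pool()
    ann = assign_causal(pool, SimModel.from_name("G"), seed=5)
    rare = np.flatnonzero(kinds)
    causal = ann.causal_indices
    np.testing.assert_array_equal(causal, rare[67:134])
    assert np.all(ann.direction[causal] == 1)
    # common variants always neutral
    assert np.all(ann.direction[~kinds] == 0)


def test_extra_common_variant_is_the_maf_010_one():
    pool, kinds = _fabricated_pool()
    annA = assign_causal(pool, SimModel.from_name("A"), seed=5)
    annE = assign_causal(pool, SimModel.from_name("E"), seed=5)
    added = np.flatnonzero((annE.direction == 1) & (annA.direction != 1))
    assert added.size == 1
    assert pool.maf[added[0]] == 0.10
    assert annE.odds_ratio[added[0]] == 1.5  # MAF > 0.01 bin


def test_protective_ors_are_reciprocal():
    pool, _ = _fabricated_pool()
    ann = assign_causal(pool, SimModel.from_name("D"), seed=9)
    prot = np.flatnonzero(ann.direction == -1)
    risk_or = or_for_variant(pool.maf[prot], np.ones(prot.size), "whole")
    np.testing.assert_allclose(ann.odds_ratio[prot], 1.0 / risk_or)


def test_assign_causal_too_few_rare():
    pool = RegionPool(
        haplotypes=np.zeros((2, 4), dtype=np.int8),
        positions=np.arange(4, dtype=float),
        maf=np.array([0.2, 0.3, 0.01, 0.4]),
        length_bp=4.0,
    )
    with pytest.raises(ValueError, match="rare"):
        assign_causal(pool, SimModel.from_name("A"), seed=1)


# ---------------------------------------------------------------------------
# Baseline calibration and sampling
# ---------------------------------------------------------------------------


def test_calibrate_no_causal_closed_form():
    pool, _ = _fabricated_pool()
    ann = assign_causal(pool, SimModel.from_name("null"), seed=1)
    c = calibrate_baseline(pool, ann, prevalence=0.10)
    assert c == pytest.approx(0.10 / 0.90)
    np.testing.assert_allclose(case_probabilities(pool, ann, c), 0.10)


def test_calibrate_hand_enumeration():
    """10-individual toy pool, one risk variant (OR = 2) carried once by 3
    individuals: c must solve (7 c/(1+c) + 3*2c/(1+2c))/10 = 0.1, solved
    here from that explicit 10-term expression."""
    hap = np.zeros((20, 1), dtype=np.int8)
    hap[[0, 2, 4], 0] = 1  # individuals 0,1,2 carry one copy
    pool = RegionPool(haplotypes=hap, positions=np.array([1.0]),
                      maf=np.array([0.15]), length_bp=100.0)
    ann = CausalAnnotation(direction=np.array([1], dtype=np.int8),
                           odds_ratio=np.array([2.0]))
    expected = brentq(
        lambda c: (7 * c / (1 + c) + 3 * 2 * c / (1 + 2 * c)) / 10 - 0.1,
        1e-9, 10,
    )
    assert calibrate_baseline(pool, ann, 0.10) == pytest.approx(expected, rel=1e-9)


def test_calibration_hits_prevalence(small_pool):
    ann = assign_causal(small_pool, SimModel.from_name("A"), seed=3)
    c = calibrate_baseline(small_pool, ann, 0.10)
    probs = case_probabilities(small_pool, ann, c)
    assert probs.mean() == pytest.approx(0.10, abs=1e-6)
    # realized pool case fraction within 3 binomial SEs of target
    status = np.random.default_rng(4).random(small_pool.n_diploids) < probs
    se = np.sqrt(0.1 * 0.9 / small_pool.n_diploids)
    assert abs(status.mean() - 0.10) < 3 * se


def test_sample_case_control_basics(small_pool):
    ann = assign_causal(small_pool, SimModel.from_name("null"), seed=1)
    c = calibrate_baseline(small_pool, ann, 0.10)
    gm, phen = sample_case_control(small_pool, ann, c, 30, 30, seed=8)
    assert gm.n_subjects == 60 and phen.n_cases == 30
    assert gm.n_variants == small_pool.n_variants
    gm2, phen2 = sample_case_control(small_pool, ann, c, 30, 30, seed=8)
    np.testing.assert_array_equal(gm.counts, gm2.counts)
    assert gm.sample_ids == gm2.sample_ids
    with pytest.raises(ValueError, match="cannot sample"):
        sample_case_control(small_pool, ann, c, small_pool.n_diploids, 10, seed=8)


def test_null_model_gives_uniform_pvalues(small_pool):
    """With all ORs = 1, cases and controls are exchangeable and the DMAF
    p-value is calibrated."""
    ann = assign_causal(small_pool, SimModel.from_name("null"), seed=1)
    probs = case_probabilities(small_pool, ann, calibrate_baseline(small_pool, ann))
    hits, n_rep = 0, 200
    for rep in range(n_rep):
        gm, phen = sample_case_control(small_pool, ann, 1/9, 30, 30, seed=rep,
                                       probabilities=probs)
        hits += permutation_pvalue(gm, phen, n_perm=200, seed=rep).p_value < 0.05
    assert 0.01 <= hits / n_rep <= 0.10


def test_power_monotone_in_effect_size(small_pool):
    """Doubling every causal log-OR cannot decrease power."""
    ann = assign_causal(small_pool, SimModel.from_name("A"), seed=3)
    doubled = CausalAnnotation(
        direction=ann.direction.copy(),
        odds_ratio=np.exp(2 * np.log(ann.odds_ratio)),
    )
    powers = []
    for a in (ann, doubled):
        c = calibrate_baseline(small_pool, a, 0.10)
        probs = case_probabilities(small_pool, a, c)
        hits, n_rep = 0, 200
        for rep in range(n_rep):
            gm, phen = sample_case_control(small_pool, a, c, 30, 30, seed=rep,
                                           probabilities=probs)
            hits += permutation_pvalue(gm, phen, n_perm=150, seed=rep).p_value < 0.05
        powers.append(hits / n_rep)
    se = np.sqrt(powers[0] * (1 - powers[0]) / 200 + 0.25 / 200)
    assert powers[1] >= powers[0] - 2 * se


def test_causal_index_range_mapping():
    ann = CausalAnnotation(
        direction=np.array([0, 0, 1, 0, 1, 0, 0], dtype=np.int8),
        odds_ratio=np.array([1, 1, 2.0, 1, 2.0, 1, 1]),
    )
    # analysis keeps columns 0,2,3,5,6 -> causal span cols [2,4] -> idx [1,3)
    assert causal_index_range(np.array([0, 2, 3, 5, 6]), ann) == (1, 3)
    null_ann = CausalAnnotation(
        direction=np.zeros(7, dtype=np.int8), odds_ratio=np.ones(7)
    )
    assert causal_index_range(np.array([0, 1]), null_ann) == (0, 0)


# ---------------------------------------------------------------------------
# Coalescent region simulation
# ---------------------------------------------------------------------------


def test_zero_mutation_rate_gives_empty_pool():
    pool = simulate_region(
        RegionParams(length_bp=10_000, mu=0.0, n_diploids=20), seed=1
    )
    assert pool.n_variants == 0


def test_pool_seed_determinism():
    params = RegionParams(length_bp=10_000, n_diploids=50)
    a = simulate_region(params, seed=77)
    b = simulate_region(params, seed=77)
    np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
    np.testing.assert_array_equal(a.positions, b.positions)
    assert np.all((a.maf > 0) & (a.maf <= 0.5))
    assert np.all(np.diff(a.positions) >= 0)


def test_variant_count_tracks_watterson_and_length():
    """Mean segregating-site count over replicates matches the Watterson
    expectation theta * a_{n-1}, and doubles when the region doubles."""
    n_hap = 200
    a_n = np.sum(1.0 / np.arange(1, n_hap))
    counts = {}
    for L in (10_000, 20_000):
        theta = 4 * 10_000 * 1e-8 * L
        expect = theta * a_n
        cs = [
            simulate_region(
                RegionParams(length_bp=L, n_diploids=n_hap // 2), seed=1000 + L + r
            ).n_variants
            for r in range(20)
        ]
        counts[L] = np.mean(cs)
        sd_mean = np.sqrt((expect + theta**2 * 1.64) / 20)
        assert abs(counts[L] - expect) < 3.5 * sd_mean
    assert 1.6 < counts[20_000] / counts[10_000] < 2.4


def test_hotspot_params_validated():
    with pytest.raises(ValueError, match="hotspot"):
        RegionParams(length_bp=10_000, hotspot=(9_500, 2_000, 15.0))
    p = RegionParams.with_midpoint_hotspot(length_bp=50_000)
    assert p.hotspot == (24_000.0, 2_000.0, 15.0)
    pool = simulate_region(
        RegionParams.with_midpoint_hotspot(length_bp=10_000, n_diploids=30), seed=5
    )
    assert pool.n_variants > 0


# ---------------------------------------------------------------------------
# Nagelkerke R2
# ---------------------------------------------------------------------------


def test_nagelkerke_null_and_perfect():
    rng = np.random.default_rng(6)
    g = rng.binomial(2, 0.2, size=(2000, 5))
    y = rng.binomial(1, 0.3, 2000)
    assert nagelkerke_r2(g, y) < 0.02  # permutation-independent predictors
    y2 = rng.binomial(1, 0.5, 400)
    assert nagelkerke_r2(y2[:, None].astype(float), y2) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ValueError, match="constant"):
        nagelkerke_r2(g[:400], np.ones(400))
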