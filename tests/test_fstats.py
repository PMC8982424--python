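"""f-statistics, FST estimators, block jackknife and ascertainment."""

import itertools

import numpy as np
import pytest

import iopopgen as io
from iopopgen import synthetic_data as sd
from iopopgen.fstats import (BlockPartition, FStatEstimate, PopFrequencies,
                             block_jackknife)
from iopopgen.genotype_io import MISSING, GenotypePanel


def _two_block_partition(n_markers, markers=None):
    block = np.repeat([0, 1], n_markers // 2)
    return BlockPartition(block, 2, n_markers // 2)


def _freqs(p, a, markers=None):
    p = np.asarray(p, float)
    return PopFrequencies([f"P{i}" for i in range(p.shape[0])], p,
                          np.full_like(p, a), markers)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def test_compute_frequencies_matches_recount_oracle(toy_panel):
    f = io.compute_frequencies(toy_panel)
    g = toy_panel.genotypes
    for k, pop in enumerate(f.populations):
        idx = toy_panel.pop_index(pop)
        for m in range(toy_panel.n_markers):
            col = g[idx, m]
            col = col[col != MISSING]
            if col.size == 0:
                assert f.a[k, m] == 0
            else:
                assert f.a[k, m] == 2 * col.size
                assert f.p[k, m] == pytest.approx(col.sum() / (2 * col.size))


def test_frequencies_basic_and_all_missing(small_map):
    g = np.array([[0, MISSING], [1, MISSING], [2, MISSING]], dtype=np.int8)
    panel = GenotypePanel(small_map.subset(np.arange(2)), ["a", "b", "c"],
                          ["P"] * 3, g)
    f = io.compute_frequencies(panel)
    assert f.p[0, 0] == pytest.approx(0.5)
    assert f.a[0, 0] == 6
    assert f.a[0, 1] == 0 and np.isnan(f.p[0, 1])


# ---------------------------------------------------------------------------
# block jackknife
# ---------------------------------------------------------------------------

def test_jackknife_identical_blocks_zero_se():
    part = _two_block_partition(20)
    num = np.full(20, 0.3)
    den = np.ones(20)
    est, se, B = block_jackknife(num, den, part)
    assert est == pytest.approx(0.3)
    assert se == pytest.approx(0.0, abs=1e-12)
    assert B == 2


def test_jackknife_matches_naive_leave_one_out():
    """Equal-size blocks reduce to the classical delete-one jackknife."""
    rng = np.random.default_rng(3)
    num = rng.normal(0.1, 0.05, 40)
    den = np.ones(40)
    block = np.repeat(np.arange(4), 10)
    part = BlockPartition(block, 4, 10)
    est, se, B = block_jackknife(num, den, part)
    theta = num.mean()
    theta_del = np.array([num[block != b].mean() for b in range(4)])
    se_naive = np.sqrt((4 - 1) / 4 * np.sum((theta_del - theta_del.mean()) ** 2))
    assert est == pytest.approx(theta)
    assert se == pytest.approx(se_naive, rel=1e-9)


def test_jackknife_needs_two_blocks():
    part = BlockPartition(np.zeros(10, dtype=int), 1, 10)
    with pytest.raises(ValueError):
        block_jackknife(np.ones(10), np.ones(10), part)


def test_block_partition_respects_chromosomes():
    markers = sd.make_map(100, n_chromosomes=4, total_cM=400)
    part = BlockPartition.from_map(markers, 10)
    for b in range(part.n_blocks):
        chroms = markers.chromosome[part.block == b]
        assert len(set(chroms)) == 1
        assert len(chroms) == 10
    # 25 per chromosome -> 2 blocks of 10 each, 5 markers unassigned
    assert part.n_blocks == 8
    assert (part.block == -1).sum() == 20


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def test_heterozygosity_closed_form():
    p = np.full((1, 20), 0.5)
    est = io.heterozygosity(_freqs(p, 100), "P0", _two_block_partition(20))
    assert est.estimate == pytest.approx(2 * 0.25 * 100 / 99)


def test_heterozygosity_monomorphic_zero():
    p = np.zeros((1, 20))
    est = io.heterozygosity(_freqs(p, 40), "P0", _two_block_partition(20))
    assert est.estimate == 0.0


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

def _wc_oracle(p, a):
    """Independent per-locus Weir–Cockerham components, scalar loops."""
    n_pop, n_mrk = p.shape
    num = np.empty(n_mrk)
    den = np.empty(n_mrk)
    for m in range(n_mrk):
        ns = [a[k, m] for k in range(n_pop)]
        ps = [p[k, m] for k in range(n_pop)]
        r = len(ns)
        N = sum(ns)
        pbar = sum(n * x for n, x in zip(ns, ps)) / N
        nc = (N - sum(n * n for n in ns) / N) / (r - 1)
        msp = sum(n * (x - pbar) ** 2 for n, x in zip(ns, ps)) / (r - 1)
        msg = sum(n * x * (1 - x) for n, x in zip(ns, ps)) / (N - r)
        num[m] = msp - msg
        den[m] = msp + (nc - 1) * msg
    return num.sum() / den.sum()


def test_fst_anova_matches_component_oracle():
    rng = np.random.default_rng(11)
    p = rng.uniform(0.1, 0.9, size=(3, 5))
    a = rng.choice([20, 30, 40], size=(3, 5)).astype(float)
    freqs = PopFrequencies(["P0", "P1", "P2"], p, a)
    part = BlockPartition(np.array([0, 0, 0, 1, 1]), 2, 2)
    est = io.fst_anova(freqs, ["P0", "P1", "P2"], part)
    assert est.estimate == pytest.approx(_wc_oracle(p, a), abs=1e-12)


def test_fst_fixed_difference_is_one():
    p = np.vstack([np.zeros(20), np.ones(20)])
    est = io.fst_anova(_freqs(p, 40), ["P0", "P1"],
                       _two_block_partition(20))
    assert est.estimate == pytest.approx(1.0)


def test_fst_duplicated_population_near_zero():
    rng = np.random.default_rng(7)
    markers = sd.make_map(400, n_chromosomes=2, total_cM=200)
    g_half = rng.binomial(2, rng.uniform(0.2, 0.8, 400),
                          size=(15, 400)).astype(np.int8)
    g = np.vstack([g_half, g_half])
    panel = GenotypePanel(markers, [f"i{k}" for k in range(30)],
                          ["P1"] * 15 + ["P2"] * 15, g)
    f = io.compute_frequencies(panel)
    part = BlockPartition.from_map(markers, 100)
    est = io.fst_anova(f, ["P1", "P2"], part)
    assert est.estimate <= 0.0 + 3 * max(est.jackknife_se, 1e-6)


def test_fst_needs_two_populations():
    with pytest.raises(ValueError):
        io.fst_anova(_freqs(np.full((1, 10), 0.5), 20), ["P0"],
                     _two_block_partition(10))


# ---------------------------------------------------------------------------
# population-specific FST
# ---------------------------------------------------------------------------

def test_popspecific_identical_freqs_near_zero():
    p = np.full((3, 40), 0.5)
    out = io.fst_popspecific(_freqs(p, 10000), _two_block_partition(40))
    for est in out.values():
        assert abs(est.estimate) < 1e-3


def test_popspecific_fixed_population_stands_out():
    p = np.vstack([np.ones(40), np.full(40, 0.5), np.full(40, 0.5)])
    out = io.fst_popspecific(_freqs(p, 1000), _two_block_partition(40))
    assert out["P0"].estimate > out["P1"].estimate
    assert out["P0"].estimate > out["P2"].estimate


# ---------------------------------------------------------------------------
# f2 / f3 / f4
# ---------------------------------------------------------------------------

def test_f3_with_duplicate_source_is_f2_minus_correction():
    """f3(A;B,B) = f2(A,B) + B's own correction term (algebraic identity)."""
    rng = np.random.default_rng(2)
    p = rng.uniform(0.2, 0.8, size=(2, 30))
    a = np.full((2, 30), 50.0)
    freqs = PopFrequencies(["A", "B"], p, a)
    part = _two_block_partition(30)
    f2 = io.f_statistics(freqs, [("A", "B")], part)[0]
    f3 = io.f_statistics(freqs, [("A", "B", "B")], part)[0]
    corr_b = np.mean(p[1] * (1 - p[1]) / (a[1] - 1))
    assert f3.estimate == pytest.approx(f2.estimate + corr_b, abs=1e-12)


def test_f4_identities(graph_panel, graph_partition):
    _, panel, _ = graph_panel
    f = io.compute_frequencies(panel)
    part = graph_partition
    zero = io.f_statistics(f, [("A", "B", "M", "M")], part)[0]
    assert zero.estimate == 0.0
    ab = io.f_statistics(f, [("A", "B", "M", "OUT")], part)[0]
    ba = io.f_statistics(f, [("B", "A", "M", "OUT")], part)[0]
    assert ab.estimate == pytest.approx(-ba.estimate, abs=1e-15)
    assert ab.jackknife_se == pytest.approx(ba.jackknife_se, rel=1e-9)


def test_f3_negative_at_admixed_leaf(graph_panel, graph_partition):
    """The admixture-constructed leaf must show a negative f3 signal."""
    f = io.compute_frequencies(graph_panel[1])
    est = io.f_statistics(f, [("M", "A", "B")], graph_partition)[0]
    assert est.estimate < 0
    assert est.zscore < -2.33


def test_allele_relabel_invariance(toy_panel):
    """Flipping the counted allele at every marker leaves f2, FST and f4
    unchanged (both factors of each product negate)."""
    part = _two_block_partition(toy_panel.n_markers)
    f = io.compute_frequencies(toy_panel)
    flipped = PopFrequencies(f.populations, 1.0 - f.p, f.a, f.markers)
    f2a = io.f_statistics(f, [("P1", "P2")], part)[0]
    f2b = io.f_statistics(flipped, [("P1", "P2")], part)[0]
    assert f2a.estimate == pytest.approx(f2b.estimate, abs=1e-15)
    fsta = io.fst_anova(f, ["P1", "P2", "P3"], part)
    fstb = io.fst_anova(flipped, ["P1", "P2", "P3"], part)
    assert fsta.estimate == pytest.approx(fstb.estimate, abs=1e-12)
    req = [("P1", "P2", "P3", "P1")]
    assert io.f_statistics(f, req, part)[0].estimate == pytest.approx(
        io.f_statistics(flipped, req, part)[0].estimate, abs=1e-15)


def test_marker_order_invariance(toy_panel):
    """Ratio-of-sums averaging is invariant to permuting markers in a block."""
    part = _two_block_partition(toy_panel.n_markers)
    f = io.compute_frequencies(toy_panel)
    est = io.f_statistics(f, [("P1", "P2")], part)[0]
    rng = np.random.default_rng(0)
    # permute within each block (partition assignment must stay contiguous)
    idx = np.concatenate([rng.permutation(5), 5 + rng.permutation(5)])
    shuffled = PopFrequencies(f.populations, f.p[:, idx], f.a[:, idx],
                              f.markers)
    est2 = io.f_statistics(shuffled, [("P1", "P2")], part)[0]
    assert est.estimate == pytest.approx(est2.estimate, abs=1e-15)
    assert est.jackknife_se == pytest.approx(est2.jackknife_se, rel=1e-12)


# ---------------------------------------------------------------------------
# admixture test and ascertainment
# ---------------------------------------------------------------------------

def test_admixture_test_thresholds():
    def est(z):
        # se = 1 makes the Z-score bitwise equal to the stated value
        return FStatEstimate("f3", ("A", "B", "C"), z, 1.0, 10)

    flagged_99 = io.admixture_test_f3([est(-3.92), est(-2.33), est(-1.0)],
                                      alpha_level=0.99)
    # Z = -2.33 exactly is NOT flagged (strict inequality)
    assert [e.zscore for e in flagged_99] == [-3.92]
    flagged_95 = io.admixture_test_f3([est(-1.66), est(-1.0), est(-1.65)],
                                      alpha_level=0.95)
    assert [e.zscore for e in flagged_95] == [-1.66]
    with pytest.raises(ValueError):
        io.admixture_test_f3([est(-3.0)], alpha_level=0.9)


def test_ascertainment_boundary_and_oracle():
    p = np.array([[0.0, 0.051, 0.5, 0.02],
                  [0.5, 0.051, 0.5, 0.5],
                  [0.5, 0.5, 0.5, 0.9]])
    a = np.full((3, 4), 100.0)
    freqs = PopFrequencies(["Z1", "Z2", "T1"], p, a)
    groups = {"ZEB": ["Z1", "Z2"], "AFT": ["T1"]}
    keep = io.ascertain_markers(freqs, groups, maf=0.05)
    # marker 0: ZEB pooled 0.25 ok, AFT 0.5 ok -> kept
    # marker 1: ZEB pooled 0.051 > 0.05 kept; marker 3: ZEB pooled 0.26 ok,
    # AFT 0.9 -> maf 0.1 ok
    assert keep.tolist() == [True, True, True, True]
    strict = io.ascertain_markers(freqs, {"Z1_only": ["Z1"]}, maf=0.05)
    assert strict.tolist() == [False, True, True, False]
    # double-loop oracle
    for m in range(4):
        expect = all(
            min(np.average(p[[0, 1], m], weights=a[[0, 1], m]),
                1 - np.average(p[[0, 1], m], weights=a[[0, 1], m])) > 0.05
            if name == "ZEB" else
            min(p[2, m], 1 - p[2, m]) > 0.05
            for name in groups)
        assert keep[m] == expect
    with pytest.raises(ValueError):
        io.ascertain_markers(freqs, {"empty": []})


def test_popspecific_fst_pure_drift_ordering():
    """With migration off, the smaller-Ne daughter drifts more, so its
    population-specific FST is larger (1/Ne ordering)."""
    wins = 0
    for seed in range(6):
        panel, _ = sd.simulate_split_migration(
            4000, seed=seed, m_pair=(0.0, 0.0), sampling_offsets=(0, 0))
        f = io.compute_frequencies(panel)
        part = BlockPartition.from_map(panel.markers, 100)
        ps = io.fst_popspecific(f, part)
        wins += ps["MAY"].estimate > ps["ZMA"].estimate  # Ne 1045 < 2160
    assert wins >= 5
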