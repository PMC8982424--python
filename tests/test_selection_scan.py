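"""EHH pair-counting oracle, iHS/Rsb transforms, gene calling, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, norm

import iopopgen as io
from iopopgen import synthetic_data as sd
from iopopgen.genotype_io import MarkerMap
from iopopgen.selection_scan import GeneTable, HaplotypePanel, ScanScores


def _map(n, spacing_cM=0.1):
    pos_cm = spacing_cM * (np.arange(n) + 1)
    bp = (pos_cm * 1e6).astype(int)
    return MarkerMap([f"m{i}" for i in range(n)], np.ones(n, int), bp,
                     pos_cm, ["A"] * n, ["B"] * n)


def _toy_panel():
    """Six haplotypes, nine markers; core at index 4."""
    haps = np.array([
        [0, 0, 1, 0, 1, 0, 1, 0, 0],
        [0, 0, 1, 0, 1, 0, 1, 1, 0],
        [0, 1, 1, 0, 1, 0, 0, 1, 0],
        [1, 1, 0, 1, 0, 1, 1, 0, 1],
        [1, 1, 0, 1, 0, 1, 1, 0, 0],
        [1, 0, 0, 1, 0, 0, 1, 0, 0]], dtype=np.uint8)
    return HaplotypePanel(haps, _map(9), ["P"] * 3)


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def test_ehh_matches_pair_counting_oracle():
    panel = _toy_panel()
    prof = io.ehh(panel, core_marker=4, core_allele=1, cutoff=0.0,
                  max_gap_cM=10.0)
    # carriers of allele 1 at marker 4: haplotypes 0,1,2
    haps = panel.haplotypes[[0, 1, 2]]

    def oracle(markers):
        key = [tuple(h[m] for m in markers) for h in haps]
        num = sum(k1 == k2 for i, k1 in enumerate(key)
                  for k2 in key[i + 1:]) * 2
        return num / (3 * 2)

    d_right, e_right = prof["right"]
    for s, e in enumerate(e_right):
        assert e == pytest.approx(oracle(range(5, 6 + s)), abs=1e-12)
    d_left, e_left = prof["left"]
    for s, e in enumerate(e_left):
        assert e == pytest.approx(oracle(range(3 - s, 4))), (s, e_left)


def test_ehh_identical_carriers_stay_one():
    haps = np.vstack([np.tile([1, 0, 1, 1, 0, 1], (4, 1)),
                      np.array([[0, 1, 0, 0, 1, 0]] * 2)]).astype(np.uint8)
    panel = HaplotypePanel(haps, _map(6), ["P"] * 3)
    prof = io.ehh(panel, core_marker=2, core_allele=1, cutoff=0.0,
                  max_gap_cM=10.0)
    assert np.allclose(prof["right"][1], 1.0)
    assert np.allclose(prof["left"][1], 1.0)


def test_ehh_non_increasing_and_monomorphic_error():
    panel = _toy_panel()
    prof = io.ehh(panel, core_marker=4, core_allele=0, cutoff=0.0,
                  max_gap_cM=10.0)
    for side in ("left", "right"):
        e = prof[side][1]
        assert np.all(np.diff(e) <= 1e-12)
    mono = HaplotypePanel(np.ones((4, 5), dtype=np.uint8), _map(5),
                          ["P"] * 2)
    with pytest.raises(ValueError):
        io.ehh(mono, core_marker=2, core_allele=0)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def test_p_ihs_transform_values():
    z = np.array([0.0, 1.959964, -1.959964])
    p = -np.log10(1 - 2 * np.abs(norm.cdf(z) - 0.5))
    assert p[0] == pytest.approx(0.0)
    assert p[1] == pytest.approx(1.301, abs=1e-3)
    assert p[2] == pytest.approx(p[1])          # symmetric in sign


def test_rsb_identical_panels_and_antisymmetry():
    hp, _ = sd.simulate_wf_haplotypes(300, 15, seed=50, n_chromosomes=3,
                                      morgans_per_chrom=0.5,
                                      mutation_rate=5e-8, target_snps=3000)
    s12 = io.rsb(hp, hp)
    t = s12.table[s12.table.defined]
    np.testing.assert_allclose(t.rsb_raw, 0.0, atol=1e-12)
    # identical panels: all raw scores 0 -> sd 0 -> standardized undefined
    assert t.rsb.isna().all() or np.allclose(t.rsb.dropna(), 0)
    # antisymmetry against a genuinely different panel
    hp2, _ = sd.simulate_wf_haplotypes(300, 15, seed=51, n_chromosomes=3,
                                       morgans_per_chrom=0.5,
                                       mutation_rate=5e-8, target_snps=3000)
    common = min(hp.n_markers, hp2.n_markers)
    a = HaplotypePanel(hp.haplotypes[:, :common],
                       hp.markers.subset(np.arange(common)),
                       list(hp.population))
    b = HaplotypePanel(hp2.haplotypes[:, :common],
                       hp.markers.subset(np.arange(common)),
                       list(hp2.population))
    ab = io.rsb(a, b).table
    ba = io.rsb(b, a).table
    sel = ab.defined & ba.defined
    np.testing.assert_allclose(ab.rsb_raw[sel], -ba.rsb_raw[sel],
                               atol=1e-12)


def test_ihs_sweep_power_and_unphased_rejection():
    hp, _ = sd.simulate_wf_haplotypes(500, 25, seed=52, n_chromosomes=4,
                                      morgans_per_chrom=1.0,
                                      target_snps=16000)
    swept, truth = sd.inject_sweep(hp, (2, 50_000_000), 0.8, 1.0, seed=53)
    scores = io.ihs(swept, "WF")
    t = scores.table[scores.table.defined]
    core_cm = truth.params["core_cM"]
    near = t[(t.chromosome == truth.params["chromosome"])
             & (np.abs(t.position_bp * 1e-6 - core_cm) < 0.5)]
    assert near.p_ihs.max() > 4.0
    with pytest.raises(ValueError, match="phased"):
        HaplotypePanel(np.full((4, 5), 2, dtype=np.uint8), _map(5),
                       ["P"] * 2)


# ---------------------------------------------------------------------------
# gene calling
# ---------------------------------------------------------------------------

def _scores_table(chroms, pos, scores):
    df = pd.DataFrame({
        "marker_id": [f"s{i}" for i in range(len(pos))],
        "chromosome": chroms, "position_bp": pos, "p_ihs": scores})
    return ScanScores(df, "ihs")


def test_gene_calling_min_snps_rule_and_flank_arithmetic():
    genes = GeneTable(pd.DataFrame({
        "gene": ["G1", "G2", "G3"],
        "chromosome": [1, 1, 2],
        "start_bp": [100_000, 500_000, 100_000],
        "end_bp": [120_000, 540_000, 200_000]}))
    scores = _scores_table(
        chroms=[1, 1, 1, 1, 2, 2],
        pos=[85_000, 84_999, 505_000, 530_000, 150_000, 215_000],
        scores=[5.0, 9.9, 4.1, 4.3, 5.0, 5.0])
    out = io.call_candidate_genes(scores, genes).set_index("gene")
    # SNP at start-15000 = 85,000 is inside G1's flank; 84,999 is not
    assert out.loc["G1", "n_snps"] == 1
    assert not out.loc["G1", "candidate"]      # single SNP: min_snps rule
    assert out.loc["G2", "n_extreme"] == 2     # 4.1 and 4.3 both > 4
    assert bool(out.loc["G2", "candidate"])
    assert bool(out.loc["G3", "candidate"])    # 150k inside, 215k in flank


def test_gene_calling_matches_bruteforce_interval_scan():
    rng = np.random.default_rng(23)
    genes = GeneTable(pd.DataFrame({
        "gene": [f"g{i}" for i in range(10)],
        "chromosome": rng.integers(1, 3, 10),
        "start_bp": (s := rng.integers(1, 2_000_000, 10)),
        "end_bp": s + rng.integers(1_000, 100_000, 10)}))
    chroms = rng.integers(1, 3, 50)
    pos = rng.integers(1, 2_100_000, 50)
    scr = rng.uniform(0, 8, 50)
    out = io.call_candidate_genes(_scores_table(chroms, pos, scr), genes)
    out = out.set_index("gene")
    for _, g in genes.table.iterrows():
        lo, hi = g.start_bp - 15_000, g.end_bp + 15_000
        assigned = [(c == g.chromosome and lo <= p <= hi)
                    for c, p in zip(chroms, pos)]
        n_ext = sum(a and v > 4.0 for a, v in zip(assigned, scr))
        if sum(assigned) == 0:
            assert g.gene not in out.index
        else:
            assert out.loc[g.gene, "n_snps"] == sum(assigned)
            assert out.loc[g.gene, "n_extreme"] == n_ext
            assert out.loc[g.gene, "candidate"] == (n_ext >= 2)
    # SNP order invariance
    perm = rng.permutation(50)
    out2 = io.call_candidate_genes(
        _scores_table(chroms[perm], pos[perm], scr[perm]), genes)
    pd.testing.assert_frame_equal(
        out.reset_index(), out2, check_like=True)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_matches_hypergeometric_tail():
    universe = [f"g{i}" for i in range(100)]
    category = universe[:20]
    candidates = set(universe[:3]) | set(universe[50:57])  # 3 in category
    ann = pd.DataFrame({"gene": category, "category": "CAT"})
    out = io.geneset_enrichment(candidates, ann, universe)
    expect = hypergeom.sf(2, 100, 20, 10)
    assert out.p_value[0] == pytest.approx(expect, rel=1e-12)
    # manual tail sum oracle
    tail = sum(hypergeom.pmf(k, 100, 20, 10) for k in range(3, 11))
    assert out.p_value[0] == pytest.approx(tail, rel=1e-9)


def test_enrichment_extreme_category_flagged_and_errors():
    universe = [f"g{i}" for i in range(60)]
    cands = set(universe[:6])
    ann = pd.DataFrame({"gene": universe[:8], "category": "HOT"})
    out = io.geneset_enrichment(cands, ann, universe)
    assert out.significant[0]
    assert out.p_value[0] < 1e-4
    with pytest.raises(ValueError):
        io.geneset_enrichment({"zzz"}, ann, universe)
    with pytest.raises(ValueError):
        io.geneset_enrichment(set(), ann, [])


def test_enrichment_null_uniform_pvalues():
    """Random candidate draws give approximately uniform p-values."""
    from scipy.stats import kstest

    rng = np.random.default_rng(24)
    universe = [f"g{i}" for i in range(200)]
    ann = pd.DataFrame({"gene": universe[:40], "category": "C"})
    pvals = []
    for _ in range(200):
        cands = set(rng.choice(universe, size=20, replace=False))
        out = io.geneset_enrichment(cands, ann, universe)
        pvals.append(out.p_value[0])
    # discrete p-values are super-uniform; KS against uniform must not
    # reject wildly in the anti-conservative direction
    stat, p = kstest(pvals, "uniform", alternative="greater")
    assert p > 0.01
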