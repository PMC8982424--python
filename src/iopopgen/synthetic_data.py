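"""Seeded generators with the statistical structure the analyses assume.

Two complementary engines, both pure functions of (parameters, seed):

* an allele-frequency engine — Gaussian drift-diffusion down an admixture
  graph (for f-statistics and graph fitting) and a discrete Wright–Fisher
  two-island split with continuous migration from a common pool (the
  scenario that reconciles the island populations' differentiation and
  heterozygosity contrasts: split ~80 generations before sampling,
  constant island Ne, asymmetric migration 4e-3 vs 2e-3 per generation);

* a haplotype engine — ancestry-mosaic haplotypes whose switch points
  follow a Poisson process at the admixture age (for weighted-LD dating),
  pedigree-style inbred individuals with recorded autozygous tracts (for
  the HBD HMM), and selective-sweep injection (for EHH scans).

Every generator emits a TruthRecord next to its dataset; recovery tests
read the truth only from there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from iopopgen.genotype_io import MISSING, GenotypePanel, MarkerMap
from iopopgen.fstats import PopFrequencies
from iopopgen.admixture_graph import AdmixtureGraph
from iopopgen.selection_scan import HaplotypePanel

__all__ = ["TruthRecord", "make_map", "simulate_graph_frequencies",
           "simulate_admixed_haplotypes", "simulate_split_migration",
           "simulate_inbred_individuals", "inject_sweep", "corrupt_panel",
           "haplotypes_from_frequencies", "simulate_wf_haplotypes",
           "island_zebu_graph"]


@dataclass
class TruthRecord:
    """Ground truth emitted alongside every synthetic dataset."""

    scenario: str
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"scenario": self.scenario, **self.params}


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def make_map(n_snps: int, n_chromosomes: int = 29, total_cM: float = 2900.0,
             cM_per_Mb: float = 1.0, prefix: str = "snp") -> MarkerMap:
    """Evenly spaced marker map over ``n_chromosomes`` equal autosomes."""
    per = np.full(n_chromosomes, n_snps // n_chromosomes, dtype=int)
    per[:n_snps % n_chromosomes] += 1
    chrom_cM = total_cM / n_chromosomes
    ids, chroms, bps, cms = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        m = per[c - 1]
        if m == 0:
            continue
        cm = (np.arange(m) + 1.0) * chrom_cM / (m + 1)
        bp = np.round(cm / cM_per_Mb * 1e6).astype(np.int64)
        bp = np.maximum.accumulate(bp + np.arange(m))  # strictly increasing
        ids.extend(f"{prefix}_{c}_{i}" for i in range(m))
        chroms.extend([c] * m)
        bps.extend(bp.tolist())
        cms.extend((bp * cM_per_Mb * 1e-6).tolist())
    n = len(ids)
    return MarkerMap(np.array(ids, dtype=object), chroms, bps, cms,
                     np.array(["A"] * n, dtype=object),
                     np.array(["B"] * n, dtype=object))


# ---------------------------------------------------------------------------
# Graph-frequency engine
# ---------------------------------------------------------------------------

def island_zebu_graph() -> AdmixtureGraph:
    """The two-pulse taurine x indicine admixture topology.

    An African-zebu ancestor mixes a NEL-related zebu with an African-
    taurine branch (alpha = 0.684 zebu); an Indian-Ocean-zebu ancestor
    then mixes that African zebu (alpha = 0.886) with a GIR-related zebu;
    the island populations MAY and ZMA both descend from it. Drift lengths
    are plausible placeholders on the data scale (x1e-3).
    """
    e = {
        ("ROOT", "TAUR"): 0.02, ("ROOT", "ZEBU"): 0.02,
        ("TAUR", "HOL"): 0.03, ("TAUR", "AFTanc"): 0.01,
        ("AFTanc", "NDA"): 0.02, ("AFTanc", "LAG"): 0.03,
        ("AFTanc", "AFTsrc"): 0.005,
        ("ZEBU", "ZEBanc"): 0.01,
        ("ZEBanc", "NEL"): 0.01, ("ZEBanc", "GIR"): 0.012,
        ("ZEBanc", "NELsrc"): 0.004, ("ZEBanc", "GIRsrc"): 0.004,
        ("NELsrc", "AFZ"): 0.004, ("AFTsrc", "AFZ"): 0.004,
        ("AFZ", "EAZ"): 0.01, ("AFZ", "AFZsrc"): 0.003,
        ("GIRsrc", "IOZ"): 0.003, ("AFZsrc", "IOZ"): 0.003,
        ("IOZ", "MAY"): 0.008, ("IOZ", "ZMA"): 0.016,
    }
    adm = {"AFZ": ("NELsrc", "AFTsrc", 0.684),
           "IOZ": ("AFZsrc", "GIRsrc", 0.886)}
    return AdmixtureGraph("ROOT", e, adm)


def simulate_graph_frequencies(graph: AdmixtureGraph, n_snps: int,
                               seed: int, n_per_pop: int = 30,
                               root_freq_law=(0.05, 0.95),
                               markers: MarkerMap | None = None):
    """Drift-diffusion allele frequencies down a graph, plus genotypes.

    Root frequencies are uniform on ``root_freq_law``; along each edge of
    drift length l the child frequency is parent + Normal(0, l p(1-p))
    truncated to [0, 1]; an admixture node mixes its parents' frequencies
    linearly with weight alpha. Leaf genotypes are binomial draws for
    ``n_per_pop`` diploids per leaf. Returns (PopFrequencies of the true
    leaf frequencies, GenotypePanel, TruthRecord).
    """
    rng = np.random.default_rng(seed)
    freq = {graph.root: rng.uniform(*root_freq_law, size=n_snps)}
    for node in graph.topological_order():
        if node == graph.root:
            continue
        if node in graph.admixture:
            pa, pb, alpha = graph.admixture[node]
            # each in-edge drifts its parent's frequency, then mix linearly
            parts = []
            for par in (pa, pb):
                l = graph.edges[(par, node)]
                v = freq[par]
                if l > 0:
                    v = np.clip(v + rng.normal(
                        0.0, np.sqrt(l * v * (1 - v))), 0.0, 1.0)
                parts.append(v)
            freq[node] = alpha * parts[0] + (1 - alpha) * parts[1]
            continue
        parent = graph.parents(node)[0]
        base = freq[parent]
        drift = graph.edges[(parent, node)]
        if drift > 0:
            base = base + rng.normal(0.0, np.sqrt(drift * base * (1 - base)))
        freq[node] = np.clip(base, 0.0, 1.0)

    leaves = graph.leaves
    p_true = np.vstack([freq[l] for l in leaves])
    a = np.full_like(p_true, 2.0 * n_per_pop)
    if markers is None:
        markers = make_map(n_snps)
    ids, pops, rows = [], [], []
    for li, leaf in enumerate(leaves):
        g = rng.binomial(2, p_true[li], size=(n_per_pop, n_snps))
        rows.append(g)
        ids.extend(f"{leaf}_{i}" for i in range(n_per_pop))
        pops.extend([leaf] * n_per_pop)
    panel = GenotypePanel(markers, ids, pops,
                          np.vstack(rows).astype(np.int8))
    truth = TruthRecord("graph_frequencies", {
        "edges": {f"{p}->{c}": l for (p, c), l in graph.edges.items()},
        "alphas": {k: v[2] for k, v in graph.admixture.items()},
        "n_snps": n_snps, "seed": seed})
    return PopFrequencies(list(leaves), p_true, a, markers), panel, truth


# ---------------------------------------------------------------------------
# Haplotype engine
# ---------------------------------------------------------------------------

def haplotypes_from_frequencies(freq: np.ndarray, n_haplotypes: int,
                                markers: MarkerMap, seed: int,
                                population: str = "POP") -> HaplotypePanel:
    """Independent-site haplotypes from per-marker allele frequencies."""
    rng = np.random.default_rng(seed)
    haps = (rng.random((n_haplotypes, len(freq))) < freq).astype(np.uint8)
    return HaplotypePanel(haps, markers,
                          [population] * (n_haplotypes // 2))


def simulate_admixed_haplotypes(source1: np.ndarray, source2: np.ndarray,
                                alpha: float, n_generations: float,
                                markers: MarkerMap, n_haplotypes: int,
                                seed: int):
    """Ancestry-mosaic haplotypes from two source haplotype pools.

    Each output haplotype is cut into tracts by a Poisson switch process
    of rate ``n_generations`` per Morgan along each chromosome; each tract
    draws its ancestry (source 1 with probability alpha) and copies a
    random haplotype of that source. Returns (HaplotypePanel,
    TruthRecord).
    """
    rng = np.random.default_rng(seed)
    cm = markers.genetic_pos_cM
    chrom = markers.chromosome
    n_mrk = len(markers)
    out = np.empty((n_haplotypes, n_mrk), dtype=np.uint8)
    tract_lengths = []
    for h in range(n_haplotypes):
        for c in np.unique(chrom):
            sel = np.flatnonzero(chrom == c)
            pos_m = cm[sel] / 100.0
            length = pos_m[-1] - pos_m[0] if len(sel) > 1 else 0.0
            # switch points along the chromosome
            n_switch = rng.poisson(n_generations * length) \
                if n_generations > 0 and length > 0 else 0
            cuts = np.sort(rng.uniform(pos_m[0], pos_m[-1], size=n_switch))
            bounds = np.concatenate(([pos_m[0] - 1e-9], cuts,
                                     [pos_m[-1] + 1e-9]))
            anc = rng.random(len(bounds) - 1) < alpha
            tract_lengths.extend(np.diff(bounds)[1:-1] if len(bounds) > 3
                                 else [])
            seg = np.searchsorted(bounds, pos_m, side="right") - 1
            for s in np.unique(seg):
                src = source1 if anc[s] else source2
                donor = src[rng.integers(0, src.shape[0])]
                msel = sel[seg == s]
                out[h, msel] = donor[msel]
    panel = HaplotypePanel(out, markers, ["ADM"] * (n_haplotypes // 2))
    truth = TruthRecord("admixed_mosaic", {
        "alpha": alpha, "n_generations": n_generations,
        "n_haplotypes": n_haplotypes, "seed": seed,
        "mean_tract_length_cM": float(np.mean(tract_lengths) * 100)
        if tract_lengths else np.nan})
    return panel, truth


def panel_from_haplotypes(haps: HaplotypePanel, population: str | None = None,
                          sampling_year: dict | None = None) -> GenotypePanel:
    """Collapse a phased panel to unphased diploid dosages."""
    g = (haps.haplotypes[0::2].astype(np.int8)
         + haps.haplotypes[1::2].astype(np.int8))
    pops = [population or p for p in haps.population]
    ids = [f"{p}_{i}" for i, p in enumerate(pops)]
    return GenotypePanel(haps.markers, ids, pops, g,
                         sampling_year or {})


def simulate_wf_haplotypes(Ne: float, n_individuals: int, seed: int,
                           n_chromosomes: int = 20,
                           morgans_per_chrom: float = 1.0,
                           target_snps: int | None = None,
                           mutation_rate: float = 1e-8,
                           demography=None, population: str = "WF"):
    """Neutral haplotypes under a (possibly piecewise) constant-Ne history.

    Coalescent simulation (msprime) of ``n_chromosomes`` independent
    chromosomes at 1 cM/Mb, giving panels whose LD decay genuinely
    reflects Ne — the ground truth for the LD-based Ne estimator and for
    neutral EHH calibration. ``demography`` may be a list of
    (time_generations, Ne) change points, most recent first; otherwise Ne
    is constant. When ``target_snps`` is set, markers are thinned to
    (at most) that count, evenly. Returns (HaplotypePanel, TruthRecord).
    """
    import msprime

    rng = np.random.default_rng(seed)
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=Ne)
    for t_gen, size in (demography or []):
        dem.add_population_parameters_change(time=t_gen, initial_size=size,
                                             population="pop0")
    chrom_bp = int(morgans_per_chrom * 1e8)  # 1 cM/Mb
    hap_chunks, ids, chroms, bps = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        ts = msprime.sim_ancestry(
            samples={"pop0": n_individuals}, demography=dem,
            sequence_length=chrom_bp, recombination_rate=1e-8,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        ts = msprime.sim_mutations(
            ts, rate=mutation_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        pos = np.array([int(s.position) for s in ts.sites()])
        gm = ts.genotype_matrix().T.astype(np.uint8)  # (n_hap, n_sites)
        # biallelic 0/1 only; collapse rare multiallelic codes
        gm = np.minimum(gm, 1)
        seg = (gm.sum(axis=0) > 0) & (gm.sum(axis=0) < gm.shape[0])
        uniq = np.concatenate(([True], np.diff(pos) > 0))
        keep = np.flatnonzero(seg & uniq)
        hap_chunks.append(gm[:, keep])
        chroms.extend([c] * len(keep))
        bps.extend((pos[keep] + 1).tolist())
        ids.extend(f"wf_{c}_{i}" for i in range(len(keep)))
    haps = np.hstack(hap_chunks)
    chroms = np.array(chroms)
    bps = np.array(bps)
    if target_snps is not None and haps.shape[1] > target_snps:
        sel = np.sort(rng.choice(haps.shape[1], size=target_snps,
                                 replace=False))
        haps = haps[:, sel]
        chroms, bps = chroms[sel], bps[sel]
        ids = [ids[i] for i in sel]
    markers = MarkerMap(np.array(ids, dtype=object), chroms, bps,
                        bps * 1e-6,
                        np.array(["A"] * len(bps), dtype=object),
                        np.array(["B"] * len(bps), dtype=object))
    panel = HaplotypePanel(haps, markers, [population] * n_individuals)
    truth = TruthRecord("wf_haplotypes", {
        "Ne": Ne, "demography": demography, "n_individuals": n_individuals,
        "n_chromosomes": n_chromosomes,
        "morgans_per_chrom": morgans_per_chrom, "seed": seed})
    return panel, truth


# ---------------------------------------------------------------------------
# Split-with-migration Wright–Fisher engine
# ---------------------------------------------------------------------------

def simulate_split_migration(n_snps: int, seed: int,
                             Ne_pair=(1045, 2160), t_split: int = 80,
                             m_pair=(4e-3, 2e-3), pool_Ne: int = 10000,
                             n_per_pop=(30, 25), sampling_offsets=(0, 4),
                             pop_names=("MAY", "ZMA"),
                             markers: MarkerMap | None = None):
    """Two-island split from a common pool with continuous migration.

    Discrete Wright–Fisher allele-frequency simulation: the ancestral pool
    sits at stationary frequencies (uniform 0.05–0.95 draw); at the split
    both daughters copy the pool and then drift for ``t_split``
    generations with binomial resampling at their Ne (2Ne gene copies),
    receiving a fraction m of their gene pool from the common pool every
    generation (the pool itself drifts at ``pool_Ne``). Daughter i is
    genotyped ``sampling_offsets[i]`` generations before the end.

    Returns (GenotypePanel covering both daughters, TruthRecord).
    """
    rng = np.random.default_rng(seed)
    p_pool = rng.uniform(0.05, 0.95, size=n_snps)
    p = [p_pool.copy(), p_pool.copy()]
    sampled = [None, None]
    for gen in range(t_split):
        p_pool = rng.binomial(2 * pool_Ne, p_pool) / (2.0 * pool_Ne)
        for i in (0, 1):
            drifted = rng.binomial(2 * Ne_pair[i], p[i]) / (2.0 * Ne_pair[i])
            p[i] = (1.0 - m_pair[i]) * drifted + m_pair[i] * p_pool
            if t_split - (gen + 1) == sampling_offsets[i]:
                sampled[i] = p[i].copy()
    for i in (0, 1):
        if sampled[i] is None:  # offset >= t_split degenerates to the split
            sampled[i] = p[i].copy()
    if markers is None:
        markers = make_map(n_snps)
    ids, pops, rows = [], [], []
    for i, name in enumerate(pop_names):
        g = rng.binomial(2, sampled[i], size=(n_per_pop[i], n_snps))
        rows.append(g)
        ids.extend(f"{name}_{j}" for j in range(n_per_pop[i]))
        pops.extend([name] * n_per_pop[i])
    panel = GenotypePanel(markers, ids, pops, np.vstack(rows).astype(np.int8))
    truth = TruthRecord("split_migration", {
        "Ne": list(Ne_pair), "t_split": t_split, "m": list(m_pair),
        "pool_Ne": pool_Ne, "sampling_offsets": list(sampling_offsets),
        "seed": seed})
    return panel, truth


# ---------------------------------------------------------------------------
# Inbred individuals with recorded HBD tracts
# ---------------------------------------------------------------------------

def _meiosis(rng, hap_a, hap_b, markers):
    """One gamete: crossover mosaic of the two parental haplotypes.

    Haplotypes are (ancestry-label, allele) pairs of arrays; crossovers
    follow a Poisson process on the genetic map per chromosome.
    """
    lab_a, al_a = hap_a
    lab_b, al_b = hap_b
    n = len(markers)
    lab = np.empty(n, dtype=np.int64)
    al = np.empty(n, dtype=np.uint8)
    cm = markers.genetic_pos_cM
    for c in np.unique(markers.chromosome):
        sel = np.flatnonzero(markers.chromosome == c)
        pos_m = cm[sel] / 100.0
        length = pos_m[-1] - pos_m[0] if len(sel) > 1 else 0.0
        n_x = rng.poisson(length)
        cuts = np.sort(rng.uniform(pos_m[0], pos_m[-1], size=n_x))
        seg = np.searchsorted(cuts, pos_m, side="right")
        use_a = (seg + rng.integers(0, 2)) % 2 == 0
        lab[sel] = np.where(use_a, lab_a[sel], lab_b[sel])
        al[sel] = np.where(use_a, al_a[sel], al_b[sel])
    return lab, al


def simulate_inbred_individuals(n_individuals: int, markers: MarkerMap,
                                seed: int, mating: str = "half_sibs",
                                freq: np.ndarray | None = None):
    """Offspring of related parents, with true autozygous tracts recorded.

    ``mating``: 'half_sibs' (parents share one parent; expected F = 1/8),
    'full_sibs' (F = 1/4), 'selfing' (one parent's two gametes; F = 1/2)
    or 'unrelated' (F = 0). Founder haplotypes are independent-site draws
    from ``freq`` (default uniform 0.1–0.9 per marker). Returns
    (GenotypePanel, true_F array, TruthRecord); true F is the realized
    autozygous genome fraction (identical founder-haplotype labels),
    length-weighted on the genetic map.
    """
    rng = np.random.default_rng(seed)
    n_mrk = len(markers)
    if freq is None:
        freq = rng.uniform(0.1, 0.9, size=n_mrk)
    label_counter = [0]

    def founder():
        lab = np.full(n_mrk, label_counter[0], dtype=np.int64)
        label_counter[0] += 1
        al = (rng.random(n_mrk) < freq).astype(np.uint8)
        return lab, al

    genos = np.empty((n_individuals, n_mrk), dtype=np.int8)
    true_f = np.empty(n_individuals)
    # length weights per marker (midpoint spacing on the cM map)
    w = np.ones(n_mrk)
    for c in np.unique(markers.chromosome):
        sel = np.flatnonzero(markers.chromosome == c)
        d = np.diff(markers.genetic_pos_cM[sel])
        wc = np.empty(len(sel))
        wc[0] = d[0] / 2 if len(d) else 1.0
        wc[-1] = d[-1] / 2 if len(d) else 1.0
        if len(sel) > 2:
            wc[1:-1] = (d[:-1] + d[1:]) / 2
        w[sel] = wc
    for i in range(n_individuals):
        if mating == "selfing":
            parent = (founder(), founder())
            g1 = _meiosis(rng, parent[0], parent[1], markers)
            g2 = _meiosis(rng, parent[0], parent[1], markers)
        elif mating == "full_sibs":
            pa, pb = founder(), founder()
            pc, pd = founder(), founder()
            sib1 = (_meiosis(rng, pa, pb, markers),
                    _meiosis(rng, pc, pd, markers))
            sib2 = (_meiosis(rng, pa, pb, markers),
                    _meiosis(rng, pc, pd, markers))
            g1 = _meiosis(rng, sib1[0], sib1[1], markers)
            g2 = _meiosis(rng, sib2[0], sib2[1], markers)
        elif mating == "half_sibs":
            shared_a, shared_b = founder(), founder()
            dam1 = (founder(), founder())
            dam2 = (founder(), founder())
            sib1 = (_meiosis(rng, shared_a, shared_b, markers),
                    _meiosis(rng, dam1[0], dam1[1], markers))
            sib2 = (_meiosis(rng, shared_a, shared_b, markers),
                    _meiosis(rng, dam2[0], dam2[1], markers))
            g1 = _meiosis(rng, sib1[0], sib1[1], markers)
            g2 = _meiosis(rng, sib2[0], sib2[1], markers)
        elif mating == "unrelated":
            p1 = (founder(), founder())
            p2 = (founder(), founder())
            g1 = _meiosis(rng, p1[0], p1[1], markers)
            g2 = _meiosis(rng, p2[0], p2[1], markers)
        else:
            raise ValueError(f"unknown mating design {mating!r}")
        hbd = g1[0] == g2[0]
        true_f[i] = float((w * hbd).sum() / w.sum())
        genos[i] = g1[1] + g2[1]
    panel = GenotypePanel(markers, [f"ind_{i}" for i in range(n_individuals)],
                          ["INBRED"] * n_individuals, genos)
    truth = TruthRecord("inbred_pedigree", {
        "mating": mating, "true_F": true_f.tolist(), "seed": seed})
    return panel, true_f, truth


# ---------------------------------------------------------------------------
# Sweep injection and panel corruption
# ---------------------------------------------------------------------------

def inject_sweep(panel: HaplotypePanel, core_position: tuple,
                 carrier_freq: float, sweep_length_cM: float, seed: int,
                 mutation_noise: float = 0.005):
    """Overwrite a carrier fraction with one template haplotype locally.

    ``core_position`` is (chromosome, position_bp); carriers are a random
    ``carrier_freq`` fraction of haplotypes whose alleles within
    +/- ``sweep_length_cM`` of the core are replaced by a single template
    (with ``mutation_noise`` per-marker flip noise). Returns (new panel,
    TruthRecord with the core marker index).
    """
    rng = np.random.default_rng(seed)
    chrom, bp = core_position
    m = panel.markers
    on_chrom = np.flatnonzero(m.chromosome == chrom)
    if on_chrom.size == 0:
        raise ValueError(f"no markers on chromosome {chrom}")
    core = on_chrom[np.argmin(np.abs(m.position_bp[on_chrom] - bp))]
    if abs(int(m.position_bp[core]) - bp) > 5e6:
        raise ValueError("core position falls outside the marker map")
    core_cm = m.genetic_pos_cM[core]
    region = on_chrom[np.abs(m.genetic_pos_cM[on_chrom] - core_cm)
                      <= sweep_length_cM]
    haps = panel.haplotypes.copy()
    n_hap = haps.shape[0]
    n_car = int(round(carrier_freq * n_hap))
    carriers = rng.choice(n_hap, size=n_car, replace=False)
    template = haps[rng.integers(0, n_hap), region].copy()
    for h in carriers:
        hap = template.copy()
        flips = rng.random(len(region)) < mutation_noise
        hap[flips] = 1 - hap[flips]
        haps[h, region] = hap
    out = HaplotypePanel(haps, panel.markers, list(panel.population))
    truth = TruthRecord("sweep", {
        "core_marker_index": int(core), "chromosome": int(chrom),
        "core_bp": int(m.position_bp[core]),
        "core_cM": float(core_cm), "carrier_freq": carrier_freq,
        "sweep_length_cM": sweep_length_cM, "seed": seed})
    return out, truth


def corrupt_panel(panel: GenotypePanel, missing_rate: float,
                  error_rate: float, seed: int) -> GenotypePanel:
    """Mask genotypes i.i.d. and flip dosages by +/-1 at the given rates."""
    if not (0 <= missing_rate <= 0.5 and 0 <= error_rate <= 0.5):
        raise ValueError("rates must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    g = panel.genotypes.copy()
    if error_rate > 0:
        flip = (rng.random(g.shape) < error_rate) & (g != MISSING)
        delta = rng.choice([-1, 1], size=g.shape)
        g = np.where(flip, np.clip(g + delta, 0, 2), g)
    if missing_rate > 0:
        g = np.where(rng.random(g.shape) < missing_rate, MISSING, g)
    return GenotypePanel(panel.markers, list(panel.individual_id),
                         list(panel.population), g.astype(np.int8),
                         dict(panel.sampling_year))
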