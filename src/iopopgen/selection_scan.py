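"""EHH-based selection scans: iHS within and Rsb between populations.

Extended haplotype homozygosity (EHH) at genetic distance d from a core
site is the probability that two random distinct carrier haplotypes are
identical over the whole stretch from the core to d. Integrating EHH
outward (trapezoid on the genetic map, truncated when EHH drops below a
cutoff or a map gap is too large) gives iHH per core allele and the
site-wise iES. Then

    iHS raw = ln(iHH_b / iHH_a)   standardized within frequency bins,
    Rsb raw = ln(iES_1 / iES_2)   standardized genome-wide,

and the Gaussian-tail transforms p_iHS = -log10(1 - 2|Phi(x) - 0.5|)
(two-sided) and p_Rsb = -log10(Phi(x)) (one-sided, with the mirrored tail
-log10(1 - Phi(x)) reported alongside). Gene-level candidate calling maps
SNPs to genes extended by a 15 kb flank and requires at least two SNPs
with a transformed score above 4; gene-set enrichment uses the
right-tailed Fisher exact (hypergeometric) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import hypergeom, norm

from iopopgen.genotype_io import MarkerMap

__all__ = ["HaplotypePanel", "ScanScores", "GeneTable", "ehh", "ihs", "rsb",
           "call_candidate_genes", "geneset_enrichment"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased haplotypes: alleles {0,1}, two rows per individual.

    Unphased or missing data are rejected — phasing is an input contract
    (phase with an external tool first; the synthetic generators emit
    phased data directly).
    """

    haplotypes: np.ndarray        # (n_haplotypes, n_markers) uint8
    markers: MarkerMap
    population: list              # per individual

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n_hap, n_mrk = self.haplotypes.shape
        if n_hap % 2:
            raise ValueError("haplotype count must be even (diploids)")
        if n_mrk != len(self.markers):
            raise ValueError("haplotype matrix width != marker count")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError(
                "phased panel must be complete {0,1}; phase unphased data "
                "externally before scanning")
        if len(self.population) != n_hap // 2:
            raise ValueError("one population label per individual required")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def pop_haplotypes(self, pop: str) -> np.ndarray:
        idx = [i for i, p in enumerate(self.population) if p == pop]
        if not idx:
            raise KeyError(f"no individuals in population {pop!r}")
        rows = np.array(sorted([2 * i for i in idx] + [2 * i + 1 for i in idx]))
        return self.haplotypes[rows]


@dataclass
class ScanScores:
    """Per-marker raw and transformed scan scores."""

    table: pd.DataFrame           # marker_id, chromosome, position_bp, ...
    statistic: str                # 'ihs' or 'rsb'

    def extreme(self, column: str, threshold: float) -> pd.DataFrame:
        return self.table[self.table[column] > threshold]


@dataclass
class GeneTable:
    """Gene coordinates, 1-based inclusive."""

    table: pd.DataFrame           # gene, chromosome, start_bp, end_bp

    def __post_init__(self) -> None:
        t = self.table
        need = {"gene", "chromosome", "start_bp", "end_bp"}
        if not need <= set(t.columns):
            raise ValueError(f"gene table needs columns {sorted(need)}")
        if (t.start_bp > t.end_bp).any():
            raise ValueError("gene start must be <= end")


# ---------------------------------------------------------------------------
# EHH core (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ehh_scan(haps, start_groups, core, pos_cm, lo, hi, cutoff, max_gap_cm):
    """EHH profile from a core outward in one direction.

    haps: (n_hap, n_markers) uint8 over the carrier subset; start_groups:
    initial group labels; scans markers core+1..hi (step +1) when hi>core,
    or core-1..lo (step -1). Returns (ehh_values, n_steps) where
    ehh_values[s] is EHH at the s-th marker out.
    """
    n_hap = haps.shape[0]
    step = 1 if hi > core else -1
    end = hi if step == 1 else lo
    n_steps = (end - core) * step
    out = np.empty(n_steps)
    groups = start_groups.copy()
    new_groups = np.empty(n_hap, dtype=np.int64)
    denom = n_hap * (n_hap - 1.0)
    prev_pos = pos_cm[core]
    count = 0
    for s in range(1, n_steps + 1):
        m = core + step * s
        if abs(pos_cm[m] - prev_pos) > max_gap_cm:
            break
        prev_pos = pos_cm[m]
        # refine groups by the allele at m
        for h in range(n_hap):
            new_groups[h] = groups[h] * 2 + haps[h, m]
        # compress labels (counts per distinct label)
        order = np.argsort(new_groups)
        ehh_num = 0.0
        run = 1
        for i in range(1, n_hap):
            if new_groups[order[i]] == new_groups[order[i - 1]]:
                run += 1
            else:
                ehh_num += run * (run - 1.0)
                run = 1
        ehh_num += run * (run - 1.0)
        # relabel compactly to avoid overflow on long scans
        label = 0
        groups[order[0]] = 0
        for i in range(1, n_hap):
            if new_groups[order[i]] != new_groups[order[i - 1]]:
                label += 1
            groups[order[i]] = label
        e = ehh_num / denom
        out[count] = e
        count += 1
        if e < cutoff:
            break
    return out, count


def _ehh_profile(haps, core, pos_cm, cutoff, max_gap_cm, carriers):
    """(distances, ehh) arrays both directions, including the core point."""
    sub = haps[carriers]
    n = sub.shape[0]
    groups0 = np.zeros(n, dtype=np.int64)
    res = {}
    for direction, bound in (("right", haps.shape[1] - 1), ("left", 0)):
        if (bound == core):
            res[direction] = (np.empty(0), np.empty(0))
            continue
        vals, cnt = _ehh_scan(sub, groups0, core, pos_cm, 0, bound,
                              cutoff, max_gap_cm)
        step = 1 if direction == "right" else -1
        ms = core + step * np.arange(1, cnt + 1)
        res[direction] = (np.abs(pos_cm[ms] - pos_cm[core]), vals[:cnt])
    return res


def ehh(panel: HaplotypePanel, core_marker: int, core_allele: int,
        cutoff: float = 0.05, max_gap_cM: float = 0.5, pop: str | None = None):
    """EHH profile around a core marker for carriers of ``core_allele``.

    Returns a dict with 'left' and 'right' (distance_cM, ehh) arrays; EHH
    at the core itself is 1 by definition. Errors if fewer than two
    haplotypes carry the allele.
    """
    haps = panel.pop_haplotypes(pop) if pop else panel.haplotypes
    carriers = np.flatnonzero(haps[:, core_marker] == core_allele)
    if len(carriers) < 2:
        raise ValueError("core allele must be carried by >= 2 haplotypes")
    return _ehh_profile(haps, core_marker, panel.markers.genetic_pos_cM,
                        cutoff, max_gap_cM, carriers)


@njit(cache=True)
def _site_scan_all(haps, pos_cm, cutoff, max_gap_cm, alleles_split):
    """iHH (per allele) or iES (pooled) for every marker.

    alleles_split=True: returns (ihh0, ihh1, ok) integrating per-allele
    EHH; False: returns (ies, ies, ok) with haplotypes pooled but split by
    the core allele (site EHH normalized to 1 at the core).
    """
    n_hap, n_mrk = haps.shape
    out0 = np.zeros(n_mrk)
    out1 = np.zeros(n_mrk)
    ok = np.zeros(n_mrk, dtype=np.uint8)
    groups = np.empty(n_hap, dtype=np.int64)
    new_groups = np.empty(n_hap, dtype=np.int64)
    for core in range(n_mrk):
        n1 = 0
        for h in range(n_hap):
            n1 += haps[h, core]
        n0 = n_hap - n1
        if alleles_split:
            if n0 < 2 or n1 < 2:
                continue
            passes = 2
        else:
            passes = 1
        good = True
        for pa in range(passes):
            if alleles_split:
                target = pa
                nsub = n0 if pa == 0 else n1
            else:
                target = -1
                nsub = n_hap
            integral = 0.0
            for direction in range(2):
                step = 1 if direction == 0 else -1
                # initial groups
                if alleles_split:
                    idx = np.empty(nsub, dtype=np.int64)
                    j = 0
                    for h in range(n_hap):
                        if haps[h, core] == target:
                            idx[j] = h
                            j += 1
                    for j in range(nsub):
                        groups[j] = 0
                    denom = nsub * (nsub - 1.0)
                else:
                    idx = np.arange(n_hap)
                    for j in range(n_hap):
                        groups[j] = haps[j, core]
                    # normalize site EHH to 1 at the core
                    c1 = 0
                    for j in range(n_hap):
                        c1 += haps[j, core]
                    c0 = n_hap - c1
                    denom = 1.0 * (c0 * (c0 - 1.0) + c1 * (c1 - 1.0))
                    if denom == 0.0:
                        good = False
                        break
                prev_e = 1.0
                prev_d = 0.0
                m = core
                prev_pos = pos_cm[core]
                while True:
                    m += step
                    if m < 0 or m >= n_mrk:
                        # hit the chromosome end before decaying
                        if prev_e >= cutoff:
                            good = False
                        break
                    if abs(pos_cm[m] - prev_pos) > max_gap_cm:
                        break
                    prev_pos = pos_cm[m]
                    for j in range(nsub):
                        new_groups[j] = groups[j] * 2 + haps[idx[j], m]
                    order = np.argsort(new_groups[:nsub])
                    num = 0.0
                    run = 1
                    for i in range(1, nsub):
                        if new_groups[order[i]] == new_groups[order[i - 1]]:
                            run += 1
                        else:
                            num += run * (run - 1.0)
                            run = 1
                    num += run * (run - 1.0)
                    label = 0
                    groups[order[0]] = 0
                    for i in range(1, nsub):
                        if new_groups[order[i]] != new_groups[order[i - 1]]:
                            label += 1
                        groups[order[i]] = label
                    e = num / denom
                    d = abs(pos_cm[m] - pos_cm[core])
                    lo_e = e if e > cutoff else cutoff
                    hi_e = prev_e if prev_e > cutoff else cutoff
                    integral += 0.5 * (lo_e + hi_e - 2 * cutoff) * (d - prev_d)
                    prev_e = e
                    prev_d = d
                    if e < cutoff:
                        break
            if not good:
                break
            if pa == 0:
                out0[core] = integral
            if pa == passes - 1:
                out1[core] = integral
        if good:
            ok[core] = 1
    return out0, out1, ok


def _standardize_bins(raw, freq, ok, n_bins):
    """Mean-0/SD-1 within equal-width frequency bins; small bins merged."""
    z = np.full_like(raw, np.nan)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_id = np.clip(np.digitize(freq, edges) - 1, 0, n_bins - 1)
    # merge bins with <10 usable markers into their left neighbor
    order = list(range(n_bins))
    merged = {}
    counts = np.array([(ok & (bin_id == b)).sum() for b in order])
    group = 0
    groups = np.zeros(n_bins, dtype=int)
    acc = 0
    for b in order:
        groups[b] = group
        acc += counts[b]
        if acc >= 10:
            group += 1
            acc = 0
    if acc > 0 and group > 0:  # leftover tail joins the previous group
        groups[groups == group] = group - 1
    gid = groups[bin_id]
    for g in np.unique(gid):
        sel = ok & (gid == g)
        if sel.sum() < 2:
            continue
        mu, sd = raw[sel].mean(), raw[sel].std()
        if sd > 0:
            z[sel] = (raw[sel] - mu) / sd
    return z


def ihs(panel: HaplotypePanel, pop: str | None = None,
        polarized: bool = False, bins: int = 20, cutoff: float = 0.05,
        max_gap_cM: float = 0.5) -> ScanScores:
    """iHS scan: ln(iHH_b / iHH_a) standardized within frequency bins.

    Unpolarized mode (the default) fixes each allele's role by the panel
    coding (allele_b is the 'derived-role' allele) and bins on the
    allele_b frequency; per-bin standardization removes the frequency
    dependence either way. Markers whose EHH never decays below the
    cutoff before a chromosome end are flagged undefined and excluded
    from the bins. p_iHS = -log10(1 - 2|Phi(iHS) - 0.5|).
    """
    haps = panel.pop_haplotypes(pop) if pop else panel.haplotypes
    pos = panel.markers.genetic_pos_cM.astype(float)
    ihh0 = np.zeros(panel.n_markers)
    ihh1 = np.zeros(panel.n_markers)
    okv = np.zeros(panel.n_markers, dtype=bool)
    for c in np.unique(panel.markers.chromosome):
        sel = np.flatnonzero(panel.markers.chromosome == c)
        o0, o1, ok = _site_scan_all(haps[:, sel], pos[sel], cutoff,
                                    max_gap_cM, True)
        ihh0[sel], ihh1[sel], okv[sel] = o0, o1, ok.astype(bool)
    freq = haps.mean(axis=0)
    usable = okv & (ihh0 > 0) & (ihh1 > 0)
    raw = np.full(panel.n_markers, np.nan)
    raw[usable] = np.log(ihh1[usable] / ihh0[usable])
    z = _standardize_bins(raw, freq, usable, bins)
    with np.errstate(invalid="ignore"):
        p = -np.log10(np.maximum(1.0 - 2.0 * np.abs(norm.cdf(z) - 0.5),
                                 1e-300))
    p = np.where(np.isfinite(z), p, np.nan)
    table = pd.DataFrame({
        "marker_id": panel.markers.marker_id,
        "chromosome": panel.markers.chromosome,
        "position_bp": panel.markers.position_bp,
        "freq_b": freq, "ihh_a": ihh0, "ihh_b": ihh1,
        "ihs_raw": raw, "ihs": z, "p_ihs": p, "defined": usable})
    return ScanScores(table, "ihs")


def _ies(panel: HaplotypePanel, pop, cutoff, max_gap_cM):
    haps = panel.pop_haplotypes(pop) if pop else panel.haplotypes
    pos = panel.markers.genetic_pos_cM.astype(float)
    ies = np.zeros(panel.n_markers)
    okv = np.zeros(panel.n_markers, dtype=bool)
    for c in np.unique(panel.markers.chromosome):
        sel = np.flatnonzero(panel.markers.chromosome == c)
        _, o1, ok = _site_scan_all(haps[:, sel], pos[sel], cutoff,
                                   max_gap_cM, False)
        ies[sel], okv[sel] = o1, ok.astype(bool)
    return ies, okv


def rsb(panel1: HaplotypePanel, panel2: HaplotypePanel,
        pop1: str | None = None, pop2: str | None = None,
        cutoff: float = 0.05, max_gap_cM: float = 0.5,
        median_center: bool = False) -> ScanScores:
    """Rsb scan: ln(iES_1 / iES_2), standardized genome-wide.

    Both panels must share the marker map. Large positive Rsb means longer
    haplotype homozygosity in population 1, so the one-sided transform
    -log10(1 - Phi(Rsb)) (column ``p_rsb_pop1``) flags sweeps driven by
    population 1 and -log10(Phi(Rsb)) (``p_rsb_pop2``) the mirrored tail.
    """
    if panel1.n_markers != panel2.n_markers or np.any(
            panel1.markers.position_bp != panel2.markers.position_bp):
        raise ValueError("panels must share the marker map")
    ies1, ok1 = _ies(panel1, pop1, cutoff, max_gap_cM)
    ies2, ok2 = _ies(panel2, pop2, cutoff, max_gap_cM)
    usable = ok1 & ok2 & (ies1 > 0) & (ies2 > 0)
    raw = np.full(panel1.n_markers, np.nan)
    raw[usable] = np.log(ies1[usable] / ies2[usable])
    vals = raw[usable]
    center = np.median(vals) if median_center else vals.mean()
    sd = vals.std()
    z = (raw - center) / sd if sd > 0 else np.full_like(raw, np.nan)
    with np.errstate(invalid="ignore"):
        cdf = norm.cdf(z)
        p_left = -np.log10(np.maximum(cdf, 1e-300))
        p_right = -np.log10(np.maximum(1.0 - cdf, 1e-300))
    table = pd.DataFrame({
        "marker_id": panel1.markers.marker_id,
        "chromosome": panel1.markers.chromosome,
        "position_bp": panel1.markers.position_bp,
        "ies_1": ies1, "ies_2": ies2, "rsb_raw": raw, "rsb": z,
        "p_rsb_pop1": p_right, "p_rsb_pop2": p_left, "defined": usable})
    return ScanScores(table, "rsb")


# ---------------------------------------------------------------------------
# Gene-level candidate calling and enrichment
# ---------------------------------------------------------------------------

def call_candidate_genes(scores: ScanScores, genes: GeneTable,
                         score_column: str | None = None,
                         flank_bp: int = 15000, threshold: float = 4.0,
                         min_snps: int = 2) -> pd.DataFrame:
    """Genes with >= ``min_snps`` assigned SNPs above ``threshold``.

    A SNP is assigned to every gene whose [start - flank, end + flank]
    interval (1-based inclusive) contains it. Returns a DataFrame of
    candidates (gene, n_snps, n_extreme, best_score) plus per-gene counts
    for non-candidates with at least one assigned SNP.
    """
    if score_column is None:
        score_column = "p_ihs" if scores.statistic == "ihs" else "p_rsb_pop1"
    t = scores.table
    snp_chrom = t["chromosome"].to_numpy()
    snp_pos = t["position_bp"].to_numpy()
    snp_score = t[score_column].to_numpy()
    rows = []
    for _, g in genes.table.iterrows():
        lo, hi = g.start_bp - flank_bp, g.end_bp + flank_bp
        sel = (snp_chrom == g.chromosome) & (snp_pos >= lo) & (snp_pos <= hi)
        n = int(sel.sum())
        if n == 0:
            continue
        sc = snp_score[sel]
        finite = np.isfinite(sc)
        n_extreme = int((sc[finite] > threshold).sum())
        best = float(np.nanmax(sc)) if finite.any() else np.nan
        rows.append((g.gene, n, n_extreme, best, n_extreme >= min_snps))
    out = pd.DataFrame(rows, columns=["gene", "n_snps", "n_extreme",
                                      "best_score", "candidate"])
    return out


def geneset_enrichment(candidates, annotation: pd.DataFrame,
                       reference) -> pd.DataFrame:
    """Right-tailed Fisher exact (hypergeometric) per category.

    ``annotation`` maps genes to categories (columns 'gene', 'category');
    ``reference`` is the gene universe and must contain every candidate.
    Returns per-category p-values sorted ascending, with a significance
    flag at p < 0.05.
    """
    reference = set(reference)
    candidates = set(candidates)
    if not reference:
        raise ValueError("empty gene universe")
    if not candidates <= reference:
        raise ValueError("candidates must be a subset of the reference")
    M, N = len(reference), len(candidates)
    rows = []
    for cat, sub in annotation.groupby("category"):
        in_cat = set(sub["gene"]) & reference
        n = len(in_cat)
        k = len(in_cat & candidates)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append((cat, n, k, p))
    out = pd.DataFrame(rows, columns=["category", "n_in_category",
                                      "n_candidates_in_category", "p_value"])
    out = out.sort_values("p_value", kind="mergesort", ignore_index=True)
    out["significant"] = out["p_value"] < 0.05
    return out
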