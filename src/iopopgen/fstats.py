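"""Allele-frequency-based estimators with block-jackknife standard errors.

Implements within-population heterozygosity, the Weir–Cockerham (ANOVA)
FST, population-specific FST by allele matching, and the f2/f3/f4 family
with their sampling-bias corrections. All multi-marker statistics are
ratio-of-sums averages; standard errors come from a weighted leave-one-
block-out jackknife over blocks of consecutive SNPs (default 5,000) that
never span chromosomes.

Estimator definitions (p = frequency of the counted allele, a = observed
allele count per population per marker):

* unbiased heterozygosity        h = 2 p (1-p) a/(a-1)
* f2(A,B)   = (pA-pB)^2 - pA(1-pA)/(aA-1) - pB(1-pB)/(aB-1)
* f3(A;B,C) = (pA-pB)(pA-pC) - pA(1-pA)/(aA-1)
* f4(A,B;C,D) = (pA-pB)(pC-pD)

A significantly negative f3(A;B,C) demonstrates that A is admixed between
sources related to B and C; the Z-score thresholds follow the usual
one-sided normal quantiles (-1.65 at 95%, -2.33 at 99%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from iopopgen.genotype_io import MISSING, GenotypePanel, MarkerMap

__all__ = [
    "PopFrequencies", "FStatEstimate", "BlockPartition",
    "compute_frequencies", "heterozygosity", "fst_anova", "fst_popspecific",
    "f_statistics", "block_jackknife", "admixture_test_f3",
    "ascertain_markers",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PopFrequencies:
    """Per-population allele_b frequencies and observed allele counts.

    ``p[k, m]`` is the allele_b frequency of population ``k`` at marker
    ``m`` (NaN where no individual is called); ``a[k, m]`` is the observed
    allele count (2 x called individuals).
    """

    populations: list
    p: np.ndarray
    a: np.ndarray
    markers: MarkerMap | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.p.shape != self.a.shape:
            raise ValueError("p and a must share a shape")
        if len(self.populations) != self.p.shape[0]:
            raise ValueError("population list length mismatch")

    @property
    def n_markers(self) -> int:
        return self.p.shape[1]

    def index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in frequency table") from None

    def defined(self, pop: str) -> np.ndarray:
        k = self.index(pop)
        return self.a[k] > 0


@dataclass
class FStatEstimate:
    """One f-type statistic with its block-jackknife standard error."""

    kind: str
    populations: tuple
    estimate: float
    jackknife_se: float
    n_blocks: int

    @property
    def zscore(self) -> float:
        if self.jackknife_se > 0:
            return self.estimate / self.jackknife_se
        return np.nan

    def __repr__(self) -> str:  # compact table-friendly form
        return (f"{self.kind}{self.populations}: {self.estimate:.6g} "
                f"+/- {self.jackknife_se:.3g} (Z={self.zscore:.2f}, "
                f"B={self.n_blocks})")


@dataclass
class BlockPartition:
    """Assignment of markers to contiguous equal-SNP-count blocks.

    ``block[m]`` is the 0-based block id of marker ``m`` or -1 for trailing
    markers (within a chromosome) that cannot fill a complete block.
    """

    block: np.ndarray
    n_blocks: int
    block_snps: int

    @classmethod
    def from_map(cls, markers: MarkerMap, block_snps: int = 5000,
                 mask: np.ndarray | None = None) -> "BlockPartition":
        """Partition consecutive SNPs into blocks that never span chromosomes.

        ``mask`` restricts the partition to a marker subset (e.g. after
        ascertainment); unmasked markers get block -1.
        """
        n = len(markers)
        block = np.full(n, -1, dtype=np.int64)
        nxt = 0
        use = np.ones(n, bool) if mask is None else np.asarray(mask, bool)
        for c in np.unique(markers.chromosome):
            idx = np.flatnonzero((markers.chromosome == c) & use)
            n_full = len(idx) // block_snps
            for b in range(n_full):
                block[idx[b * block_snps:(b + 1) * block_snps]] = nxt
                nxt += 1
        return cls(block, nxt, block_snps)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def compute_frequencies(panel: GenotypePanel) -> PopFrequencies:
    """Per-population allele_b frequency p and allele count a per marker."""
    pops = panel.populations
    n_pop, n_mrk = len(pops), panel.n_markers
    p = np.full((n_pop, n_mrk), np.nan)
    a = np.zeros((n_pop, n_mrk))
    g = panel.genotypes
    called = g != MISSING
    for k, pop in enumerate(pops):
        idx = panel.pop_index(pop)
        cal = called[idx]
        tot = 2.0 * cal.sum(axis=0)
        cnt = np.where(cal, g[idx], 0).sum(axis=0)
        a[k] = tot
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(tot > 0, cnt / np.maximum(tot, 1), np.nan)
    return PopFrequencies(list(pops), p, a, panel.markers)


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------

def block_jackknife(num: np.ndarray, den: np.ndarray,
                    partition: BlockPartition):
    """Estimate a ratio-of-sums statistic and its block-jackknife SE.

    ``num``/``den`` are per-marker numerator and denominator contributions
    (NaN entries, e.g. undefined markers, are excluded). The estimate is
    sum(num)/sum(den); the standard error is the weighted delete-one-block
    jackknife (Busing-type), with weights proportional to each block's
    contributing marker count. With equal block sizes this reduces to the
    classical delete-one jackknife.
    """
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    ok = np.isfinite(num) & np.isfinite(den) & (partition.block >= 0)
    B = partition.n_blocks
    if B < 2:
        raise ValueError("need at least 2 jackknife blocks")
    bl = partition.block[ok]
    m_j = np.bincount(bl, minlength=B).astype(float)
    num_j = np.bincount(bl, weights=num[ok], minlength=B)
    den_j = np.bincount(bl, weights=den[ok], minlength=B)
    live = m_j > 0
    if live.sum() < 2:
        raise ValueError("fewer than 2 blocks hold defined markers")
    m_j, num_j, den_j = m_j[live], num_j[live], den_j[live]
    B = len(m_j)
    tot_num, tot_den = num_j.sum(), den_j.sum()
    if tot_den == 0:
        raise ZeroDivisionError("statistic denominator sums to zero")
    theta = tot_num / tot_den
    theta_del = (tot_num - num_j) / (tot_den - den_j)
    n = m_j.sum()
    h = n / m_j
    theta_J = B * theta - np.sum((1.0 - m_j / n) * theta_del)
    tau = h * theta - (h - 1.0) * theta_del  # weighted pseudo-values
    var = np.sum((tau - theta_J) ** 2 / (h - 1.0)) / B
    return float(theta), float(np.sqrt(max(var, 0.0))), B


def _estimate(kind, pops, num, den, partition) -> FStatEstimate:
    est, se, B = block_jackknife(num, den, partition)
    return FStatEstimate(kind, tuple(pops), est, se, B)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity(freqs: PopFrequencies, pop: str,
                   partition: BlockPartition) -> FStatEstimate:
    """Unbiased within-population heterozygosity, averaged over markers."""
    k = freqs.index(pop)
    p, a = freqs.p[k], freqs.a[k]
    ok = a >= 2
    if not ok.any():
        raise ValueError(f"no defined markers for population {pop!r}")
    h = np.where(ok, 2.0 * p * (1.0 - p) * a / np.maximum(a - 1.0, 1.0),
                 np.nan)
    return _estimate("het", (pop,), h, np.where(ok, 1.0, np.nan), partition)


# ---------------------------------------------------------------------------
# Weir–Cockerham (ANOVA) FST
# ---------------------------------------------------------------------------

def _wc_components(p: np.ndarray, a: np.ndarray):
    """Per-marker WC numerator/denominator from an allele-level ANOVA.

    p, a: (n_pop, n_markers); markers need >= 2 populations with a >= 2.
    Returns (num, den) with NaN where undefined.
    """
    ok = a >= 2
    r = ok.sum(axis=0).astype(float)
    aa = np.where(ok, a, 0.0)
    pp = np.where(ok, p, 0.0)
    N = aa.sum(axis=0)
    valid = r >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(N > 0, (aa * pp).sum(axis=0) / np.maximum(N, 1), np.nan)
        nc = (N - (aa ** 2).sum(axis=0) / np.maximum(N, 1)) / np.maximum(r - 1, 1)
        msp = (aa * (pp - pbar) ** 2).sum(axis=0) / np.maximum(r - 1, 1)
        msg = (aa * pp * (1 - pp)).sum(axis=0) / np.maximum(N - r, 1)
        num = msp - msg
        den = msp + (nc - 1.0) * msg
    num = np.where(valid & (N - r > 0), num, np.nan)
    den = np.where(valid & (N - r > 0), den, np.nan)
    return num, den


def fst_anova(freqs: PopFrequencies, pops, partition: BlockPartition,
              pairwise: bool = False):
    """Weir–Cockerham variance-components FST over a population set.

    With ``pairwise=True`` returns a dict of per-pair estimates; otherwise
    the overall multi-population estimate. Multi-marker averaging is the
    ratio of summed numerator and denominator components.
    """
    pops = list(pops)
    if len(pops) < 2:
        raise ValueError("FST needs at least 2 populations")
    if pairwise:
        out = {}
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                pair = (pops[i], pops[j])
                out[pair] = fst_anova(freqs, pair, partition)
        return out
    ix = [freqs.index(q) for q in pops]
    num, den = _wc_components(freqs.p[ix], freqs.a[ix])
    return _estimate("fst_pairwise" if len(pops) == 2 else "fst_overall",
                     pops, num, den, partition)


def fst_popspecific(freqs: PopFrequencies, partition: BlockPartition):
    """Population-specific FST by allele matching.

    F_i = (M_ii - M_B) / (1 - M_B) as a ratio of sums over markers, with
    M_ii the bias-corrected within-population allele-matching proportion
    (1 minus unbiased heterozygosity) and M_B the mean between-population
    matching over all ordered pairs involving any two distinct populations.
    """
    n_pop = len(freqs.populations)
    if n_pop < 2:
        raise ValueError("population-specific FST needs >= 2 populations")
    p, a = freqs.p, freqs.a
    ok = a >= 2
    m_within = np.where(ok, 1.0 - 2.0 * p * (1.0 - p) * a
                        / np.maximum(a - 1.0, 1.0), np.nan)
    # between-population matching for unordered pairs
    pair_m = []
    for i in range(n_pop):
        for j in range(i + 1, n_pop):
            both = ok[i] & ok[j]
            mij = np.where(both, p[i] * p[j] + (1 - p[i]) * (1 - p[j]), np.nan)
            pair_m.append(mij)
    m_between = np.nanmean(np.array(pair_m), axis=0)
    out = {}
    for i, pop in enumerate(freqs.populations):
        num = m_within[i] - m_between
        den = 1.0 - m_between
        est, se, B = block_jackknife(num, den, partition)
        out[pop] = FStatEstimate("fst_popspecific", (pop,), est, se, B)
    return out


# ---------------------------------------------------------------------------
# f2 / f3 / f4
# ---------------------------------------------------------------------------

def _f_num(freqs: PopFrequencies, pops):
    """Per-marker f-statistic values with sampling corrections applied."""
    ix = [freqs.index(q) for q in pops]
    p = freqs.p[ix]
    a = freqs.a[ix]
    ok = np.all(a >= 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = p * (1 - p) / np.maximum(a - 1.0, 1.0)
        if len(pops) == 2:
            val = (p[0] - p[1]) ** 2 - corr[0] - corr[1]
        elif len(pops) == 3:
            val = (p[0] - p[1]) * (p[0] - p[2]) - corr[0]
        elif len(pops) == 4:
            val = (p[0] - p[1]) * (p[2] - p[3])
        else:
            raise ValueError("f-statistics take 2, 3 or 4 populations")
    return np.where(ok, val, np.nan), ok


def f_statistics(freqs: PopFrequencies, requests,
                 partition: BlockPartition):
    """Estimate f2/f3/f4 for a list of population tuples.

    Per-marker values are averaged with equal weights over markers where
    every tuple member has >= 1 called individual (complete-tuple
    analysis); jackknife SE/Z per the block partition.
    """
    out = []
    kind_by_arity = {2: "f2", 3: "f3", 4: "f4"}
    for pops in requests:
        pops = tuple(pops)
        for q in pops:
            freqs.index(q)  # raises on unknown population
        num, ok = _f_num(freqs, pops)
        out.append(_estimate(kind_by_arity[len(pops)], pops, num,
                             np.where(ok, 1.0, np.nan), partition))
    return out


def admixture_test_f3(estimates, alpha_level: float = 0.99):
    """Flag f3 triplets with significantly negative Z as admixed.

    ``alpha_level`` 0.95 flags Z < -1.65; 0.99 flags Z < -2.33 (strict
    inequalities, matching one-sided normal quantiles).
    """
    thresholds = {0.95: -1.65, 0.99: -2.33}
    if alpha_level not in thresholds:
        raise ValueError("alpha_level must be 0.95 or 0.99")
    thr = thresholds[alpha_level]
    flagged = []
    for est in estimates:
        if est.kind != "f3":
            raise ValueError("admixture test applies to f3 estimates")
        if np.isfinite(est.zscore) and est.zscore < thr:
            flagged.append(est)
    return flagged


def ascertain_markers(freqs: PopFrequencies, groups: dict,
                      maf: float = 0.05) -> np.ndarray:
    """Keep markers polymorphic (pooled MAF > maf) within every named group.

    ``groups`` maps a group name to a list of population labels; the pooled
    frequency is the allele-count-weighted mean over the group's
    populations. Returns a boolean marker mask.
    """
    keep = np.ones(freqs.n_markers, dtype=bool)
    for name, pops in groups.items():
        if not pops:
            raise ValueError(f"ascertainment group {name!r} is empty")
        ix = [freqs.index(q) for q in pops]
        a = freqs.a[ix]
        p = np.where(a > 0, freqs.p[ix], 0.0)
        tot = a.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = np.where(tot > 0, (a * p).sum(axis=0) / np.maximum(tot, 1),
                              np.nan)
        grp_maf = np.minimum(pooled, 1 - pooled)
        keep &= grp_maf > maf
    return keep
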