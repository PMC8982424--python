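"""Genotype panel I/O, marker QC and genetic-map handling.

Panels are diploid, biallelic, autosomal SNP genotypes stored as counts of
``allele_b`` (0/1/2, missing = -1) in an individuals x markers matrix, with
a marker map carrying physical and genetic positions. Readers accept
PLINK-style text (.ped/.map) and plain-text VCF 4.x; the writer emits
PLINK-style text. QC applies, in order: individual call rate, overall and
per-population SNP call rate, global MAF, and a within-population exact
Hardy–Weinberg test (full enumeration over heterozygote counts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("iopopgen")

MISSING = -1  # internal sentinel for a missing diploid genotype


class PanelFormatError(ValueError):
    """Raised when an input genotype file violates its declared format."""


class EmptyPanelError(ValueError):
    """Raised when a filter removes every marker (or individual)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Per-marker map: identifiers, physical and genetic coordinates, alleles.

    Markers are sorted by (chromosome, position_bp), strictly increasing
    within a chromosome; coordinates are 1-based. ``genetic_pos_cM`` defaults
    to physical position at 1 cM/Mb and must be non-decreasing within a
    chromosome. ``allele_b`` is the counted allele.
    """

    marker_id: np.ndarray      # object/str
    chromosome: np.ndarray     # int, 1..29
    position_bp: np.ndarray    # int, 1-based
    genetic_pos_cM: np.ndarray  # float >= 0
    allele_a: np.ndarray       # single-character labels
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.genetic_pos_cM = np.asarray(self.genetic_pos_cM, dtype=float)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.marker_id)
        for name in ("chromosome", "position_bp", "genetic_pos_cM",
                     "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name} has wrong length")
        order = np.lexsort((self.position_bp, self.chromosome))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("markers must be sorted by (chromosome, position)")
        for c in np.unique(self.chromosome):
            sel = self.chromosome == c
            pos = self.position_bp[sel]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}")
            cm = self.genetic_pos_cM[sel]
            if np.any(np.diff(cm) < 0):
                raise ValueError(
                    f"genetic positions decreasing on chromosome {c}")
        if np.any(self.genetic_pos_cM < 0):
            raise ValueError("genetic_pos_cM must be >= 0")

    def __len__(self) -> int:
        return len(self.marker_id)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.marker_id[index], self.chromosome[index],
            self.position_bp[index], self.genetic_pos_cM[index],
            self.allele_a[index], self.allele_b[index])


@dataclass
class GenotypePanel:
    """Diploid genotype matrix plus map, labels and sampling years.

    ``genotypes[i, m]`` counts copies of ``allele_b`` for individual ``i``
    at marker ``m`` (0/1/2, -1 missing). Every individual carries a
    population label; ``sampling_year`` maps population -> year and may be
    empty.
    """

    markers: MarkerMap
    individual_id: list
    population: list
    genotypes: np.ndarray
    sampling_year: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_mrk = self.genotypes.shape
        if n_ind != len(self.individual_id) or n_ind != len(self.population):
            raise ValueError("genotype matrix row count != individual count")
        if n_mrk != len(self.markers):
            raise ValueError("genotype matrix column count != marker count")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,missing}")
        if any(not p for p in self.population):
            raise ValueError("every individual needs a population label")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list:
        seen: dict = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def pop_index(self, pop: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.population) if p == pop])
        if idx.size == 0:
            raise KeyError(f"no individuals in population {pop!r}")
        return idx

    def subset_markers(self, index: np.ndarray) -> "GenotypePanel":
        return replace(self, markers=self.markers.subset(index),
                       genotypes=self.genotypes[:, index])

    def subset_individuals(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return replace(
            self,
            individual_id=[self.individual_id[i] for i in index],
            population=[self.population[i] for i in index],
            genotypes=self.genotypes[index, :])


@dataclass
class AlignmentHitTable:
    """Per-marker alignment hits: (chromosome, position_bp, score) tuples.

    ``hits[marker_id]`` is a list of hits; an absent or empty list means the
    marker's probe sequence found no placement on the assembly.
    """

    hits: dict

    def n_hits(self, marker_id: str) -> int:
        return len(self.hits.get(marker_id, ()))


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def _finalize_alleles(a_list, b_list, n_markers):
    a = np.array([x if x is not None else "A" for x in a_list], dtype=object)
    b = np.array([x if x is not None else "B" for x in b_list], dtype=object)
    # monomorphic columns may never reveal a second allele; keep placeholder
    return a[:n_markers], b[:n_markers]


def _read_plink(prefix: str) -> GenotypePanel:
    """Read a .ped/.map pair. Family ID is taken as the population label."""
    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    mids, chroms, cms, bps = [], [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PanelFormatError(
                    f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                chroms.append(int(parts[0]))
                cms.append(float(parts[2]))
                bps.append(int(parts[3]))
            except ValueError as exc:
                raise PanelFormatError(f"{map_path}:{ln}: {exc}") from None
            mids.append(parts[1])
    n_mrk = len(mids)
    cms = np.asarray(cms)
    bps = np.asarray(bps)
    if np.all(cms == 0):
        cms = bps * 1e-6  # default 1 cM/Mb
    ids, pops, rows = [], [], []
    allele_a: list = [None] * n_mrk
    allele_b: list = [None] * n_mrk
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_mrk:
                raise PanelFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_mrk} fields, "
                    f"got {len(parts)}")
            pops.append(parts[0])
            ids.append(parts[1])
            row = np.empty(n_mrk, dtype=np.int8)
            al = parts[6::2]
            ar = parts[7::2]
            for m in range(n_mrk):
                g = 0
                ok = True
                for a in (al[m], ar[m]):
                    if a in ("0", ".", "-9", "N"):
                        ok = False
                        break
                    if allele_a[m] is None:
                        allele_a[m] = a
                    if a != allele_a[m]:
                        if allele_b[m] is None:
                            allele_b[m] = a
                        if a != allele_b[m]:
                            raise PanelFormatError(
                                f"{ped_path}:{ln}: marker {mids[m]} has >2 "
                                f"alleles")
                        g += 1
                row[m] = g if ok else MISSING
            rows.append(row)
    aa, bb = _finalize_alleles(allele_a, allele_b, n_mrk)
    geno = np.array(rows, dtype=np.int8)
    # honor an allele-coding sidecar when present: .ped alone cannot say
    # which allele is counted, and round-trips must preserve the coding
    import os
    ref_path = f"{prefix}.ref"
    if os.path.exists(ref_path):
        ref = {}
        with open(ref_path) as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    ref[parts[0]] = (parts[1], parts[2])
        for m, mid in enumerate(mids):
            if mid not in ref:
                continue
            ra, rb = ref[mid]
            if aa[m] == rb or bb[m] == ra:  # coding swapped vs sidecar
                col = geno[:, m]
                geno[:, m] = np.where(col == MISSING, MISSING, 2 - col)
            aa[m], bb[m] = ra, rb
    markers = MarkerMap(np.array(mids, dtype=object), chroms, bps, cms, aa, bb)
    return GenotypePanel(markers, ids, pops, geno)


def _read_vcf(path: str, popmap: dict | None) -> GenotypePanel:
    """Read an uncompressed VCF 4.x; non-biallelic records are skipped."""
    mids, chroms, bps, ref, alt, rows = [], [], [], [], [], []
    samples: list = []
    n_skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise PanelFormatError(f"{path}:{ln}: no sample columns")
                samples = cols[9:]
                continue
            if not samples:
                raise PanelFormatError(f"{path}:{ln}: data before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise PanelFormatError(
                    f"{path}:{ln}: expected {9 + len(samples)} columns, "
                    f"got {len(cols)}")
            if "," in cols[4] or len(cols[3]) != 1 or len(cols[4]) != 1:
                n_skipped += 1
                continue
            try:
                chrom = int(cols[0].removeprefix("chr"))
                pos = int(cols[1])
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{ln}: {exc}") from None
            fmt = cols[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                raise PanelFormatError(f"{path}:{ln}: no GT field") from None
            row = np.empty(len(samples), dtype=np.int8)
            for s, cell in enumerate(cols[9:]):
                gt = cell.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    row[s] = MISSING
                else:
                    row[s] = sum(int(a) for a in gt.split("/"))
            mids.append(cols[2] if cols[2] != "." else f"{chrom}:{pos}")
            chroms.append(chrom)
            bps.append(pos)
            ref.append(cols[3])
            alt.append(cols[4])
            rows.append(row)
    if n_skipped:
        logger.warning("skipped %d non-biallelic VCF record(s)", n_skipped)
        warnings.warn(f"skipped {n_skipped} non-biallelic VCF record(s)",
                      stacklevel=3)
    bps = np.asarray(bps)
    markers = MarkerMap(np.array(mids, dtype=object), chroms, bps, bps * 1e-6,
                        np.array(ref, dtype=object), np.array(alt, dtype=object))
    geno = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    popmap = popmap or {}
    pops = [popmap.get(s, "POP1") for s in samples]
    return GenotypePanel(markers, samples, pops, geno)


def read_panel(path: str, format: str = "plink-text",
               popmap: dict | None = None,
               sampling_year: dict | None = None) -> GenotypePanel:
    """Read a genotype panel from PLINK text (``path`` = prefix) or VCF.

    Parameters
    ----------
    path
        File prefix (plink-text: ``path.ped`` + ``path.map``) or VCF path.
    format
        ``"plink-text"`` or ``"vcf"``.
    popmap
        Optional sample -> population mapping (VCF has no population field;
        PLINK uses the family-ID column and ignores this).
    sampling_year
        Optional population -> calendar-year mapping attached to the panel.
    """
    if format == "plink-text":
        panel = _read_plink(path)
    elif format == "vcf":
        panel = _read_vcf(path, popmap)
    else:
        raise ValueError(f"unknown format {format!r}")
    if sampling_year:
        panel.sampling_year = dict(sampling_year)
    return panel


def write_panel(panel: GenotypePanel, prefix: str) -> None:
    """Write PLINK-style text (.ped/.map); inverse of plink-text reading."""
    m = panel.markers
    with open(f"{prefix}.map", "w") as fh:
        for i in range(len(m)):
            fh.write(f"{m.chromosome[i]}\t{m.marker_id[i]}\t"
                     f"{m.genetic_pos_cM[i]:.8f}\t{m.position_bp[i]}\n")
    with open(f"{prefix}.ref", "w") as fh:
        for i in range(len(m)):
            fh.write(f"{m.marker_id[i]}\t{m.allele_a[i]}\t{m.allele_b[i]}\n")
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(panel.n_individuals):
            fields = [panel.population[i], str(panel.individual_id[i]),
                      "0", "0", "0", "-9"]
            g = panel.genotypes[i]
            for j in range(len(m)):
                fields.extend(_ped_alleles(g[j], m.allele_a[j],
                                           m.allele_b[j]))
            fh.write(" ".join(fields) + "\n")


def _ped_alleles(g: int, a: str, b: str) -> tuple:
    if g == MISSING:
        return ("0", "0")
    return ((a, a), (a, b), (b, b))[g]


# ---------------------------------------------------------------------------
# Multi-hit marker filter
# ---------------------------------------------------------------------------

def filter_multihit_markers(markers, hits: AlignmentHitTable,
                            max_hits: int = 9):
    """Resolve marker positions from an alignment-hit table.

    Markers whose probe sequence has no hit, or more than ``max_hits`` hits,
    are dropped; single-hit markers keep that position; markers with
    2..``max_hits`` hits take the highest-scoring hit's position. Ties on
    the top score break deterministically to the lowest chromosome, then
    lowest position (with a logged warning).

    Parameters
    ----------
    markers
        Iterable of marker identifiers (every one must appear in ``hits``).

    Returns
    -------
    dict
        marker_id -> (chromosome, position_bp) for the kept markers, in
        input order.
    """
    kept = {}
    for mid in markers:
        if mid not in hits.hits:
            raise KeyError(f"marker {mid!r} absent from the hit table")
        hl = hits.hits[mid]
        n = len(hl)
        if n == 0 or n > max_hits:
            continue
        best = sorted(hl, key=lambda h: (-h[2], h[0], h[1]))
        if len(best) > 1 and best[0][2] == best[1][2]:
            logger.warning("marker %s: tied top alignment score; keeping "
                           "chr%d:%d", mid, best[0][0], best[0][1])
        kept[mid] = (best[0][0], best[0][1])
    return kept


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy–Weinberg test for one biallelic SNP.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count of matching parity and sums the probabilities of all
    configurations no more likely than the observed one (the standard exact
    formulation). Returns the p-value.
    """
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        return 1.0
    n_b = 2 * n_hom_b + n_het  # minor-or-major; symmetric
    n_a = 2 * n - n_b
    rare = min(n_a, n_b)
    # log-probability of each heterozygote count, up to a shared constant:
    # P(het=h) prop 2^h * n! / (na!nb!... ) — use gammaln for stability
    from scipy.special import gammaln

    hs = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hs) // 2
    logp = (hs * np.log(2.0) - gammaln(hom_r + 1) - gammaln(hs + 1)
            - gammaln(n - hom_r - hs + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hs == n_het]
    if obs.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(panel: GenotypePanel, ind_call: float = 0.90,
             snp_call_overall: float = 0.90, snp_call_per_pop: float = 0.75,
             maf_min: float = 0.01, hwe_p_min: float = 1e-3):
    """Apply the marker/individual QC cascade; returns (panel, report).

    Order of application: individuals below ``ind_call`` call rate are
    removed first; then SNPs failing the overall call rate, then any
    per-population call rate, then global MAF (pooled over retained
    individuals), then the within-population exact Hardy–Weinberg test
    (failed if p < ``hwe_p_min`` in at least one population). The report is
    a DataFrame of counts removed per criterion in application order.
    """
    if panel.n_markers == 0 or panel.n_individuals == 0:
        raise EmptyPanelError("cannot QC an empty panel")
    g = panel.genotypes
    called = g != MISSING

    ind_rate = called.mean(axis=1)
    keep_ind = ind_rate >= ind_call
    n_ind_removed = int((~keep_ind).sum())
    panel = panel.subset_individuals(np.flatnonzero(keep_ind))
    g = panel.genotypes
    called = g != MISSING
    if panel.n_individuals == 0:
        raise EmptyPanelError("all individuals removed by call-rate filter")

    report_rows = [("individual_call_rate", n_ind_removed)]
    keep = np.ones(panel.n_markers, dtype=bool)

    # overall SNP call rate
    snp_rate = called.mean(axis=0)
    fail = keep & (snp_rate < snp_call_overall)
    report_rows.append(("snp_call_rate_overall", int(fail.sum())))
    keep &= ~fail

    # per-population SNP call rate
    fail = np.zeros_like(keep)
    for pop in panel.populations:
        idx = panel.pop_index(pop)
        rate = called[idx].mean(axis=0)
        fail |= rate < snp_call_per_pop
    fail &= keep
    report_rows.append(("snp_call_rate_per_pop", int(fail.sum())))
    keep &= ~fail

    # global MAF over all retained individuals pooled
    nb = np.where(called, g, 0).sum(axis=0)
    tot = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, nb / np.maximum(tot, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    fail = keep & ~(maf >= maf_min)
    report_rows.append(("maf", int(fail.sum())))
    keep &= ~fail

    # HWE exact test within each population
    fail = np.zeros_like(keep)
    cand = np.flatnonzero(keep)
    for pop in panel.populations:
        idx = panel.pop_index(pop)
        sub = g[idx]
        for m in cand:
            if fail[m]:
                continue
            col = sub[:, m]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            counts = np.bincount(col, minlength=3)
            if hwe_exact_test(*counts) < hwe_p_min:
                fail[m] = True
    report_rows.append(("hwe_exact", int(fail.sum())))
    keep &= ~fail

    if not keep.any():
        raise EmptyPanelError("QC removed every marker")
    report = pd.DataFrame(report_rows, columns=["criterion", "n_removed"])
    return panel.subset_markers(np.flatnonzero(keep)), report


def genetic_distances(markers: MarkerMap, cM_per_Mb: float = 1.0) -> MarkerMap:
    """Fill genetic positions from physical positions at a constant ratio.

    genetic_pos_cM = position_bp * cM_per_Mb * 1e-6.
    """
    if cM_per_Mb <= 0:
        raise ValueError("cM_per_Mb must be positive")
    return MarkerMap(markers.marker_id, markers.chromosome,
                     markers.position_bp,
                     markers.position_bp * cM_per_Mb * 1e-6,
                     markers.allele_a, markers.allele_b)
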