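"""LD-based recent effective-population-size trajectories.

The expected squared dosage correlation between loci at recombination
fraction c reflects effective population size roughly 1/(2c) generations
before sampling. After a sampling-size correction, the classical inverse
relation for unphased dosage data,

    Ne(t) = (1 / r2_adj - alpha) / (4 cbar),   t = 1 / (2 cbar),
    r2_adj = r2_hat - beta / n_ind            (alpha = 2, beta = 1)

applied within recombination-fraction bins yields a point trajectory.
Confidence envelopes follow the leave-one-block-out procedure: the panel
is cut into non-overlapping blocks of consecutive SNPs (default 10,000,
never spanning chromosomes), the trajectory is re-estimated once per
omitted block, and the per-time 2.5/97.5 percentiles of those runs form a
95% envelope around their mean. Recombination fractions derive from the
cM map through the inverse Haldane function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from iopopgen.genotype_io import MISSING, GenotypePanel

__all__ = ["NeTrajectory", "ld_ne_trajectory", "jackknife_envelope",
           "harmonic_mean_ne", "to_calendar_axis", "recombination_bins"]

ALPHA_UNPHASED = 2.0   # squared-correlation offset for unphased dosages
BETA_SAMPLE = 1.0      # sampling correction: r2 - beta / n_ind


@dataclass
class NeTrajectory:
    """Ne point estimates on a generations-before-sampling grid.

    ``t`` = 1/(2 cbar) per recombination bin, strictly increasing;
    ``ne`` are point (or jackknife-mean) estimates, NaN where the bin is
    undefined; ``lo``/``hi`` bound the 95% jackknife envelope when built
    by :func:`jackknife_envelope`.
    """

    t: np.ndarray
    ne: np.ndarray
    c_bins: list
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    n_blocks: int = 0
    calendar_year: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.ne = np.asarray(self.ne, float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


def recombination_bins(n_bins: int = 30, c_min: float = 1e-4,
                       c_max: float = 0.1):
    """Default log-spaced recombination-fraction bins [c_min, c_max]."""
    edges = np.geomspace(c_min, c_max, n_bins + 1)
    return [(edges[i], edges[i + 1]) for i in range(n_bins)]


def _haldane_c(d_morgans: np.ndarray) -> np.ndarray:
    """Recombination fraction from map distance (inverse Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def ld_ne_trajectory(panel: GenotypePanel, pop: str,
                     c_bins=None) -> NeTrajectory:
    """Binned inverse-LD point estimates of historical Ne for one population.

    For every intra-chromosome marker pair whose Haldane recombination
    fraction falls in a bin, the squared dosage correlation is averaged;
    the bin's Ne then follows the inverse relation above at
    t = 1/(2 cbar). Bins with no pairs, or with adjusted r2 <= 0 or an
    implied Ne <= 0, are flagged undefined (NaN).
    """
    if c_bins is None:
        c_bins = recombination_bins()
    idx = panel.pop_index(pop)
    if len(idx) < 10:
        import logging
        logging.getLogger("iopopgen").warning(
            "population %s has %d individuals; LD-based Ne is noisy below "
            "10", pop, len(idx))
    g = panel.genotypes[idx].astype(float)
    miss = g == MISSING
    if miss.any():
        col_mean = np.where(miss, 0, g).sum(axis=0) / np.maximum(
            (~miss).sum(axis=0), 1)
        g = np.where(miss, col_mean[None, :], g)
    n_ind = g.shape[0]
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    ok_col = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        gz = np.where(ok_col[None, :], gc / np.where(sd > 0, sd, 1.0), np.nan)

    c_bins = [tuple(b) for b in c_bins]
    edges = np.array([b[0] for b in c_bins] + [c_bins[-1][1]])
    n_bins = len(c_bins)
    r2_sum = np.zeros(n_bins)
    c_sum = np.zeros(n_bins)
    n_pair = np.zeros(n_bins, dtype=np.int64)

    cm = panel.markers.genetic_pos_cM
    # maximum map distance worth scanning: invert Haldane at c_max
    c_hi = edges[-1]
    d_max_cm = -50.0 * np.log(1.0 - 2.0 * min(c_hi, 0.499999))
    for c in np.unique(panel.markers.chromosome):
        sel = np.flatnonzero(panel.markers.chromosome == c)
        pos = cm[sel]
        z = gz[:, sel]
        m = len(sel)
        hi = np.searchsorted(pos, pos + d_max_cm, side="right")
        for x in range(m - 1):
            if not np.isfinite(z[0, x]):
                continue
            y0, y1 = x + 1, hi[x]
            if y1 <= y0:
                continue
            ys = slice(y0, y1)
            cfrac = _haldane_c((pos[ys] - pos[x]) / 100.0)
            b = np.searchsorted(edges, cfrac, side="right") - 1
            okb = (b >= 0) & (b < n_bins) & np.isfinite(z[0, ys.start:ys.stop])
            if not okb.any():
                continue
            r = (z[:, x] @ z[:, ys]) / n_ind
            r2 = r * r
            np.add.at(r2_sum, b[okb], r2[okb])
            np.add.at(c_sum, b[okb], cfrac[okb])
            np.add.at(n_pair, b[okb], 1)

    ne = np.full(n_bins, np.nan)
    cbar = np.full(n_bins, np.nan)
    for bi in range(n_bins):
        if n_pair[bi] == 0:
            continue
        cbar[bi] = c_sum[bi] / n_pair[bi]
        r2_adj = r2_sum[bi] / n_pair[bi] - BETA_SAMPLE / n_ind
        if r2_adj <= 0:
            continue
        est = (1.0 / r2_adj - ALPHA_UNPHASED) / (4.0 * cbar[bi])
        if est > 0:
            ne[bi] = est
    # nominal (geometric) centers stand in where a bin saw no pairs; bins
    # are disjoint c intervals so t is automatically strictly ordered
    geo = np.sqrt(edges[:-1] * edges[1:])
    cbar = np.where(np.isfinite(cbar), cbar, geo)
    t = 1.0 / (2.0 * cbar)
    return NeTrajectory(t[::-1], ne[::-1], c_bins)


def snp_blocks(panel: GenotypePanel, block_snps: int):
    """Index arrays of full blocks of consecutive SNPs within chromosomes."""
    blocks = []
    for c in np.unique(panel.markers.chromosome):
        idx = np.flatnonzero(panel.markers.chromosome == c)
        for b in range(len(idx) // block_snps):
            blocks.append(idx[b * block_snps:(b + 1) * block_snps])
    return blocks


def jackknife_envelope(panel: GenotypePanel, pop: str,
                       block_snps: int = 10000, c_bins=None,
                       estimator=ld_ne_trajectory) -> NeTrajectory:
    """Leave-one-block-out trajectory with a 95% percentile envelope.

    Builds all full blocks of ``block_snps`` consecutive SNPs (within
    chromosomes), re-runs ``estimator`` on the panel minus each block, and
    summarizes the B trajectories by their per-time mean and 2.5/97.5
    percentiles.
    """
    if c_bins is None:
        c_bins = recombination_bins()
    blocks = snp_blocks(panel, block_snps)
    if len(blocks) < 2:
        raise ValueError("need >= 2 full blocks for the jackknife envelope")
    runs = []
    for block in blocks:
        mask = np.ones(panel.n_markers, dtype=bool)
        mask[block] = False
        sub = panel.subset_markers(np.flatnonzero(mask))
        runs.append(estimator(sub, pop, c_bins=c_bins))
    # every run shares the bin layout, so align by bin position; the grid
    # is the per-position mean of the runs' (data-dependent) time points
    mat = np.vstack([r.ne for r in runs])
    grid = np.vstack([r.t for r in runs]).mean(axis=0)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # bins undefined in every jackknife run stay NaN in the envelope
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        lo = np.nanpercentile(mat, 2.5, axis=0)
        hi = np.nanpercentile(mat, 97.5, axis=0)
    return NeTrajectory(grid, mean, list(c_bins), lo=lo, hi=hi,
                        n_blocks=len(blocks))


def harmonic_mean_ne(traj: NeTrajectory, t_from: float, t_to: float) -> float:
    """Harmonic mean of the mean trajectory over grid points in [t_from, t_to]."""
    sel = (traj.t >= t_from) & (traj.t <= t_to) & np.isfinite(traj.ne)
    if not sel.any():
        raise ValueError("no trajectory points in the requested range")
    vals = traj.ne[sel]
    if np.any(vals <= 0):
        raise ValueError("harmonic mean undefined for non-positive Ne")
    return float(len(vals) / np.sum(1.0 / vals))


def to_calendar_axis(traj: NeTrajectory, sampling_year: int,
                     g_years: float = 6.0) -> NeTrajectory:
    """Attach calendar years: calendar(t) = sampling_year - g_years * t."""
    out = NeTrajectory(traj.t, traj.ne, traj.c_bins, lo=traj.lo, hi=traj.hi,
                       n_blocks=traj.n_blocks)
    out.calendar_year = sampling_year - g_years * traj.t
    return out
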