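"""Multi-class homozygosity-by-descent hidden Markov model.

An individual's genome is modelled as a mosaic of HBD and non-HBD
segments. Each HBD class k carries a rate R_k (default R_k = 2^k for
k = 1..11) controlling both the expected segment length (1/R_k Morgans)
and the age of the ancestor that transmitted it (about R_k / 2
generations before sampling); one extra non-HBD class shares the rate of
the oldest HBD class. Between adjacent markers at map distance d Morgans
the chain stays in its class with probability exp(-R_k d) and otherwise
re-enters a class drawn from the stationary mixing weights gamma (a
single-layer model with no class-to-class memory). Emissions: a non-HBD
marker shows Hardy–Weinberg genotype probabilities; an HBD marker shows
homozygotes with probabilities (q, p) and heterozygotes only through the
genotyping-error rate epsilon. Forward–backward posteriors give per-class
genome fractions; EM (rates fixed, gamma free) fits the mixing weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from iopopgen.genotype_io import MISSING, MarkerMap

__all__ = ["HBDModel", "HBDPartition", "class_to_generations",
           "hbd_forward_backward", "fit_mixing_weights", "partition_by_age"]


@dataclass
class HBDModel:
    """HBD-class rates, mixing weights, error rate and allele frequencies.

    ``rates`` has K+1 entries: K HBD classes (strictly increasing) plus
    the non-HBD class, whose rate equals the last HBD rate. ``gamma`` is a
    simplex vector of the same length. ``freq`` is the per-marker
    allele_b frequency used by the emissions (typically computed from the
    analyzed population itself).
    """

    rates: np.ndarray
    gamma: np.ndarray
    freq: np.ndarray
    epsilon: float = 0.001

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, float)
        self.gamma = np.asarray(self.gamma, float)
        self.freq = np.asarray(self.freq, float)
        if len(self.rates) != len(self.gamma):
            raise ValueError("rates and gamma must have equal length")
        hbd = self.rates[:-1]
        if np.any(np.diff(hbd) <= 0):
            raise ValueError("HBD class rates must be strictly increasing")
        if not np.isclose(self.gamma.sum(), 1.0) or np.any(self.gamma < 0):
            raise ValueError("gamma must lie on the simplex")
        if not 0.0 <= self.epsilon <= 0.05:
            raise ValueError("epsilon must be in [0, 0.05]")

    @classmethod
    def default(cls, freq: np.ndarray, n_classes: int = 11,
                epsilon: float = 0.001, gamma=None) -> "HBDModel":
        """Standard model: R_k = 2^k for k=1..n_classes, non-HBD at R_K."""
        rates = np.array([2.0 ** k for k in range(1, n_classes + 1)]
                         + [2.0 ** n_classes])
        if gamma is None:
            g = np.full(n_classes + 1, 0.5 / n_classes)
            g[-1] = 0.5
            gamma = g
        return cls(rates, np.asarray(gamma, float), freq, epsilon)

    @property
    def n_hbd_classes(self) -> int:
        return len(self.rates) - 1


@dataclass
class HBDPartition:
    """Per-marker posterior class probabilities and genome fractions."""

    posteriors: np.ndarray         # (n_markers, K+1)
    rates: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        s = self.posteriors.sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-6):
            raise ValueError("posteriors must sum to 1 at every marker")

    @property
    def class_fractions(self) -> np.ndarray:
        """Mean posterior per class (last entry = non-HBD)."""
        return self.posteriors.mean(axis=0)

    @property
    def inbreeding_coefficient(self) -> float:
        """F = summed genome fractions over all HBD classes."""
        return float(self.class_fractions[:-1].sum())


def class_to_generations(rate: float) -> float:
    """Ancestor depth (generations before sampling) of an HBD class: R/2."""
    if rate <= 0:
        raise ValueError("class rate must be positive")
    return rate / 2.0


# ---------------------------------------------------------------------------
# Emissions and transitions
# ---------------------------------------------------------------------------

def _emissions(model: HBDModel, genotypes: np.ndarray) -> np.ndarray:
    """Emission probabilities, shape (n_markers, K+1).

    HBD classes: hom_a with q(1-eps), hom_b with p(1-eps), het with eps.
    Non-HBD: Hardy–Weinberg probabilities blended with a uniform error
    floor, (1-eps) HW + eps/3. Missing genotypes emit 1 in every class.
    """
    p = model.freq
    q = 1.0 - p
    eps = model.epsilon
    n = len(genotypes)
    K1 = len(model.rates)
    em = np.ones((n, K1))
    g = genotypes
    hbd = np.select([g == 0, g == 1, g == 2],
                    [q * (1 - eps), np.full_like(p, eps), p * (1 - eps)],
                    default=1.0)
    hw = np.select([g == 0, g == 1, g == 2],
                   [q * q, 2 * p * q, p * p], default=1.0)
    hw = np.where(g == MISSING, 1.0, (1 - eps) * hw + eps / 3.0)
    hbd = np.where(g == MISSING, 1.0, hbd)
    em[:, :-1] = hbd[:, None]
    em[:, -1] = hw
    return em


def _stay_probs(model: HBDModel, map_cM: np.ndarray) -> np.ndarray:
    """exp(-R_k * d) per inter-marker interval, shape (n_markers-1, K+1).

    Chromosome breaks should be encoded as large distances by the caller
    (the chain forgets its class across chromosomes).
    """
    d = np.diff(map_cM) / 100.0
    return np.exp(-np.outer(d, model.rates))


def _intervals(markers: MarkerMap) -> np.ndarray:
    """Inter-marker Morgan distances; chromosome breaks become huge."""
    d = np.diff(markers.genetic_pos_cM) / 100.0
    breaks = np.diff(markers.chromosome) != 0
    return np.where(breaks, 1e6, np.maximum(d, 0.0))


# ---------------------------------------------------------------------------
# Forward–backward
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fb_core(em, stay, gamma):
    """Scaled forward–backward for the class re-entry transition structure.

    T_t[i, j] = stay_t[i] delta_ij + (1 - stay_t[i]) gamma[j].
    Returns (posteriors, log-likelihood, xi_reentry) where
    ``xi_reentry[j]`` accumulates the expected number of re-entries into
    class j (plus the initial draw), the sufficient statistic for gamma.
    A negative log-likelihood sentinel of -inf marks a zero-probability
    path (handled by the caller).
    """
    n, K1 = em.shape
    alpha = np.empty((n, K1))
    scale = np.empty(n)
    s = 0.0
    for j in range(K1):
        alpha[0, j] = gamma[j] * em[0, j]
        s += alpha[0, j]
    if s <= 0.0 or not np.isfinite(s):
        return alpha, -np.inf, gamma.copy()
    for j in range(K1):
        alpha[0, j] /= s
    scale[0] = s
    for t in range(1, n):
        jump = 0.0
        for j in range(K1):
            jump += alpha[t - 1, j] * (1.0 - stay[t - 1, j])
        s = 0.0
        for j in range(K1):
            a = (alpha[t - 1, j] * stay[t - 1, j] + jump * gamma[j]) \
                * em[t, j]
            alpha[t, j] = a
            s += a
        if s <= 0.0 or not np.isfinite(s):
            return alpha, -np.inf, gamma.copy()
        for j in range(K1):
            alpha[t, j] /= s
        scale[t] = s
    beta = np.ones(K1)
    post = np.empty((n, K1))
    xi = np.zeros(K1)
    for j in range(K1):
        post[n - 1, j] = alpha[n - 1, j]
    for t in range(n - 2, -1, -1):
        dot = 0.0
        eb = np.empty(K1)
        for j in range(K1):
            eb[j] = em[t + 1, j] * beta[j]
            dot += gamma[j] * eb[j]
        jump_mass = 0.0
        for j in range(K1):
            jump_mass += alpha[t, j] * (1.0 - stay[t, j])
        ssum = 0.0
        for j in range(K1):
            xi[j] += jump_mass * gamma[j] * eb[j] / scale[t + 1]
            beta_new = (stay[t, j] * eb[j] + (1.0 - stay[t, j]) * dot) \
                / scale[t + 1]
            post[t, j] = alpha[t, j] * beta_new
            ssum += post[t, j]
            beta[j] = beta_new
        for j in range(K1):
            post[t, j] /= ssum
    ll = 0.0
    for t in range(n):
        ll += np.log(scale[t])
    for j in range(K1):
        xi[j] += post[0, j]  # the initial class draw also follows gamma
    return post, ll, xi


def _forward_backward(em: np.ndarray, stay: np.ndarray, gamma: np.ndarray):
    post, ll, xi = _fb_core(em, stay, gamma)
    if not np.isfinite(ll):
        raise FloatingPointError(
            "zero-probability path (all emissions 0 at some marker)")
    return post, float(ll), xi


def hbd_forward_backward(genotypes: np.ndarray, markers: MarkerMap,
                         model: HBDModel) -> HBDPartition:
    """Posterior HBD-class probabilities for one individual's genotypes."""
    genotypes = np.asarray(genotypes)
    if len(genotypes) != len(markers):
        raise ValueError("genotype vector length != marker count")
    em = _emissions(model, genotypes)
    stay = np.exp(-np.outer(_intervals(markers), model.rates))
    post, ll, _ = _forward_backward(em, stay, model.gamma)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood")
    return HBDPartition(post, model.rates, ll)


# ---------------------------------------------------------------------------
# EM for the mixing weights
# ---------------------------------------------------------------------------

def fit_mixing_weights(genotypes: np.ndarray, markers: MarkerMap,
                       model: HBDModel, tol: float = 1e-6,
                       max_iter: int = 1000):
    """EM fit of gamma (rates fixed) for one individual.

    Iterates until the log-likelihood gain drops below ``tol`` or
    ``max_iter`` iterations; the log-likelihood is non-decreasing at every
    step. Returns (fitted HBDModel, HBDPartition, log-likelihood trace).
    """
    genotypes = np.asarray(genotypes)
    if len(genotypes) < 200:
        import logging
        logging.getLogger("iopopgen").warning(
            "only %d markers; gamma estimates will be unstable below ~200",
            len(genotypes))
    em = _emissions(model, genotypes)
    stay = np.exp(-np.outer(_intervals(markers), model.rates))
    gamma = model.gamma.copy()
    trace = []
    post = None
    for _ in range(max_iter):
        post, ll, xi = _forward_backward(em, stay, gamma)
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        xi = np.maximum(xi, 1e-300)
        gamma = xi / xi.sum()
    fitted = HBDModel(model.rates, gamma, model.freq, model.epsilon)
    final_ll = trace[-1]
    return fitted, HBDPartition(post, model.rates, final_ll), np.array(trace)


def partition_by_age(partition: HBDPartition, g_split: float):
    """Split total inbreeding into recent and ancient components.

    Classes whose ancestor depth R/2 is <= ``g_split`` generations count
    as recent; the rest (excluding non-HBD) as ancient. Returns
    (recent_F, ancient_F) with recent + ancient = total F exactly.
    """
    frac = partition.class_fractions[:-1]
    depth = partition.rates[:-1] / 2.0
    recent = float(frac[depth <= g_split].sum())
    ancient = float(frac[depth > g_split].sum())
    return recent, ancient
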