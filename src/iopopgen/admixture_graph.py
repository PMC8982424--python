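"""Admixture-graph construction and fitting on the f2 basis.

A rooted graph whose edges carry drift lengths (t/2Ne units, up to the
panel's heterozygosity scale) and whose admixture nodes mix two parents
with proportion alpha. Predicted f2 between leaves is the weighted sum
over edges of squared leaf-usage-weight differences; f3/f4 follow from the
standard linear identities:

    f3(A;B,C)   = (f2(A,B) + f2(A,C) - f2(B,C)) / 2
    f4(A,B;C,D) = (f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D)) / 2

The scaffold tree of unadmixed populations comes from neighbor joining on
the pairwise-f2 distance matrix (scikit-bio), rooted on a prescribed
outgroup bipartition. Admixed leaves are then grafted — as a plain branch
or a two-parent admixture — over every insertion order, each candidate
refit by weighted least squares, and ranked by BIC with the conventional
"more than 8 units lower" support rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["AdmixtureGraph", "GraphFit", "scaffold_tree", "predict_fstats",
           "fit_graph", "insert_admixed_leaves", "diagnose_fit"]

_ALPHA_LO, _ALPHA_HI = 1e-3, 1.0 - 1e-3


# ---------------------------------------------------------------------------
# Graph structure
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureGraph:
    """Rooted graph with drift-length edges and two-parent admixture nodes.

    ``edges`` maps (parent, child) -> drift length (>= 0).
    ``admixture`` maps an admixture node -> (parentA, parentB, alpha) where
    alpha is the proportion inherited from parentA. Admixture-node in-edges
    still appear in ``edges`` and carry their own drift lengths.
    """

    root: str
    edges: dict
    admixture: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = dict(self.edges)
        self.admixture = dict(self.admixture)
        self.validate()

    # -- structural helpers -------------------------------------------------

    def children(self, node: str):
        return [c for (p, c) in self.edges if p == node]

    def parents(self, node: str):
        return [p for (p, c) in self.edges if c == node]

    @property
    def nodes(self):
        out = {self.root: None}
        for p, c in self.edges:
            out.setdefault(p, None)
            out.setdefault(c, None)
        return list(out)

    @property
    def leaves(self):
        inner = {p for (p, _) in self.edges}
        return [n for n in self.nodes if n not in inner]

    def validate(self) -> None:
        for (p, c), l in self.edges.items():
            if l < -1e-12:
                raise ValueError(f"negative drift length on edge {p}->{c}")
        for node in self.nodes:
            pars = self.parents(node)
            if node == self.root:
                if pars:
                    raise ValueError("root must have no parent")
            elif node in self.admixture:
                pa, pb, alpha = self.admixture[node]
                if sorted(pars) != sorted((pa, pb)):
                    raise ValueError(f"admixture node {node} parent mismatch")
                if not (0.0 < alpha < 1.0):
                    raise ValueError(f"alpha for {node} must be in (0,1)")
            elif len(pars) != 1:
                raise ValueError(f"node {node} must have exactly one parent")
        # reachability + acyclicity via topological order
        self.topological_order()

    def topological_order(self):
        """Nodes ordered parents-before-children; raises on cycles."""
        order, state = [], {}

        def visit(n):
            if state.get(n) == 1:
                raise ValueError("graph contains a cycle")
            if state.get(n) == 2:
                return
            state[n] = 1
            for c in self.children(n):
                visit(c)
            state[n] = 2
            order.append(n)

        visit(self.root)
        unreachable = set(self.nodes) - set(order)
        if unreachable:
            raise ValueError(f"nodes unreachable from root: {unreachable}")
        return order[::-1]

    # -- usage weights ------------------------------------------------------

    def leaf_edge_weights(self, leaf: str) -> dict:
        """Path-probability weight of every edge for one leaf.

        Propagates mass from the leaf toward the root; admixture nodes
        split their mass alpha / (1 - alpha) between parents, so a weight
        is the probability that the leaf's lineage uses that edge.
        """
        mass = {leaf: 1.0}
        weights = {e: 0.0 for e in self.edges}
        for node in reversed(self.topological_order()):
            m = mass.get(node, 0.0)
            if m == 0.0 or node == self.root:
                continue
            if node in self.admixture:
                pa, pb, alpha = self.admixture[node]
                shares = {pa: alpha * m, pb: (1.0 - alpha) * m}
            else:
                shares = {self.parents(node)[0]: m}
            for par, share in shares.items():
                weights[(par, node)] += share
                mass[par] = mass.get(par, 0.0) + share
        return weights

    def copy(self) -> "AdmixtureGraph":
        return AdmixtureGraph(self.root, dict(self.edges),
                              {k: tuple(v) for k, v in self.admixture.items()})


@dataclass
class GraphFit:
    """Result of weighted-least-squares graph fitting."""

    graph: AdmixtureGraph
    objective: float
    bic: float
    n_stats: int
    n_params: int
    residual_z: dict = field(default_factory=dict)

    @property
    def worst_z(self) -> float:
        if not self.residual_z:
            return np.nan
        key = max(self.residual_z, key=lambda k: abs(self.residual_z[k]))
        return self.residual_z[key]

    @property
    def worst_statistic(self):
        if not self.residual_z:
            return None
        return max(self.residual_z, key=lambda k: abs(self.residual_z[k]))


# ---------------------------------------------------------------------------
# Scaffold tree
# ---------------------------------------------------------------------------

def scaffold_tree(f2_matrix, populations, outgroup_side) -> AdmixtureGraph:
    """Neighbor-joining tree on the pairwise-f2 distance matrix, rooted.

    ``outgroup_side`` is the set of populations that must fall on one side
    of the root; the root is placed midway on the edge realizing that
    bipartition (error if the NJ tree has no such edge). Negative NJ branch
    lengths are clamped to zero.
    """
    import skbio

    populations = list(populations)
    f2 = np.asarray(f2_matrix, float)
    outgroup_side = set(outgroup_side)
    if not outgroup_side or not outgroup_side < set(populations):
        raise ValueError("outgroup_side must be a proper non-empty subset")
    if len(populations) == 2:
        l = max(f2[0, 1], 0.0) / 2.0
        a, b = populations
        return AdmixtureGraph("ROOT", {("ROOT", a): l, ("ROOT", b): l})
    dm = skbio.DistanceMatrix(np.maximum(f2, 0.0), ids=populations)
    tree = skbio.tree.nj(dm)

    # convert the unrooted skbio tree to edge list with a midpoint-style
    # root on the outgroup bipartition edge
    clamped = [False]

    def length(node):
        l = node.length or 0.0
        if l < 0:
            clamped[0] = True
            return 0.0
        return l

    # collect bipartitions: for each edge (child subtree), the tip set below
    target = None
    for node in tree.postorder(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if tips == outgroup_side or tips == set(populations) - outgroup_side:
            target = node
            break
    if target is None:
        raise ValueError("outgroup_side is not a bipartition of the NJ tree")
    rooted = tree.root_at(target, above=True, reset=True)
    # root_at(above=True) splits the bipartition edge at its midpoint;
    # rebuild the skbio tree as our graph

    edges, counter = {}, itertools.count()

    def build(node, parent_name):
        if node.is_tip():
            name = node.name
        else:
            name = node.name or f"N{next(counter)}"
            node.name = name
        if parent_name is not None:
            edges[(parent_name, name)] = length(node)
        for ch in node.children:
            build(ch, name)
        return name

    rooted.name = "ROOT"
    for ch in rooted.children:
        build(ch, "ROOT")
    if clamped[0]:
        import logging
        logging.getLogger("iopopgen").warning(
            "negative NJ branch length(s) clamped to 0")
    return AdmixtureGraph("ROOT", edges)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_fstats(graph: AdmixtureGraph, requests) -> dict:
    """Predicted f2/f3/f4 for population tuples of arity 2/3/4."""
    weights = {leaf: graph.leaf_edge_weights(leaf) for leaf in graph.leaves}

    def f2(a, b):
        wa, wb = weights[a], weights[b]
        return sum((wa[e] - wb[e]) ** 2 * l for e, l in graph.edges.items())

    out = {}
    for pops in requests:
        pops = tuple(pops)
        if len(pops) == 2:
            out[pops] = f2(*pops)
        elif len(pops) == 3:
            a, b, c = pops
            out[pops] = (f2(a, b) + f2(a, c) - f2(b, c)) / 2.0
        elif len(pops) == 4:
            a, b, c, d = pops
            out[pops] = (f2(a, d) + f2(b, c) - f2(a, c) - f2(b, d)) / 2.0
        else:
            raise ValueError("requests must have arity 2, 3 or 4")
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _pack(graph):
    edge_keys = sorted(graph.edges)
    adm_keys = sorted(graph.admixture)
    x0 = np.array([graph.edges[e] for e in edge_keys]
                  + [graph.admixture[k][2] for k in adm_keys])
    bounds = [(0.0, None)] * len(edge_keys) + \
             [(_ALPHA_LO, _ALPHA_HI)] * len(adm_keys)
    return edge_keys, adm_keys, x0, bounds


def _unpack(graph, edge_keys, adm_keys, x):
    g = graph.copy()
    for e, v in zip(edge_keys, x[:len(edge_keys)]):
        g.edges[e] = max(float(v), 0.0)
    for k, v in zip(adm_keys, x[len(edge_keys):]):
        pa, pb, _ = g.admixture[k]
        g.admixture[k] = (pa, pb, float(np.clip(v, _ALPHA_LO, _ALPHA_HI)))
    return g


def fit_graph(graph: AdmixtureGraph, observed: dict, variances: dict,
              n_restarts: int = 25, seed: int = 0) -> GraphFit:
    """Weighted least-squares fit of drift lengths and admixture proportions.

    ``observed`` maps population pairs -> observed f2; ``variances`` maps
    the same keys -> jackknife variances (diagonal weighting). Minimizes
    Q = sum_i r_i^2 / var_i with L-BFGS-B from ``n_restarts`` seeded
    starting points; BIC = Q* + k ln(n_stats) with k the free-parameter
    count (relative comparison only).
    """
    pairs = sorted(observed)
    obs = np.array([observed[p] for p in pairs])
    w = np.array([1.0 / max(variances[p], 1e-18) for p in pairs])
    edge_keys, adm_keys, x0, bounds = _pack(graph)
    k = len(x0)
    if k >= len(pairs):
        import logging
        logging.getLogger("iopopgen").warning(
            "graph has %d free parameters for %d statistics "
            "(identifiability at risk)", k, len(pairs))

    def objective(x):
        g = _unpack(graph, edge_keys, adm_keys, x)
        pred = predict_fstats(g, pairs)
        r = obs - np.array([pred[p] for p in pairs])
        return float(np.sum(w * r * r))

    rng = np.random.default_rng(seed)
    scale = max(float(np.mean(np.abs(obs))), 1e-6)
    best_x, best_q = None, np.inf
    for i in range(n_restarts):
        if i == 0:
            start = x0.copy()
        else:
            start = np.empty(k)
            start[:len(edge_keys)] = rng.uniform(0, 2 * scale, len(edge_keys))
            start[len(edge_keys):] = rng.uniform(0.1, 0.9, len(adm_keys))
        res = minimize(objective, start, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and res.fun < best_q:
            best_q, best_x = float(res.fun), res.x
    if best_x is None:
        raise RuntimeError(
            f"graph fitting failed to converge from {n_restarts} restarts")
    fitted = _unpack(graph, edge_keys, adm_keys, best_x)
    bic = best_q + k * np.log(len(pairs))
    fit = GraphFit(fitted, best_q, bic, len(pairs), k)
    fit.residual_z = _residuals(fitted, observed, variances)
    return fit


def _residuals(graph, observed, variances):
    pred = predict_fstats(graph, list(observed))
    out = {}
    for key, o in observed.items():
        se = np.sqrt(max(variances[key], 1e-18))
        out[key] = (o - pred[key]) / se
    return out


def diagnose_fit(fit: GraphFit, observed: dict, variances: dict) -> dict:
    """Residual Z for every supplied f-statistic (any arity) plus worst.

    Returns a dict with 'residual_z' (tuple -> Z), 'worst_z' and
    'worst_statistic'; a fit is conventionally adequate iff |worst_z| < 3.
    """
    z = _residuals(fit.graph, observed, variances)
    worst = max(z, key=lambda k: abs(z[k]))
    return {"residual_z": z, "worst_z": z[worst], "worst_statistic": worst,
            "adequate": abs(z[worst]) < 3.0}


# ---------------------------------------------------------------------------
# Admixed-leaf insertion search
# ---------------------------------------------------------------------------

def _graft_branch(graph, leaf, edge, counter):
    """New graph with ``leaf`` hung from the middle of ``edge``."""
    g = graph.copy()
    (p, c) = edge
    mid = f"G{next(counter)}"
    l = g.edges.pop(edge)
    g.edges[(p, mid)] = l / 2.0
    g.edges[(mid, c)] = l / 2.0
    g.edges[(mid, leaf)] = l / 2.0 + 1e-4
    return g


def _graft_admixed(graph, leaf, edge1, edge2, counter):
    """New graph with ``leaf`` admixed between the middles of two edges."""
    g = graph.copy()
    mids = []
    for edge in (edge1, edge2):
        (p, c) = edge
        mid = f"G{next(counter)}"
        l = g.edges.pop(edge)
        g.edges[(p, mid)] = l / 2.0
        g.edges[(mid, c)] = l / 2.0
        mids.append(mid)
    g.edges[(mids[0], leaf)] = 1e-4
    g.edges[(mids[1], leaf)] = 1e-4
    g.admixture[leaf] = (mids[0], mids[1], 0.5)
    return g


def insert_admixed_leaves(scaffold: AdmixtureGraph, leaves, observed: dict,
                          variances: dict, n_restarts_search: int = 5,
                          n_restarts_final: int = 25, seed: int = 0):
    """Graft admixed leaves onto the scaffold over all insertion orders.

    For every permutation of ``leaves``, each leaf is grafted greedily as a
    plain branch on every edge and as a two-parent admixture between every
    edge pair, keeping the BIC-best placement before inserting the next
    leaf. Returns (best GraphFit, BIC gap to the runner-up over final
    per-permutation candidates). With no leaves, returns the scaffold fit
    and an infinite gap.
    """
    counter = itertools.count()
    leaves = list(leaves)

    def fit_for(graph, pops, restarts):
        keys = [tuple(sorted(p)) for p in
                itertools.combinations(sorted(pops), 2)]
        obs = {k: observed[k] for k in keys}
        var = {k: variances[k] for k in keys}
        return fit_graph(graph, obs, var, n_restarts=restarts, seed=seed)

    base_pops = list(scaffold.leaves)
    if not leaves:
        fit = fit_for(scaffold, base_pops, n_restarts_final)
        return fit, np.inf

    finals = []
    for order in itertools.permutations(leaves):
        graph = scaffold
        pops = list(base_pops)
        for leaf in order:
            pops.append(leaf)
            best = None
            edges = list(graph.edges)
            candidates = [_graft_branch(graph, leaf, e, counter)
                          for e in edges]
            candidates += [_graft_admixed(graph, leaf, e1, e2, counter)
                           for e1, e2 in itertools.combinations(edges, 2)]
            for cand in candidates:
                try:
                    fit = fit_for(cand, pops, n_restarts_search)
                except (RuntimeError, ValueError):
                    continue
                if best is None or fit.bic < best.bic:
                    best = fit
            if best is None:
                raise RuntimeError(f"no valid placement found for {leaf}")
            graph = best.graph
        finals.append(fit_for(graph, pops, n_restarts_final))
    finals.sort(key=lambda f: f.bic)
    gap = finals[1].bic - finals[0].bic if len(finals) > 1 else np.inf
    return finals[0], gap
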