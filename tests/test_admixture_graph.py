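"""Scaffold trees, graph prediction, fitting, BIC search and diagnostics."""

import itertools

import numpy as np
import pytest

import iopopgen as io
from iopopgen import synthetic_data as sd
from iopopgen.admixture_graph import AdmixtureGraph
from tests.conftest import f2_basis


def _tree():
    return AdmixtureGraph("ROOT", {
        ("ROOT", "X"): 0.01, ("ROOT", "OUT"): 0.05,
        ("X", "A"): 0.02, ("X", "B"): 0.03})


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def test_graph_validation_rejects_cycles_and_bad_alpha():
    with pytest.raises(ValueError):
        AdmixtureGraph("R", {("R", "A"): 1, ("A", "B"): 1, ("B", "A"): 1})
    with pytest.raises(ValueError, match="alpha"):
        AdmixtureGraph("R", {("R", "P"): 1, ("R", "Q"): 1, ("P", "M"): 0.1,
                             ("Q", "M"): 0.1},
                       {"M": ("P", "Q", 1.5)})


def test_leaf_edge_weights_sum_to_one_at_cuts(admixed_graph):
    w = admixed_graph.leaf_edge_weights("M")
    # at the cut just above the admixture node the two in-edges share mass
    assert w[("Asrc", "M")] + w[("Bsrc", "M")] == pytest.approx(1.0)
    assert w[("ROOT", "X")] + w[("ROOT", "Y")] == pytest.approx(1.0)
    assert all(0.0 <= v <= 1.0 for v in w.values())


# ---------------------------------------------------------------------------
# scaffold tree
# ---------------------------------------------------------------------------

def test_scaffold_three_point_formula():
    """Additive 3-taxon distances are recovered exactly by NJ."""
    # place A, B, C at distances from internal node: 1, 2, 5
    d = {("A", "B"): 3.0, ("A", "C"): 6.0, ("B", "C"): 7.0}
    pops = ["A", "B", "C"]
    m = np.zeros((3, 3))
    for (x, y), v in d.items():
        i, j = pops.index(x), pops.index(y)
        m[i, j] = m[j, i] = v
    tree = io.scaffold_tree(m, pops, {"C"})
    # external branch lengths from the three-point formula
    w = {leaf: tree.leaf_edge_weights(leaf) for leaf in "ABC"}

    def dist(x, y):
        return sum((w[x][e] - w[y][e]) ** 2 * l
                   for e, l in tree.edges.items())

    for (x, y), v in d.items():
        assert dist(x, y) == pytest.approx(v, abs=1e-9)


def test_scaffold_recovers_ultrametric_topology():
    truth = AdmixtureGraph("ROOT", {
        ("ROOT", "U"): 0.01, ("ROOT", "V"): 0.01,
        ("U", "A"): 0.02, ("U", "B"): 0.02,
        ("V", "C"): 0.02, ("V", "D"): 0.02})
    pops = ["A", "B", "C", "D"]
    pred = io.predict_fstats(truth, list(itertools.combinations(pops, 2)))
    m = np.zeros((4, 4))
    for (x, y), v in pred.items():
        i, j = pops.index(x), pops.index(y)
        m[i, j] = m[j, i] = v
    tree = io.scaffold_tree(m, pops, {"C", "D"})
    # A,B must be siblings under the recovered rooted tree
    par_a = tree.parents("A")[0]
    assert set(tree.children(par_a)) == {"A", "B"}


def test_scaffold_two_populations_and_bad_outgroup():
    tree = io.scaffold_tree(np.array([[0.0, 0.08], [0.08, 0.0]]),
                            ["A", "B"], {"A"})
    assert set(tree.leaves) == {"A", "B"}
    assert sum(tree.edges.values()) == pytest.approx(0.08)
    truth_m = np.array([[0, 1, 4, 4], [1, 0, 4, 4],
                        [4, 4, 0, 1], [4, 4, 1, 0]], float)
    with pytest.raises(ValueError, match="bipartition"):
        io.scaffold_tree(truth_m, ["A", "B", "C", "D"], {"A", "C"})


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_tree_additivity():
    tree = _tree()
    pred = io.predict_fstats(tree, [("A", "OUT"), ("A", "B")])
    assert pred[("A", "OUT")] == pytest.approx(0.02 + 0.01 + 0.05)
    assert pred[("A", "B")] == pytest.approx(0.02 + 0.03)


def test_predict_f3_negative_for_balanced_admixture(admixed_graph):
    pred = io.predict_fstats(admixed_graph, [("M", "A", "B")])
    assert pred[("M", "A", "B")] < 0


def test_predict_identities_hold_exactly(admixed_graph):
    g = admixed_graph
    pops = g.leaves
    f2 = io.predict_fstats(g, list(itertools.combinations(pops, 2)))

    def get(x, y):
        return f2.get((x, y), f2.get((y, x), 0.0))

    quads = list(itertools.permutations(pops, 4))[:20]
    pred4 = io.predict_fstats(g, quads)
    for (a, b, c, d) in quads:
        expect = (get(a, d) + get(b, c) - get(a, c) - get(b, d)) / 2
        assert pred4[(a, b, c, d)] == pytest.approx(expect, abs=1e-12)
        assert pred4[(a, b, c, d)] == pytest.approx(
            -io.predict_fstats(g, [(b, a, c, d)])[(b, a, c, d)], abs=1e-12)


def test_predict_matches_monte_carlo_simulation(admixed_graph):
    """Predicted f2 equals the estimator on simulated frequencies, up to
    the heterozygosity scale, within 3 jackknife SE."""
    freqs, panel, _ = sd.simulate_graph_frequencies(
        admixed_graph, 100_000, seed=9, n_per_pop=50)
    from iopopgen.fstats import BlockPartition
    part = BlockPartition.from_map(panel.markers, 1000)
    f = io.compute_frequencies(panel)
    pairs = [("M", "A"), ("A", "B"), ("M", "OUT")]
    ests = io.f_statistics(f, pairs, part)
    pred = io.predict_fstats(admixed_graph, pairs)
    # shared scale: E[p(1-p)] at the root, estimated from the panel itself
    scale = np.array([e.estimate for e in ests]).sum() \
        / np.array([pred[p] for p in pairs]).sum()
    for e, p in zip(ests, pairs):
        # [0,1]-truncation of the drift kernel compresses the deepest
        # pairs slightly, so allow 3% on top of the 3-SE sampling band
        tol = 3 * e.jackknife_se + 0.03 * abs(pred[p] * scale)
        assert e.estimate == pytest.approx(pred[p] * scale, abs=tol)


def test_degenerate_alpha_reduces_to_tree(admixed_graph):
    g = admixed_graph.copy()
    pa, pb, _ = g.admixture["M"]
    g.admixture["M"] = (pa, pb, 1.0 - 1e-12)
    tree_like = io.predict_fstats(g, [("M", "A")])[("M", "A")]
    # manual additive path through the alpha~1 parent
    expect = (g.edges[("Asrc", "M")] + g.edges[("X", "Asrc")]
              + g.edges[("X", "A")])
    assert tree_like == pytest.approx(expect, abs=1e-6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_noiseless_tree():
    tree = _tree()
    pops = tree.leaves
    pairs = [tuple(sorted(p)) for p in itertools.combinations(sorted(pops), 2)]
    obs = io.predict_fstats(tree, pairs)
    var = {p: 1e-10 for p in pairs}
    start = tree.copy()
    for e in start.edges:
        start.edges[e] = 0.01
    fit = io.fit_graph(start, obs, var, n_restarts=10, seed=0)
    assert fit.objective < 1e-6
    pred = io.predict_fstats(fit.graph, pairs)
    for p in pairs:
        assert pred[p] == pytest.approx(obs[p], abs=1e-6)


def test_fit_scale_consistency(graph_panel, graph_partition, admixed_graph):
    _, part, obs, var = f2_basis((graph_panel, graph_partition))
    fit1 = io.fit_graph(admixed_graph, obs, var, n_restarts=6, seed=0)
    c = 10.0
    obs_c = {k: v * c for k, v in obs.items()}
    var_c = {k: v * c * c for k, v in var.items()}
    fit2 = io.fit_graph(admixed_graph, obs_c, var_c, n_restarts=6, seed=0)
    a1 = fit1.graph.admixture["M"][2]
    a2 = fit2.graph.admixture["M"][2]
    assert a2 == pytest.approx(a1, abs=0.02)
    l1 = sum(fit1.graph.edges.values())
    l2 = sum(fit2.graph.edges.values())
    assert l2 / l1 == pytest.approx(c, rel=0.05)


def test_fit_alpha_recovery_on_simulated_graph(graph_panel, graph_partition,
                                               admixed_graph):
    _, part, obs, var = f2_basis((graph_panel, graph_partition))
    fit = io.fit_graph(admixed_graph, obs, var, n_restarts=10, seed=1)
    assert fit.graph.admixture["M"][2] == pytest.approx(0.5, abs=0.1)
    assert abs(fit.worst_z) < 3.0


# ---------------------------------------------------------------------------
# insertion search and diagnostics
# ---------------------------------------------------------------------------

def test_insert_zero_leaves_returns_scaffold_fit(graph_panel,
                                                 graph_partition):
    _, part, obs, var = f2_basis((graph_panel, graph_partition))
    scaffold = io.scaffold_tree(
        np.array([[0.0, obs[("A", "OUT")]], [obs[("A", "OUT")], 0.0]]),
        ["A", "OUT"], {"OUT"})
    fit, gap = io.insert_admixed_leaves(scaffold, [], obs, var, seed=0)
    assert gap == np.inf
    assert set(fit.graph.leaves) == {"A", "OUT"}


def test_insert_places_admixed_leaf_as_admixture(graph_panel,
                                                 graph_partition):
    """A genuinely two-source leaf is grafted as an admixture and beats the
    best pure-tree placement by more than 8 BIC units."""
    f, part, obs, var = f2_basis((graph_panel, graph_partition))
    scaff_pops = ["A", "B", "OUT"]
    m = np.zeros((3, 3))
    for i, x in enumerate(scaff_pops):
        for j, y in enumerate(scaff_pops):
            if i < j:
                key = tuple(sorted((x, y)))
                m[i, j] = m[j, i] = obs[key]
    scaffold = io.scaffold_tree(m, scaff_pops, {"OUT"})
    best, gap = io.insert_admixed_leaves(
        scaffold, ["M"], obs, var, n_restarts_search=4,
        n_restarts_final=10, seed=0)
    assert "M" in best.graph.admixture
    # compare against the best branch-only placement
    from iopopgen.admixture_graph import _graft_branch
    import itertools as it
    counter = it.count(1000)
    tree_bics = []
    keys = [tuple(sorted(p)) for p in
            it.combinations(sorted(scaff_pops + ["M"]), 2)]
    for e in list(scaffold.edges):
        cand = _graft_branch(scaffold, "M", e, counter)
        fit = io.fit_graph(cand, {k: obs[k] for k in keys},
                           {k: var[k] for k in keys}, n_restarts=6, seed=0)
        tree_bics.append(fit.bic)
    assert min(tree_bics) - best.bic > 8.0


def test_diagnose_fit_reports_worst_statistic(graph_panel, graph_partition,
                                              admixed_graph):
    f, part, obs, var = f2_basis((graph_panel, graph_partition))
    fit = io.fit_graph(admixed_graph, obs, var, n_restarts=8, seed=0)
    pops = sorted(admixed_graph.leaves)
    quads = [q for q in itertools.combinations(pops, 4)]
    ests = io.f_statistics(f, quads, part)
    all_obs = dict(obs)
    all_var = dict(var)
    for e in ests:
        all_obs[e.populations] = e.estimate
        all_var[e.populations] = e.jackknife_se ** 2
    diag = io.diagnose_fit(fit, all_obs, all_var)
    assert diag["worst_statistic"] in all_obs
    assert abs(diag["worst_z"]) == max(abs(z)
                                       for z in diag["residual_z"].values())
    assert diag["adequate"] == (abs(diag["worst_z"]) < 3.0)
    # perfect-fit synthetic data: every residual within calibration bounds
    assert abs(diag["worst_z"]) < 4.5
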