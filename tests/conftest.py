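import itertools

import numpy as np
import pytest

from iopopgen import synthetic_data as sd
from iopopgen.admixture_graph import AdmixtureGraph
from iopopgen.fstats import BlockPartition
from iopopgen.genotype_io import GenotypePanel, MarkerMap


@pytest.fixture
def small_map():
    """10 markers on 2 chromosomes with hand-set positions."""
    return MarkerMap(
        [f"m{i}" for i in range(10)],
        [1] * 5 + [2] * 5,
        [100_000 * (i + 1) for i in range(5)] * 2,
        [0.1 * (i + 1) for i in range(5)] * 2,
        ["A"] * 10, ["B"] * 10)


@pytest.fixture
def toy_panel(small_map):
    """3 populations x 4 individuals on the small map."""
    rng = np.random.default_rng(42)
    g = rng.integers(0, 3, size=(12, 10)).astype(np.int8)
    return GenotypePanel(
        small_map,
        [f"i{i}" for i in range(12)],
        ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4,
        g)


@pytest.fixture(scope="session")
def admixed_graph():
    """Admixed leaf M between deep sources; f3(M;A,B) < 0 by construction."""
    edges = {("ROOT", "X"): 0.05, ("ROOT", "Y"): 0.05,
             ("X", "A"): 0.01, ("X", "Asrc"): 0.001,
             ("Y", "B"): 0.01, ("Y", "Bsrc"): 0.001,
             ("Asrc", "M"): 0.001, ("Bsrc", "M"): 0.001,
             ("X", "OUT"): 0.06}
    return AdmixtureGraph("ROOT", edges, {"M": ("Asrc", "Bsrc", 0.5)})


@pytest.fixture(scope="session")
def graph_panel(admixed_graph):
    """50k-SNP panel simulated from the admixed 5-leaf graph."""
    freqs, panel, truth = sd.simulate_graph_frequencies(
        admixed_graph, 50_000, seed=202, n_per_pop=30)
    return freqs, panel, truth


@pytest.fixture(scope="session")
def graph_partition(graph_panel):
    _, panel, _ = graph_panel
    return BlockPartition.from_map(panel.markers, 500)


def f2_basis(freqs_panel_partition):
    """Observed f2 basis + variances from a (freqs, panel, truth) tuple."""
    import iopopgen as io

    (pf, panel, _), part = freqs_panel_partition
    f = io.compute_frequencies(panel)
    pops = f.populations
    pairs = [tuple(sorted(p)) for p in itertools.combinations(sorted(pops), 2)]
    ests = io.f_statistics(f, pairs, part)
    obs = {e.populations: e.estimate for e in ests}
    var = {e.populations: e.jackknife_se ** 2 for e in ests}
    return f, part, obs, var
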