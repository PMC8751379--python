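import networkx as nx
import numpy as np
import pytest

from netprio import (
    BenchmarkSpec,
    simulate_drug_target_network,
    simulate_gwas_benchmark,
    simulate_interactome_with_module,
)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down benchmark for fast integration tests."""
    return BenchmarkSpec(
        n_nodes=150,
        n_loci=8,
        candidates_per_locus=4,
        n_proximal_drugs=2,
        n_distal_drugs=4,
        targets_per_drug=2,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_benchmark(small_spec):
    net, planted = simulate_interactome_with_module(small_spec)
    gwas = simulate_gwas_benchmark(net, planted, small_spec)
    drugs, drug_truth = simulate_drug_target_network(net, planted, small_spec)
    return {
        "spec": small_spec,
        "net": net,
        "planted": planted,
        "gwas": gwas,
        "drugs": drugs,
        "drug_truth": drug_truth,
    }


@pytest.fixture(scope="session")
def default_benchmark():
    """The full default benchmark (500 nodes, 20 loci x 5, density 0.3, seed 7)."""
    spec = BenchmarkSpec()
    net, planted = simulate_interactome_with_module(spec)
    gwas = simulate_gwas_benchmark(net, planted, spec)
    return {"spec": spec, "net": net, "planted": planted, "gwas": gwas}


def random_graph(n_nodes: int, p: float, seed: int, connected: bool = False) -> nx.Graph:
    """Erdos-Renyi graph with string labels matching the package convention."""
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    if connected and not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        for c1, c2 in zip(comps, comps[1:]):
            g.add_edge(min(c1), min(c2))
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
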