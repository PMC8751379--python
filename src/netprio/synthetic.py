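"""Synthetic benchmark generator.

Produces interactomes, GWAS locus tables, drug-target networks and
expression matrices with the statistical structure the inference assumes:
a sparse scale-free background graph, a planted gene module whose members
are densely interconnected (the "causal genes cluster in the network"
assumption), loci whose candidate lists contain one planted gene plus
degree-matched decoys, and drugs whose targets are either proximal or
distal to the planted module. Every generator is a pure function of its
spec and seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import degree_bins
from .prioritize import GwasLocus, Locus, LocusTable, build_candidate_sets

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkSpec",
    "simulate_interactome_with_module",
    "SimulatedGwas",
    "simulate_gwas_benchmark",
    "simulate_drug_target_network",
    "simulate_expression_matrix",
    "write_benchmark",
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions for the synthetic benchmark.

    Defaults: a 500-node preferential-attachment interactome (2 edges per
    new node), 20 loci with 5 candidates each, planted module at internal
    edge density 0.3, and a 5-proximal / 45-distal drug library with 6
    targets per drug (the target-set size of a typical multi-target
    FDA-approved drug in curated drug-target networks).
    """

    n_nodes: int = 500
    attachment: int = 2
    n_loci: int = 20
    candidates_per_locus: int = 5
    planted_module_density: float = 0.3
    n_proximal_drugs: int = 5
    n_distal_drugs: int = 45
    targets_per_drug: int = 6
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if min(
            self.n_nodes, self.attachment, self.n_loci,
            self.candidates_per_locus, self.targets_per_drug,
        ) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 < self.planted_module_density <= 1.0:
            raise ValueError("planted_module_density must be in (0, 1]")
        if self.n_nodes <= self.n_loci:
            raise ValueError("n_nodes must exceed the planted module size")


def _gene_id(i: int) -> str:
    # Entrez-like numeric identifiers, offset so they never collide with
    # chromosome labels or SNP names.
    return str(10_001 + i)


def simulate_interactome_with_module(
    spec: BenchmarkSpec,
) -> tuple[nx.Graph, list[str]]:
    """Scale-free background graph with a densely wired planted module.

    A Barabasi-Albert graph on ``n_nodes`` nodes is generated, a module of
    ``n_loci`` genes is chosen uniformly at random, and edges are added
    among module members until their internal density reaches
    ``planted_module_density`` (density 1 yields a clique). Node labels are
    Entrez-like strings.
    """
    rng = np.random.default_rng(spec.rng_seed)
    g0 = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=spec.rng_seed)
    g = nx.relabel_nodes(g0, {i: _gene_id(i) for i in g0.nodes})
    planted = sorted(
        _gene_id(i)
        for i in rng.choice(spec.n_nodes, size=spec.n_loci, replace=False)
    )
    k = len(planted)
    target_edges = int(np.ceil(spec.planted_module_density * k * (k - 1) / 2))
    internal = [
        (a, b) for a, b in itertools.combinations(planted, 2) if g.has_edge(a, b)
    ]
    missing = [
        (a, b) for a, b in itertools.combinations(planted, 2) if not g.has_edge(a, b)
    ]
    need = target_edges - len(internal)
    if need > len(missing):
        raise ValueError("requested module density infeasible")
    if need > 0:
        picks = rng.choice(len(missing), size=need, replace=False)
        g.add_edges_from(missing[i] for i in picks)
    return g, planted


@dataclass
class SimulatedGwas:
    """A synthetic GWAS benchmark plus the tables it round-trips through."""

    locus_table: LocusTable
    truth: dict[str, str]  # snp_id -> planted gene
    loci_frame: pd.DataFrame = field(repr=False)
    annotation_frame: pd.DataFrame = field(repr=False)


def simulate_gwas_benchmark(
    net: nx.Graph, planted: list[str], spec: BenchmarkSpec
) -> SimulatedGwas:
    """Loci whose candidate lists hide one planted gene among matched decoys.

    Locus i gets its own chromosome with an index SNP; the planted gene and
    ``candidates_per_locus - 1`` decoy genes receive TSS coordinates inside
    the 2-Mb window at random offsets (so the true gene is not positionally
    identifiable). Decoys are drawn, without replacement across loci, from
    non-planted nodes in the same degree bin as the planted gene, using the
    shared log-degree binning — the same matching the permutation nulls use.
    All remaining network genes are annotated on a background chromosome so
    the tables cover the full node set and round-trip through
    ``build_candidate_sets`` exactly.
    """
    if len(planted) < spec.n_loci:
        raise ValueError("not enough planted genes for the requested loci")
    rng = np.random.default_rng(spec.rng_seed + 1)
    bins = degree_bins(net)
    non_planted = sorted(set(net.nodes) - set(planted))
    used: set[str] = set(planted)
    loci_rows, ann_rows = [], []
    truth: dict[str, str] = {}
    snp_pos = 50_000_000
    half = 1_000_000
    for i in range(spec.n_loci):
        true_gene = planted[i]
        chrom = f"chr{i + 1}"
        snp_id = f"rs{i + 1:04d}"
        truth[snp_id] = true_gene
        n_decoys = spec.candidates_per_locus - 1
        b = bins.bin_of[true_gene]
        pool = [g for g in bins.members[b] if g in set(non_planted) and g not in used]
        if len(pool) < n_decoys:
            wider = [g for g in non_planted if g not in used]
            extra = [g for g in wider if g not in pool]
            pool = pool + extra
        if len(pool) < n_decoys:
            raise ValueError("not enough decoy genes available")
        decoys = [pool[j] for j in rng.choice(len(pool), size=n_decoys, replace=False)]
        used.update(decoys)
        members = [true_gene] + decoys
        offsets = rng.choice(np.arange(-half, half + 1, 1000), size=len(members), replace=False)
        for g, off in zip(members, offsets):
            ann_rows.append(
                {"gene_id": g, "symbol": f"G{g}", "chr": chrom, "tss": snp_pos + int(off)}
            )
        loci_rows.append(
            {"snp_id": snp_id, "chr": chrom, "pos": snp_pos, "pval": 1e-6}
        )
    # background annotation for genes not at any locus
    leftover = sorted(set(net.nodes) - {r["gene_id"] for r in ann_rows})
    for j, g in enumerate(leftover):
        ann_rows.append(
            {"gene_id": g, "symbol": f"G{g}", "chr": "chr_bg", "tss": 1_000 + 10_000 * j}
        )
    loci_frame = pd.DataFrame(loci_rows)
    ann_frame = pd.DataFrame(ann_rows)
    table = build_candidate_sets(
        loci_frame, ann_frame, window_bp=2_000_000, max_candidates=20
    )
    return SimulatedGwas(
        locus_table=table, truth=truth, loci_frame=loci_frame, annotation_frame=ann_frame
    )


def simulate_drug_target_network(
    net: nx.Graph, planted: list[str], spec: BenchmarkSpec
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Drug library split into module-proximal and module-distal drugs.

    Proximal drugs draw targets from the planted module and its one-hop
    neighborhood; distal drugs draw targets at least 3 hops from every
    planted gene, degree-matched to the proximal pool's degree bins where
    possible. Returns the drug -> target map and the truth labels
    ("proximal" / "distal").
    """
    if spec.n_proximal_drugs + spec.n_distal_drugs < 1:
        raise ValueError("need at least one drug")
    rng = np.random.default_rng(spec.rng_seed + 2)
    dist = nx.multi_source_dijkstra_path_length(net, set(planted))
    prox_pool = sorted(n for n, d in dist.items() if d <= 1)
    dist_pool = sorted(
        [n for n, d in dist.items() if d >= 3]
        + [n for n in net.nodes if n not in dist]
    )
    if len(prox_pool) < spec.targets_per_drug or len(dist_pool) < spec.targets_per_drug:
        raise ValueError("module neighborhood or distal pool too small")
    bins = degree_bins(net)
    dist_by_bin: dict[int, list[str]] = {}
    for n in dist_pool:
        dist_by_bin.setdefault(bins.bin_of[n], []).append(n)
    drugs: dict[str, set[str]] = {}
    truth: dict[str, str] = {}
    for i in range(spec.n_proximal_drugs):
        name = f"drugP{i + 1:02d}"
        picks = rng.choice(len(prox_pool), size=spec.targets_per_drug, replace=False)
        drugs[name] = {prox_pool[j] for j in picks}
        truth[name] = "proximal"
    for i in range(spec.n_distal_drugs):
        name = f"drugD{i + 1:02d}"
        targets: set[str] = set()
        while len(targets) < spec.targets_per_drug:
            template = prox_pool[rng.integers(len(prox_pool))]
            pool = dist_by_bin.get(bins.bin_of[template]) or dist_pool
            targets.add(pool[rng.integers(len(pool))])
        drugs[name] = targets
        truth[name] = "distal"
    return drugs, truth


def simulate_expression_matrix(
    genes: list[str],
    n_columns: int = 10,
    rng_seed: int = 0,
    log_mean: float = 1.0,
    log_sd: float = 1.0,
) -> pd.DataFrame:
    """Lognormal genes x tissues/samples matrix for expression-layer tests."""
    rng = np.random.default_rng(rng_seed)
    vals = rng.lognormal(log_mean, log_sd, size=(len(genes), n_columns))
    return pd.DataFrame(
        vals, index=[str(g) for g in genes],
        columns=[f"t{i + 1}" for i in range(n_columns)],
    )


def write_benchmark(out_dir, spec: BenchmarkSpec) -> dict[str, str]:
    """Write a full benchmark (net, loci, annotations, drug targets, truth).

    Returns the mapping of logical names to file paths. Files are plain TSV
    (plus truth.json) and round-trip through the package loaders.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, planted = simulate_interactome_with_module(spec)
    gwas = simulate_gwas_benchmark(net, planted, spec)
    drugs, drug_truth = simulate_drug_target_network(net, planted, spec)
    paths = {}
    p = out / "net.tsv"
    with p.open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")
    paths["net"] = str(p)
    p = out / "loci.tsv"
    gwas.loci_frame.to_csv(p, sep="\t", index=False)
    paths["loci"] = str(p)
    p = out / "genes.tsv"
    gwas.annotation_frame.to_csv(p, sep="\t", index=False)
    paths["genes"] = str(p)
    p = out / "drug_targets.tsv"
    with p.open("w") as fh:
        fh.write("drug_id\ttarget\n")
        for d in sorted(drugs):
            for t in sorted(drugs[d]):
                fh.write(f"{d}\t{t}\n")
    paths["drug_targets"] = str(p)
    p = out / "truth.json"
    p.write_text(
        json.dumps(
            {"planted_genes": planted, "locus_truth": gwas.truth, "drug_truth": drug_truth},
            indent=1,
        )
    )
    paths["truth"] = str(p)
    return paths
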