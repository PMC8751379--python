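"""Interactome handling: I/O, connectivity, and degree-preserving randomization.

The protein-protein interactome is represented as an undirected
:class:`networkx.Graph` with string node identifiers (Entrez gene IDs in
real data; any opaque identifier in synthetic fixtures). No self-loops, no
parallel edges, no edge weights — shortest-path distances are hop counts.

Degree-preserving randomization draws random gene sets that match an input
set's size and degree distribution, the null model behind both the disease
module (largest connected component) significance test and the network
proximity z-score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "load_interactome",
    "load_gene_set",
    "largest_connected_component",
    "DegreeBins",
    "degree_bins",
    "degree_preserving_sample",
    "ModuleSignificance",
    "module_significance",
]


def _looks_like_header(fields: list[str]) -> bool:
    # Entrez IDs are positive integers; a non-numeric first row is a header.
    return not all(f.strip().lstrip("-").isdigit() for f in fields[:2])


def load_interactome(path: str | Path) -> nx.Graph:
    """Load an undirected interactome from a two-column edge-list TSV.

    Duplicate pairs (in either orientation) are collapsed to a single
    undirected edge and self-loops are dropped; both are counted in the log.
    An optional header row is auto-detected (non-numeric first row). Rows
    with fewer than two fields are skipped with a warning.

    Parameters
    ----------
    path : str or Path
        Tab-separated file whose first two columns are gene identifiers.

    Returns
    -------
    networkx.Graph
        Simple undirected graph with string node ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interactome file not found: {path}")
    g: nx.Graph = nx.Graph()
    n_self, n_bad, n_dup = 0, 0, 0
    with path.open() as fh:
        first = True
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space/comma-separated input
                fields = line.replace(",", " ").split()
            if first:
                first = False
                if _looks_like_header(fields):
                    continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                n_bad += 1
                continue
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_bad:
        logger.warning("skipped %d unparsable rows in %s", n_bad, path)
    if n_self:
        logger.warning("dropped %d self-loop rows in %s", n_self, path)
    if n_dup:
        logger.info("collapsed %d duplicate pairs in %s", n_dup, path)
    logger.info(
        "loaded interactome %s: %d nodes, %d edges",
        path.name, g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def load_gene_set(path: str | Path) -> set[str]:
    """Read a gene-set file: one identifier per line, '#' comments allowed."""
    genes: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    return genes


def largest_connected_component(
    net: nx.Graph, genes: set[str]
) -> tuple[set[str], int]:
    """Largest connected component of the subgraph induced by ``genes``.

    Genes absent from the network are dropped with a warning. Ties between
    equal-size components are broken by the lexicographically smallest
    sorted node-id tuple, so the result is deterministic.

    Returns
    -------
    (node set, edge count)
        Nodes of the LCC and the number of edges internal to it. Empty set
        and 0 if no input gene is present in the network.
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    present = set(genes) & set(net.nodes)
    missing = len(genes) - len(present)
    if missing:
        logger.warning("%d of %d genes absent from interactome", missing, len(genes))
    if not present:
        logger.warning("no input gene present in the interactome")
        return set(), 0
    sub = net.subgraph(present)
    comps = list(nx.connected_components(sub))
    max_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == max_size]
    best = min(tied, key=lambda c: tuple(sorted(c)))
    n_edges = sub.subgraph(best).number_of_edges()
    return set(best), n_edges


@dataclass
class DegreeBins:
    """Logarithmic degree bins over the nodes of one interactome.

    Bin *k* nominally covers degrees ``[2**k, 2**(k+1))``; bins with fewer
    than ``min_bin_size`` members are merged into their lower neighbor so
    every bin can support degree-matched resampling.
    """

    bin_of: dict[str, int]
    members: dict[int, list[str]] = field(repr=False)
    bin_edges: list[int] = field(default_factory=list)

    def bin_histogram(self, genes: set[str]) -> dict[int, int]:
        """Count of ``genes`` per bin (genes must all be binned)."""
        hist: dict[int, int] = {}
        for g in genes:
            b = self.bin_of[g]
            hist[b] = hist.get(b, 0) + 1
        return hist


def degree_bins(net: nx.Graph, min_bin_size: int = 20) -> DegreeBins:
    """Partition the network's nodes into log2 degree bins.

    Degree-0 and degree-1 nodes share bin 0. Underpopulated bins
    (< ``min_bin_size`` members) are merged downward (the lowest bin merges
    upward), which keeps every bin usable as a resampling pool.
    """
    raw: dict[int, list[str]] = {}
    for node in net.nodes:
        d = net.degree[node]
        k = int(math.floor(math.log2(d))) if d >= 1 else 0
        raw.setdefault(k, []).append(node)
    ks = sorted(raw)
    # merge small bins into their lower neighbor; smallest bin merges up
    merged: list[tuple[list[int], list[str]]] = []
    for k in ks:
        if merged and len(merged[-1][1]) < min_bin_size:
            merged[-1][0].append(k)
            merged[-1][1].extend(raw[k])
        else:
            merged.append(([k], list(raw[k])))
    if len(merged) > 1 and len(merged[-1][1]) < min_bin_size:
        ks2, mem = merged.pop()
        merged[-1][0].extend(ks2)
        merged[-1][1].extend(mem)
    bin_of: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    edges: list[int] = []
    for i, (ks2, mem) in enumerate(merged):
        edges.append(2 ** min(ks2))
        members[i] = sorted(mem)
        for n in mem:
            bin_of[n] = i
    return DegreeBins(bin_of=bin_of, members=members, bin_edges=edges)


def degree_preserving_sample(
    net: nx.Graph,
    genes: set[str],
    bins: DegreeBins | None = None,
    rng: np.random.Generator | int | None = None,
) -> set[str]:
    """Draw a random gene set with the same size and degree profile as ``genes``.

    For each input gene one replacement is drawn, without replacement, from
    the same degree bin. Bin membership lists are sorted so the draw is a
    pure function of the seed, independent of graph construction order.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if bins is None:
        bins = degree_bins(net)
    missing = [g for g in genes if g not in bins.bin_of]
    if missing:
        raise ValueError(f"genes not in network/bins: {sorted(missing)[:5]} ...")
    out: set[str] = set()
    hist = bins.bin_histogram(set(genes))
    for b in sorted(hist):
        need = hist[b]
        pool = bins.members[b]
        if need > len(pool):
            # degenerate externally-supplied bins: widen to neighbors
            logger.warning("bin %d smaller than requested draw; merging neighbors", b)
            pool = sorted(
                set(pool)
                | set(bins.members.get(b - 1, []))
                | set(bins.members.get(b + 1, []))
            )
        picks = rng.choice(len(pool), size=need, replace=need > len(pool))
        out.update(pool[i] for i in picks)
    # collisions across widened bins are possible only in the degenerate path
    while len(out) < len(genes):
        extra = rng.choice(sorted(net.nodes))
        out.add(str(extra))
    return out


@dataclass
class ModuleSignificance:
    """Permutation test of disease-module (LCC) size against a degree-preserving null."""

    observed_lcc_size: int
    observed_lcc_edges: int
    null_lcc_sizes: list[int]
    p_value: float

    @property
    def n_perm(self) -> int:
        return len(self.null_lcc_sizes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed": self.observed_lcc_size,
                "observed_edges": self.observed_lcc_edges,
                "n_perm": self.n_perm,
                "p_value": self.p_value,
            }
        )


def module_significance(
    net: nx.Graph,
    genes: set[str],
    n_perm: int = 1000,
    rng_seed: int | None = None,
    bins: DegreeBins | None = None,
) -> ModuleSignificance:
    """Test whether ``genes`` form a larger connected module than chance.

    The null draws ``n_perm`` degree-preserving random gene sets and records
    each one's LCC size; the one-sided p-value uses the add-one estimator
    ``(r + 1) / (n_perm + 1)`` where ``r`` counts null LCCs >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = set(genes) & set(net.nodes)
    if not present:
        raise ValueError("no input gene present in the interactome")
    obs_nodes, obs_edges = largest_connected_component(net, present)
    rng = np.random.default_rng(rng_seed)
    if bins is None:
        bins = degree_bins(net)
    null_sizes: list[int] = []
    for _ in range(n_perm):
        sample = degree_preserving_sample(net, present, bins=bins, rng=rng)
        lcc, _ = largest_connected_component(net, sample)
        null_sizes.append(len(lcc))
    r = sum(1 for s in null_sizes if s >= len(obs_nodes))
    p = (r + 1) / (n_perm + 1)
    return ModuleSignificance(
        observed_lcc_size=len(obs_nodes),
        observed_lcc_edges=obs_edges,
        null_lcc_sizes=null_sizes,
        p_value=p,
    )
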