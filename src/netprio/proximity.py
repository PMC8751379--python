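"""Network proximity between a disease module and drug target sets.

The closest distance between disease proteins A and drug targets B is

    <d_AB> = 1/(|A| + |B|) ( sum_{a in A} min_{b in B} d(a,b)
                           + sum_{b in B} min_{a in A} d(a,b) )

with d(a, b) the unweighted shortest-path length in the interactome.
Significance comes from a degree-preserving permutation null: random sets
matched to A and B in size and degree distribution, giving
z = (d_observed - null_mean) / null_sd. Drugs with z below a cutoff
(-1.5 by convention) are flagged as network-predicted repurposing
candidates.

Pairs in different components have no finite distance; such terms are
excluded from both the numerator and the effective denominator, keeping
<d_AB> finite. A configuration with no finite pair at all is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .graph import DegreeBins, degree_bins, degree_preserving_sample

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceCache",
    "closest_distance",
    "ProximityResult",
    "proximity_z",
    "ProximityScreen",
    "ProximityScreenResults",
]

_DENSE_LIMIT = 5000  # precompute the full hop-distance matrix below this size


class DistanceCache:
    """All-pairs unweighted shortest-path lengths for one interactome.

    Dense BFS matrix (scipy csgraph) for graphs up to ``_DENSE_LIMIT``
    nodes; per-source BFS on demand above that. Caching is an optimization
    only — results are identical with or without it.
    """

    def __init__(self, net: nx.Graph):
        self.net = net
        self.nodes = sorted(net.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self._dense: np.ndarray | None = None
        self._bfs_cache: dict[str, dict[str, int]] = {}
        if len(self.nodes) <= _DENSE_LIMIT:
            adj = nx.adjacency_matrix(net, nodelist=self.nodes)
            self._dense = shortest_path(
                sp.csr_matrix(adj), method="D", unweighted=True, directed=False
            )

    def submatrix(self, a: list[str], b: list[str]) -> np.ndarray:
        """|a| x |b| matrix of hop distances (inf for disconnected pairs)."""
        ia = np.array([self.index[x] for x in a], dtype=int)
        ib = np.array([self.index[x] for x in b], dtype=int)
        if self._dense is not None:
            return self._dense[np.ix_(ia, ib)]
        src = a if len(a) <= len(b) else b
        out = np.full((len(a), len(b)), np.inf)
        for s in src:
            if s not in self._bfs_cache:
                self._bfs_cache[s] = nx.single_source_shortest_path_length(self.net, s)
            dd = self._bfs_cache[s]
            if len(a) <= len(b):
                i = a.index(s)
                for j, t in enumerate(b):
                    if t in dd:
                        out[i, j] = dd[t]
            else:
                j = b.index(s)
                for i, t in enumerate(a):
                    if t in dd:
                        out[i, j] = dd[t]
        return out


def _map_sets(net: nx.Graph, a: set[str], b: set[str]) -> tuple[list[str], list[str]]:
    a_in = sorted(set(a) & set(net.nodes))
    b_in = sorted(set(b) & set(net.nodes))
    if len(a_in) < len(a):
        logger.warning("%d of %d disease genes unmapped", len(a) - len(a_in), len(a))
    if len(b_in) < len(b):
        logger.warning("%d of %d targets unmapped", len(b) - len(b_in), len(b))
    if not a_in or not b_in:
        raise ValueError("A or B has no member mapped into the network")
    return a_in, b_in


def closest_distance(
    net: nx.Graph,
    a: set[str],
    b: set[str],
    dist: DistanceCache | None = None,
) -> float:
    """Closest network distance <d_AB> between gene sets A and B.

    Symmetric in (A, B). Members absent from the network are dropped with a
    warning; infinite (cross-component) terms are excluded from numerator
    and denominator. Raises if either set is fully unmapped or no finite
    pair exists.
    """
    a_in, b_in = _map_sets(net, a, b)
    dist = dist or DistanceCache(net)
    d = dist.submatrix(a_in, b_in)
    min_a = d.min(axis=1)  # each a's nearest b
    min_b = d.min(axis=0)  # each b's nearest a
    terms = np.concatenate([min_a, min_b])
    finite = terms[np.isfinite(terms)]
    if finite.size == 0:
        raise ValueError("no finite distance between A and B (different components)")
    return float(finite.sum() / finite.size)


@dataclass
class ProximityResult:
    """Observed closest distance with its degree-preserving null summary."""

    drug_id: str
    d_observed: float
    null_mean: float
    null_sd: float
    z: float  # nan when null_sd == 0
    p_empirical: float
    n_perm: int
    n_targets_in_net: int
    degenerate_null: bool = False


def proximity_z(
    net: nx.Graph,
    a: set[str],
    b: set[str],
    n_perm: int = 1000,
    bins: DegreeBins | None = None,
    rng: np.random.Generator | int | None = None,
    dist: DistanceCache | None = None,
    randomize: str = "both",
    drug_id: str = "",
) -> ProximityResult:
    """Degree-preserving permutation z-score for the closest distance.

    The null resamples both A and B (``randomize="both"``, the default) or
    only B (``randomize="b"``) in matched degree bins, ``n_perm`` times
    (1000 by convention). z = (d_observed - mean) / sd of the null; the
    one-sided empirical p (null <= observed) uses the add-one estimator.
    Null draws with no finite pair are dropped with a warning.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if randomize not in ("both", "b"):
        raise ValueError("randomize must be 'both' or 'b'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a_in, b_in = _map_sets(net, a, b)
    dist = dist or DistanceCache(net)
    bins = bins or degree_bins(net)
    d_obs = closest_distance(net, set(a_in), set(b_in), dist=dist)
    null: list[float] = []
    n_dropped = 0
    for _ in range(n_perm):
        ra = (
            degree_preserving_sample(net, set(a_in), bins=bins, rng=rng)
            if randomize == "both"
            else set(a_in)
        )
        rb = degree_preserving_sample(net, set(b_in), bins=bins, rng=rng)
        try:
            null.append(closest_distance(net, ra, rb, dist=dist))
        except ValueError:
            n_dropped += 1
    if n_dropped:
        logger.warning("%d null draws had no finite distance; dropped", n_dropped)
    if len(null) < 2:
        raise ValueError("null distribution could not be formed")
    null_arr = np.array(null)
    mean, sd = float(null_arr.mean()), float(null_arr.std(ddof=1))
    degenerate = sd == 0.0
    z = float((d_obs - mean) / sd) if not degenerate else float("nan")
    p = (int(np.sum(null_arr <= d_obs)) + 1) / (len(null) + 1)
    return ProximityResult(
        drug_id=drug_id,
        d_observed=d_obs,
        null_mean=mean,
        null_sd=sd,
        z=z,
        p_empirical=p,
        n_perm=len(null),
        n_targets_in_net=len(b_in),
        degenerate_null=degenerate,
    )


def load_drug_targets(path) -> dict[str, set[str]]:
    """Read a drug-target TSV (drug_id, target gene id[, category]) into a map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("drug-target table needs at least two columns")
    drug_col, tgt_col = cols[0], cols[1]
    out: dict[str, set[str]] = {}
    for d, t in zip(df[drug_col], df[tgt_col]):
        if pd.isna(d) or pd.isna(t):
            continue
        out.setdefault(str(d), set()).add(str(t))
    return out


class ProximityScreen:
    """Screen a drug library against a disease module by network proximity.

    Parameters
    ----------
    interactome : networkx.Graph
    disease_genes : set of gene ids (the module A of the closest-distance
        measure; typically the inferred risk genes).
    drug_targets : mapping drug_id -> nonempty target gene set.
    z_cutoff : selection threshold on the proximity z-score (default -1.5).
    n_perm : permutations per drug for the null (default 1000).
    """

    def __init__(
        self,
        interactome: nx.Graph,
        disease_genes: set[str],
        drug_targets: dict[str, set[str]],
        z_cutoff: float = -1.5,
        n_perm: int = 1000,
        randomize: str = "both",
    ):
        if not drug_targets:
            raise ValueError("drug_targets is empty")
        for d, t in drug_targets.items():
            if not t:
                raise ValueError(f"drug {d} has an empty target set")
        self.interactome = interactome
        self.disease_genes = set(disease_genes)
        self.drug_targets = dict(drug_targets)
        self.z_cutoff = z_cutoff
        self.n_perm = n_perm
        self.randomize = randomize

    def fit(self, seed: int | None = None) -> "ProximityScreenResults":
        """Compute one ProximityResult per mappable drug, ranked by z.

        Each drug gets an independent child seed from a spawned
        ``SeedSequence``, so results do not depend on drug iteration order
        and the whole screen is reproducible from one seed.
        """
        dist = DistanceCache(self.interactome)
        bins = degree_bins(self.interactome)
        drug_ids = sorted(self.drug_targets)
        children = np.random.SeedSequence(seed).spawn(len(drug_ids))
        results: list[ProximityResult] = []
        skipped: dict[str, str] = {}
        for drug, ss in zip(drug_ids, children):
            targets = self.drug_targets[drug]
            try:
                res = proximity_z(
                    self.interactome,
                    self.disease_genes,
                    targets,
                    n_perm=self.n_perm,
                    bins=bins,
                    rng=np.random.default_rng(ss),
                    dist=dist,
                    randomize=self.randomize,
                    drug_id=drug,
                )
            except ValueError as exc:
                skipped[drug] = str(exc)
                logger.warning("drug %s skipped: %s", drug, exc)
                continue
            results.append(res)
        return ProximityScreenResults(self, results, skipped, seed=seed)


class ProximityScreenResults:
    """Ranked drug screening results with per-drug null summaries."""

    def __init__(
        self,
        model: ProximityScreen,
        results: list[ProximityResult],
        skipped: dict[str, str],
        seed: int | None = None,
    ):
        self.model = model
        self.results = sorted(results, key=lambda r: (np.isnan(r.z), r.z, r.drug_id))
        self.skipped = skipped
        self.seed = seed

    @property
    def table(self) -> pd.DataFrame:
        """Ranked table: drug_id, n_targets, d, null_mean, null_sd, z, p, selected."""
        rows = [
            {
                "drug_id": r.drug_id,
                "n_targets": r.n_targets_in_net,
                "d": r.d_observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "p": r.p_empirical,
                "selected": (not np.isnan(r.z)) and r.z < self.model.z_cutoff,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    @property
    def selected(self) -> list[str]:
        t = self.table
        return list(t.loc[t["selected"], "drug_id"])

    def summary(self) -> str:
        t = self.table
        lines = [
            "Network-proximity drug screen",
            "=" * 48,
            f"disease genes (A):   {len(self.model.disease_genes)}",
            f"drugs screened:      {len(self.results)}  (skipped: {len(self.skipped)})",
            f"permutations/drug:   {self.model.n_perm}",
            f"z cutoff:            {self.model.z_cutoff}",
            f"selected drugs:      {len(self.selected)}",
            "",
            "Most proximal drugs:",
        ]
        for _, r in t.head(10).iterrows():
            flag = "*" if r.selected else " "
            lines.append(
                f" {flag} {r.drug_id:<16} d={r.d:6.3f}  z={r.z:7.3f}  p={r.p:.4f}"
            )
        return "\n".join(lines)
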