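"""Bayesian model selection of GWAS risk genes by Gibbs sampling.

Each GWAS locus contributes a candidate list (genes whose transcription
start site lies in a window centered on the index SNP). One gene per locus
forms a candidate risk gene set; the model scores a candidate at locus l by
the odds

    P(M1 | X_-l, N) / P(M0 | X_-l, N)
        = prior_odds * P(X_-l | M1, N) / P(X_-l | M0, N)

where X_-l are the genes currently selected at the other loci and the Bayes
factor is realized as the summed RWR reachability from the candidate to
X_-l on the interactome (the alternative-model likelihood; the null-model
likelihood is assumed constant across candidates, so it cancels in the
normalization). A Gibbs sweep resamples every locus in turn from these
conditional odds; post-burn-in sampling frequencies estimate the posterior
confidence of each candidate being the risk gene at its locus.

The public surface is ``RiskGeneModel`` / ``RiskGeneResults``; the
lower-level functions (``build_candidate_sets``, ``bayes_factor_scores``,
``gibbs_sample``, ``select_risk_genes``) are exposed for testing and reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import module_significance
from .rwr import ProximityMatrix, RWRConfig, build_transition_matrix, rwr_proximity_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "GwasLocus",
    "Locus",
    "LocusTable",
    "GibbsConfig",
    "PosteriorTable",
    "RiskGeneSet",
    "build_candidate_sets",
    "bayes_factor_scores",
    "gibbs_sample",
    "select_risk_genes",
    "RiskGeneModel",
    "RiskGeneResults",
]


@dataclass(frozen=True)
class GwasLocus:
    """One GWAS index SNP."""

    snp_id: str
    chromosome: str
    position: int
    p_value: float = 1.0

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError("position must be positive")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must be in (0, 1]")


@dataclass
class Locus:
    """A locus with its candidate genes and TSS-to-SNP distances (bp)."""

    snp: GwasLocus
    candidates: list[str]
    tss_distance: dict[str, int]


@dataclass
class LocusTable:
    """Ordered loci, each with a nonempty candidate gene list."""

    loci: list[Locus]

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def candidate_universe(self) -> set[str]:
        return {g for loc in self.loci for g in loc.candidates}


def build_candidate_sets(
    loci: list[GwasLocus] | pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 2_000_000,
    max_candidates: int = 20,
) -> LocusTable:
    """Assign candidate genes to each GWAS locus by TSS proximity.

    A gene is a candidate for a locus when its TSS lies within
    ``window_bp / 2`` of the index SNP on the same chromosome (closed
    interval: a TSS exactly at the window edge is included). Lists longer
    than ``max_candidates`` keep the genes nearest the SNP, ties broken by
    smaller gene id. Loci with no candidate are dropped with a warning.

    Parameters
    ----------
    loci : list of GwasLocus or DataFrame with columns snp_id, chr, pos[, pval]
    genes : DataFrame with columns gene_id, chr, tss (symbol optional)
    """
    if isinstance(loci, pd.DataFrame):
        loci = [
            GwasLocus(
                snp_id=str(r["snp_id"]),
                chromosome=str(r["chr"]),
                position=int(r["pos"]),
                p_value=float(r["pval"]) if "pval" in r and pd.notna(r["pval"]) else 1.0,
            )
            for r in loci.to_dict("records")
        ]
    if not loci:
        raise ValueError("loci must be nonempty")
    if genes.empty:
        raise ValueError("gene annotation table is empty")
    ann = genes.assign(
        gene_id=genes["gene_id"].astype(str),
        chr=genes["chr"].astype(str),
        tss=genes["tss"].astype(int),
    )
    by_chrom = {c: d for c, d in ann.groupby("chr")}
    half = window_bp // 2
    out: list[Locus] = []
    for snp in loci:
        sub = by_chrom.get(snp.chromosome)
        if sub is None:
            logger.warning("locus %s: no annotated genes on %s; dropped", snp.snp_id, snp.chromosome)
            continue
        dist = (sub["tss"] - snp.position).abs()
        in_win = sub[dist <= half].copy()
        if in_win.empty:
            logger.warning("locus %s: no gene within window; dropped", snp.snp_id)
            continue
        in_win["dist"] = (in_win["tss"] - snp.position).abs()
        in_win = in_win.sort_values(["dist", "gene_id"]).head(max_candidates)
        out.append(
            Locus(
                snp=snp,
                candidates=list(in_win["gene_id"]),
                tss_distance=dict(zip(in_win["gene_id"], in_win["dist"].astype(int))),
            )
        )
    if not out:
        raise ValueError("no locus retained any candidate gene")
    return LocusTable(loci=out)


@dataclass(frozen=True)
class GibbsConfig:
    """Gibbs sampler settings.

    prior_odds : P(M1)/P(M0); 1 encodes the flat prior P(M1) = P(M0).
    tol : halting threshold on the sum over currently selected genes of
        squared frequency differences between consecutive rounds (1e-4).
    max_rounds : sweep cap; reaching it without convergence is a warning,
        not an error.
    burn_in : sweeps discarded before frequencies accumulate.
    freq_mode : "cumulative" compares cumulative post-burn-in frequencies
        between rounds; "round" compares single-round frequencies.
    """

    prior_odds: float = 1.0
    tol: float = 1e-4
    max_rounds: int = 200
    burn_in: int = 10
    freq_mode: str = "cumulative"

    def __post_init__(self) -> None:
        if self.prior_odds <= 0 or self.tol < 0:
            raise ValueError("prior_odds must be > 0 and tol >= 0")
        if self.freq_mode not in ("cumulative", "round"):
            raise ValueError("freq_mode must be 'cumulative' or 'round'")


@dataclass
class PosteriorTable:
    """Per-locus sampling frequencies from the Gibbs chain."""

    frequencies: list[dict[str, float]]  # one dict per locus, sums to 1
    rounds_used: int
    converged: bool


def bayes_factor_scores(
    w: ProximityMatrix,
    candidates: list[str],
    selected_others: list[str],
    prior_odds: float = 1.0,
    _warned: set | None = None,
) -> dict[str, float]:
    """Posterior sampling weights for one locus's candidates.

    Raw score of candidate g = prior_odds * sum_{x in X_-l} W[g, x]; weights
    are the raw scores normalized over the candidate list. A candidate with
    no RWR row (absent from the network) scores 0. If every raw score is 0
    (e.g. first sweep with disconnected candidates) the weights fall back
    to uniform so the sampler cannot stall.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    others = [x for x in selected_others if x in w._col_index]
    raw = np.zeros(len(candidates))
    if others:
        cols = w.col_indices(others)
        for i, g in enumerate(candidates):
            if not w.has_row(g):
                if _warned is not None and g not in _warned:
                    logger.warning("candidate %s has no RWR row; scored 0", g)
                    _warned.add(g)
                continue
            raw[i] = prior_odds * w.row(g)[cols].sum()
    total = raw.sum()
    if total <= 0:
        weights = np.full(len(candidates), 1.0 / len(candidates))
    else:
        weights = raw / total
    return dict(zip(candidates, weights))


def gibbs_sample(
    table: LocusTable,
    w: ProximityMatrix,
    cfg: GibbsConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> PosteriorTable:
    """Run the Gibbs chain over all loci and return sampling frequencies.

    One gene per locus is initialized uniformly at random. Each round sweeps
    the loci in order, resampling locus l from ``bayes_factor_scores``
    conditional on the current selections elsewhere. After ``burn_in``
    rounds, per-candidate selection frequencies accumulate; the chain halts
    when the sum over currently selected genes of squared frequency changes
    between consecutive rounds drops below ``cfg.tol``.
    """
    cfg = cfg or GibbsConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_loci = len(table)
    if n_loci == 0:
        raise ValueError("empty locus table")
    for loc in table.loci:
        if not loc.candidates:
            raise ValueError(f"locus {loc.snp.snp_id} has no candidates")

    current = [loc.candidates[rng.integers(len(loc.candidates))] for loc in table.loci]
    counts = [dict.fromkeys(loc.candidates, 0) for loc in table.loci]
    prev_freq: list[dict[str, float]] | None = None
    warned: set = set()
    converged = False
    rounds_done = 0

    for rnd in range(1, cfg.max_rounds + 1):
        for li, loc in enumerate(table.loci):
            others = [g for lj, g in enumerate(current) if lj != li]
            weights = bayes_factor_scores(
                w, loc.candidates, others, cfg.prior_odds, _warned=warned
            )
            probs = np.array([weights[g] for g in loc.candidates])
            pick = rng.choice(len(loc.candidates), p=probs)
            current[li] = loc.candidates[pick]
        rounds_done = rnd
        if rnd <= cfg.burn_in:
            continue
        n_acc = rnd - cfg.burn_in
        if cfg.freq_mode == "round":
            freq = [
                {g: (1.0 if g == current[li] else 0.0) for g in loc.candidates}
                for li, loc in enumerate(table.loci)
            ]
            for li in range(n_loci):
                counts[li][current[li]] += 1
        else:
            for li in range(n_loci):
                counts[li][current[li]] += 1
            freq = [
                {g: counts[li][g] / n_acc for g in table.loci[li].candidates}
                for li in range(n_loci)
            ]
        if prev_freq is not None:
            stat = sum(
                (freq[li][current[li]] - prev_freq[li][current[li]]) ** 2
                for li in range(n_loci)
            )
            if stat < cfg.tol:
                converged = True
                prev_freq = freq
                break
        prev_freq = freq

    if not converged:
        logger.warning(
            "Gibbs sampler hit max_rounds=%d without meeting tol=%g",
            cfg.max_rounds, cfg.tol,
        )
    n_acc = max(rounds_done - cfg.burn_in, 1)
    frequencies = [
        {g: counts[li][g] / n_acc for g in table.loci[li].candidates}
        for li in range(n_loci)
    ]
    # guard: each locus's frequencies are a distribution
    for li, f in enumerate(frequencies):
        s = sum(f.values())
        if s > 0 and abs(s - 1.0) > 1e-9:
            frequencies[li] = {g: v / s for g, v in f.items()}
    return PosteriorTable(frequencies=frequencies, rounds_used=rounds_done, converged=converged)


@dataclass
class RiskGeneSet:
    """Selected risk genes, per-locus choices and local background genes."""

    risk_genes: set[str]
    per_locus_choice: dict[str, str]  # snp_id -> gene
    background_genes: set[str]


def select_risk_genes(post: PosteriorTable, table: LocusTable) -> RiskGeneSet:
    """Pick each locus's maximum-frequency candidate and derive LBGs.

    Ties break toward the candidate whose TSS is nearer the index SNP, then
    toward the smaller gene id. Risk genes selected at several loci are
    merged (counted once); local background genes (LBGs) are every candidate
    never selected at any locus — the matched negative-control set.
    """
    if len(post.frequencies) != len(table):
        raise ValueError("posterior does not cover the locus table")
    choice: dict[str, str] = {}
    for li, loc in enumerate(table.loci):
        freq = post.frequencies[li]
        best = min(
            loc.candidates,
            key=lambda g: (-freq[g], loc.tss_distance.get(g, 0), g),
        )
        choice[loc.snp.snp_id] = best
    risk = set(choice.values())
    background = table.candidate_universe - risk
    return RiskGeneSet(risk_genes=risk, per_locus_choice=choice, background_genes=background)


class RiskGeneModel:
    """Bayesian network model for GWAS risk-gene inference.

    Couples a locus/candidate table to an interactome; ``fit`` computes the
    RWR proximity kernel for the candidate genes and runs the Gibbs sampler.

    Parameters
    ----------
    interactome : networkx.Graph
        Undirected protein-protein interaction network.
    locus_table : LocusTable
        Loci with candidate gene lists (see ``build_candidate_sets``).
    rwr_config, gibbs_config : optional
        Propagation and sampler settings; defaults are r = 0.3,
        T_rwr = 1e-6, flat prior odds, halting threshold 1e-4.
    """

    def __init__(
        self,
        interactome: nx.Graph,
        locus_table: LocusTable,
        rwr_config: RWRConfig | None = None,
        gibbs_config: GibbsConfig | None = None,
    ):
        self.interactome = interactome
        self.locus_table = locus_table
        self.rwr_config = rwr_config or RWRConfig()
        self.gibbs_config = gibbs_config or GibbsConfig()

    @classmethod
    def from_tables(
        cls,
        loci: pd.DataFrame,
        annotations: pd.DataFrame,
        interactome: nx.Graph,
        window_bp: int = 2_000_000,
        max_candidates: int = 20,
        rwr_config: RWRConfig | None = None,
        gibbs_config: GibbsConfig | None = None,
    ) -> "RiskGeneModel":
        """Construct from a GWAS SNP table and a gene-annotation table."""
        table = build_candidate_sets(loci, annotations, window_bp, max_candidates)
        return cls(interactome, table, rwr_config, gibbs_config)

    def _proximity_rows(self) -> ProximityMatrix:
        tm = build_transition_matrix(self.interactome)
        rows = {
            g for g in self.locus_table.candidate_universe if g in tm.index
        }
        missing = self.locus_table.candidate_universe - rows
        if missing:
            logger.warning(
                "%d candidate genes absent from the interactome", len(missing)
            )
        if not rows:
            raise ValueError("no candidate gene is present in the interactome")
        return rwr_proximity_matrix(tm, self.rwr_config, restrict_rows=rows)

    def fit(self, seed: int | None = None) -> "RiskGeneResults":
        """Run RWR propagation and Gibbs sampling; return results."""
        w = self._proximity_rows()
        rng = np.random.default_rng(seed)
        post = gibbs_sample(self.locus_table, w, self.gibbs_config, rng)
        selection = select_risk_genes(post, self.locus_table)
        return RiskGeneResults(self, post, selection, seed=seed)


class RiskGeneResults:
    """Fitted risk-gene inference: posterior frequencies, selections, diagnostics."""

    def __init__(
        self,
        model: RiskGeneModel,
        posterior: PosteriorTable,
        selection: RiskGeneSet,
        seed: int | None = None,
    ):
        self.model = model
        self.posterior = posterior
        self.selection = selection
        self.seed = seed

    @property
    def risk_genes(self) -> set[str]:
        return self.selection.risk_genes

    @property
    def background_genes(self) -> set[str]:
        """Local background genes: candidates never selected at any locus."""
        return self.selection.background_genes

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    @property
    def rounds_used(self) -> int:
        return self.posterior.rounds_used

    def posterior_frame(self) -> pd.DataFrame:
        """Long-format posterior: snp_id, gene, frequency, selected."""
        rows = []
        for li, loc in enumerate(self.model.locus_table.loci):
            chosen = self.selection.per_locus_choice[loc.snp.snp_id]
            for g, f in sorted(
                self.posterior.frequencies[li].items(), key=lambda kv: -kv[1]
            ):
                rows.append(
                    {
                        "snp_id": loc.snp.snp_id,
                        "gene": g,
                        "frequency": f,
                        "tss_distance": loc.tss_distance.get(g, pd.NA),
                        "selected": g == chosen,
                    }
                )
        return pd.DataFrame(rows)

    def gene_confidence(self) -> pd.DataFrame:
        """Per-gene confidence: max sampling frequency over loci."""
        df = self.posterior_frame()
        conf = (
            df.groupby("gene")["frequency"].max().sort_values(ascending=False)
        )
        return conf.rename("confidence").reset_index()

    def module_significance(
        self, n_perm: int = 1000, seed: int | None = None
    ):
        """Permutation test of the risk genes' LCC in the interactome."""
        return module_significance(
            self.model.interactome, self.risk_genes, n_perm=n_perm, rng_seed=seed
        )

    def summary(self) -> str:
        lines = [
            "Risk-gene inference (Gibbs sampling, RWR Bayes factors)",
            "=" * 56,
            f"loci:                {len(self.model.locus_table)}",
            f"candidate genes:     {len(self.model.locus_table.candidate_universe)}",
            f"risk genes:          {len(self.risk_genes)}",
            f"background genes:    {len(self.background_genes)}",
            f"rounds used:         {self.rounds_used}",
            f"converged:           {self.converged}",
            f"restart prob r:      {self.model.rwr_config.restart_prob}",
            f"halting threshold:   {self.model.gibbs_config.tol}",
            "",
            "Top selections by posterior frequency:",
        ]
        df = self.posterior_frame()
        top = df[df["selected"]].sort_values("frequency", ascending=False).head(10)
        for _, r in top.iterrows():
            lines.append(f"  {r.snp_id:<16} {r.gene:<12} freq={r.frequency:.3f}")
        return "\n".join(lines)
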