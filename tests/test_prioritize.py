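"""Candidate-set construction, Bayes factors, Gibbs sampling, selection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprio.prioritize import (
    GibbsConfig,
    GwasLocus,
    Locus,
    LocusTable,
    RiskGeneModel,
    bayes_factor_scores,
    build_candidate_sets,
    gibbs_sample,
    select_risk_genes,
)
from netprio.rwr import RWRConfig, build_transition_matrix, rwr_proximity_matrix
from netprio.synthetic import (
    BenchmarkSpec,
    simulate_gwas_benchmark,
    simulate_interactome_with_module,
)


def annotation(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chr", "tss"])


class TestBuildCandidateSets:
    def test_window_boundary_arithmetic(self):
        loci = [GwasLocus("rs1", "1", 1_000_000)]
        ann = annotation(
            [("g1", "1", 100_000), ("g2", "1", 1_500_000), ("g3", "1", 2_100_000)]
        )
        table = build_candidate_sets(loci, ann)
        assert table.loci[0].candidates == ["g1", "g2"] or set(
            table.loci[0].candidates
        ) == {"g1", "g2"}

    def test_window_edge_is_closed(self):
        loci = [GwasLocus("rs1", "1", 2_000_000)]
        ann = annotation([("edge", "1", 1_000_000), ("out", "1", 999_999)])
        table = build_candidate_sets(loci, ann)
        assert table.loci[0].candidates == ["edge"]

    def test_truncation_keeps_nearest(self):
        loci = [GwasLocus("rs1", "1", 5_000_000)]
        rows = [(f"g{i:02d}", "1", 5_000_000 + i * 10_000) for i in range(30)]
        table = build_candidate_sets(loci, annotation(rows), max_candidates=20)
        cands = table.loci[0].candidates
        assert len(cands) == 20
        assert set(cands) == {f"g{i:02d}" for i in range(20)}

    def test_distance_tie_breaks_smaller_gene_id(self):
        loci = [GwasLocus("rs1", "1", 1_000_000)]
        ann = annotation([("b", "1", 1_000_100), ("a", "1", 999_900)])
        table = build_candidate_sets(loci, ann, max_candidates=1)
        assert table.loci[0].candidates == ["a"]

    def test_empty_locus_dropped_with_warning(self, caplog):
        loci = [GwasLocus("rs1", "1", 1_000_000), GwasLocus("rs2", "9", 1_000_000)]
        ann = annotation([("g1", "1", 1_000_500)])
        with caplog.at_level("WARNING"):
            table = build_candidate_sets(loci, ann)
        assert len(table) == 1
        assert "rs2" in caplog.text

    def test_empty_annotation_errors(self):
        with pytest.raises(ValueError):
            build_candidate_sets(
                [GwasLocus("rs1", "1", 100)], annotation([])
            )


def toy_w(edges):
    tm = build_transition_matrix(nx.Graph(edges))
    return tm, rwr_proximity_matrix(tm, RWRConfig(tol=1e-18))


class TestBayesFactorScores:
    def test_isolated_candidate_scores_zero(self):
        g = nx.Graph([("a", "x"), ("x", "y")])
        g.add_node("iso")
        tm = build_transition_matrix(g)
        w = rwr_proximity_matrix(tm, RWRConfig(tol=1e-18))
        scores = bayes_factor_scores(w, ["a", "iso"], ["x"])
        assert scores["iso"] == 0.0
        assert scores["a"] == 1.0

    def test_path_nearer_candidate_wins(self):
        _, w = toy_w([("a", "b"), ("b", "c")])
        scores = bayes_factor_scores(w, ["a", "b"], ["c"])
        assert scores["b"] > scores["a"]

    def test_symmetric_candidates_get_equal_weights(self):
        # a1 and a2 are exchangeable by the automorphism fixing h
        _, w = toy_w([("a1", "h"), ("a2", "h")])
        scores = bayes_factor_scores(w, ["a1", "a2"], ["h"])
        assert scores["a1"] == pytest.approx(scores["a2"], abs=1e-12)

    def test_all_zero_scores_fall_back_to_uniform(self):
        g = nx.Graph([("x", "y")])
        g.add_node("c1")
        g.add_node("c2")
        tm = build_transition_matrix(g)
        w = rwr_proximity_matrix(tm, RWRConfig(tol=1e-18))
        scores = bayes_factor_scores(w, ["c1", "c2"], ["x"])
        assert scores["c1"] == scores["c2"] == 0.5

    def test_weights_normalize(self):
        _, w = toy_w([("a", "b"), ("b", "c"), ("c", "d")])
        scores = bayes_factor_scores(w, ["a", "b", "d"], ["c"])
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-12)


def locus(snp_id, candidates):
    return Locus(
        GwasLocus(snp_id, "1", 1_000_000), list(candidates),
        {g: i for i, g in enumerate(candidates)},
    )


class TestGibbsSampling:
    def test_single_candidate_loci_converge_immediately(self):
        _, w = toy_w([("a", "b")])
        table = LocusTable([locus("s1", ["a"]), locus("s2", ["b"])])
        post = gibbs_sample(table, w, GibbsConfig(), rng=0)
        assert post.converged
        assert post.frequencies[0]["a"] == 1.0
        assert post.frequencies[1]["b"] == 1.0

    def test_frequencies_sum_to_one_per_locus(self):
        _, w = toy_w([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        table = LocusTable([locus("s1", ["a", "c"]), locus("s2", ["b", "d"])])
        post = gibbs_sample(table, w, GibbsConfig(max_rounds=50), rng=1)
        for f in post.frequencies:
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        _, w = toy_w([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        table = LocusTable([locus("s1", ["a", "c"]), locus("s2", ["b", "d"])])
        p1 = gibbs_sample(table, w, GibbsConfig(), rng=9)
        p2 = gibbs_sample(table, w, GibbsConfig(), rng=9)
        assert p1.frequencies == p2.frequencies
        assert p1.rounds_used == p2.rounds_used

    def test_round_mode_also_runs(self):
        _, w = toy_w([("a", "b"), ("b", "c")])
        table = LocusTable([locus("s1", ["a", "b"])])
        post = gibbs_sample(
            table, w, GibbsConfig(freq_mode="round", max_rounds=60), rng=2
        )
        assert sum(post.frequencies[0].values()) == pytest.approx(1.0)

    def test_stationary_matches_sweep_kernel_enumeration(self):
        """2-locus/2-candidate chain matches exact stationary marginals.

        The oracle enumerates the 4 joint states and builds the full-sweep
        transition kernel from the same conditional weights, taking its
        stationary eigenvector — exact for the sampler regardless of the
        asymmetry of the RWR kernel.
        """
        _, w = toy_w(
            [("a1", "h"), ("a2", "h"), ("b1", "a1"), ("b2", "h"),
             ("b2", "a2"), ("c", "b1"), ("c", "h")]
        )
        c1, c2 = ["a1", "a2"], ["b1", "b2"]
        states = list(itertools.product(c1, c2))
        kernel = np.zeros((4, 4))
        for i, (_, x2) in enumerate(states):
            w1 = bayes_factor_scores(w, c1, [x2])
            for j, (y1, y2) in enumerate(states):
                w2 = bayes_factor_scores(w, c2, [y1])
                kernel[i, j] = w1[y1] * w2[y2]
        vals, vecs = np.linalg.eig(kernel.T)
        pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
        pi /= pi.sum()
        exact_a1 = pi[0] + pi[1]
        exact_b1 = pi[0] + pi[2]

        table = LocusTable([locus("s1", c1), locus("s2", c2)])
        n_rounds = 10_000
        post = gibbs_sample(
            table, w, GibbsConfig(tol=0.0, max_rounds=n_rounds, burn_in=100), rng=0
        )
        # 3 sigma Monte-Carlo band with a conservative autocorrelation factor
        sigma = 3 * np.sqrt(0.25 / n_rounds) * np.sqrt(5)
        assert abs(post.frequencies[0]["a1"] - exact_a1) < sigma
        assert abs(post.frequencies[1]["b1"] - exact_b1) < sigma


class TestSelectRiskGenes:
    def test_max_frequency_wins(self):
        _, w = toy_w([("a", "b")])
        table = LocusTable([locus("s1", ["a", "b"])])
        post = gibbs_sample(table, w, GibbsConfig(max_rounds=40), rng=0)
        sel = select_risk_genes(post, table)
        top = max(post.frequencies[0], key=post.frequencies[0].get)
        assert sel.per_locus_choice["s1"] == top

    def test_shared_gene_merged_once(self):
        from netprio.prioritize import PosteriorTable

        table = LocusTable([locus("s1", ["g", "x"]), locus("s2", ["g", "y"])])
        post = PosteriorTable(
            frequencies=[{"g": 0.8, "x": 0.2}, {"g": 0.7, "y": 0.3}],
            rounds_used=10, converged=True,
        )
        sel = select_risk_genes(post, table)
        assert sel.risk_genes == {"g"}
        assert sel.background_genes == {"x", "y"}

    def test_background_is_complement(self):
        from netprio.prioritize import PosteriorTable

        table = LocusTable(
            [locus(f"s{i}", [f"a{i}", f"b{i}"]) for i in range(6)]
        )
        post = PosteriorTable(
            frequencies=[{f"a{i}": 0.6, f"b{i}": 0.4} for i in range(6)],
            rounds_used=10, converged=True,
        )
        sel = select_risk_genes(post, table)
        assert sel.risk_genes == {f"a{i}" for i in range(6)}
        assert sel.background_genes == {f"b{i}" for i in range(6)}
        assert not sel.risk_genes & sel.background_genes
        assert sel.risk_genes | sel.background_genes == table.candidate_universe

    def test_tie_breaks_to_nearer_tss(self):
        from netprio.prioritize import PosteriorTable

        loc = Locus(
            GwasLocus("s1", "1", 100), ["far", "near"], {"far": 500, "near": 100}
        )
        table = LocusTable([loc])
        post = PosteriorTable(
            frequencies=[{"far": 0.5, "near": 0.5}], rounds_used=5, converged=True
        )
        sel = select_risk_genes(post, table)
        assert sel.per_locus_choice["s1"] == "near"


class TestRiskGeneModelEndToEnd:
    def test_recovery_on_small_benchmark(self, small_benchmark):
        gwas = small_benchmark["gwas"]
        model = RiskGeneModel(small_benchmark["net"], gwas.locus_table)
        res = model.fit(seed=3)
        correct = sum(
            res.selection.per_locus_choice[s] == g for s, g in gwas.truth.items()
        )
        assert correct / len(gwas.truth) >= 0.75
        assert res.risk_genes.isdisjoint(res.background_genes)

    def test_recovery_improves_with_module_density(self):
        """Planted-gene recovery is no worse on a denser planted module."""
        rates = []
        for density in (0.08, 0.45):
            spec = BenchmarkSpec(
                n_nodes=250, n_loci=12, candidates_per_locus=5,
                planted_module_density=density, rng_seed=5,
            )
            net, planted = simulate_interactome_with_module(spec)
            gwas = simulate_gwas_benchmark(net, planted, spec)
            res = RiskGeneModel(net, gwas.locus_table).fit(seed=5)
            correct = sum(
                res.selection.per_locus_choice[s] == g
                for s, g in gwas.truth.items()
            )
            rates.append(correct / len(gwas.truth))
        assert rates[1] >= rates[0]

    def test_fit_deterministic(self, small_benchmark):
        model = RiskGeneModel(
            small_benchmark["net"], small_benchmark["gwas"].locus_table
        )
        r1, r2 = model.fit(seed=8), model.fit(seed=8)
        assert r1.posterior.frequencies == r2.posterior.frequencies
        assert r1.risk_genes == r2.risk_genes

    def test_summary_and_frames(self, small_benchmark):
        model = RiskGeneModel(
            small_benchmark["net"], small_benchmark["gwas"].locus_table
        )
        res = model.fit(seed=1)
        df = res.posterior_frame()
        assert {"snp_id", "gene", "frequency", "selected"} <= set(df.columns)
        per_locus = df.groupby("snp_id")["frequency"].sum()
        assert np.allclose(per_locus, 1.0, atol=1e-9)
        assert "Risk-gene inference" in res.summary()
        conf = res.gene_confidence()
        assert (conf["confidence"] <= 1).all() and (conf["confidence"] >= 0).all()
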