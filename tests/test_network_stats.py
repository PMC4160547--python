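"""Fisher aggregation, community cohesion, permutation nulls and
leave-one-type-out confidence."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survnet import (SimulationConfig, community_significance,
                     degree_binned_permutation, edge_significance,
                     fisher_aggregate, loo_edge_confidence, simulate_cohort,
                     cox_lrt_per_gene, search_fixed_size)
from survnet.module_search import ModuleResult


def module_from_graph(g):
    return ModuleResult(subgraph=g, pcut=0.05, total_score=0.0,
                        scores={v: 1.0 for v in g},
                        pvals={v: 0.01 for v in g})


class TestFisher:
    def test_single_p_identity(self):
        for p in (0.01, 0.2, 0.97):
            assert fisher_aggregate([p]) == pytest.approx(p, rel=1e-12)

    def test_all_ones(self):
        assert fisher_aggregate([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_against_chi2_oracle(self):
        p = [0.01, 0.02, 0.5]
        x = -2 * np.sum(np.log(p))
        assert fisher_aggregate(p) == pytest.approx(
            float(stats.chi2.sf(x, 6)), rel=1e-12)

    def test_monotone_in_components(self):
        base = [0.3, 0.4, 0.5]
        agg = fisher_aggregate(base)
        for i in range(3):
            smaller = list(base)
            smaller[i] /= 10
            assert fisher_aggregate(smaller) <= agg

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_aggregate([])
        with pytest.raises(ValueError):
            fisher_aggregate([0.0, 0.5])


class TestCommunitySignificance:
    def test_clique_with_sparse_exits_is_cohesive(self):
        g = nx.complete_graph([f"c{i}" for i in range(5)])
        for i in range(5):
            g.add_edge(f"c{i}", f"x{i}")
        module = module_from_graph(g)
        partition = {v: ("A" if v.startswith("c") else "B") for v in g}
        res = community_significance(module, partition).set_index("community")
        # within-degrees (4,...) vs between (1,...): strong cohesion
        assert res.loc["A", "pval"] < 0.05

    def test_identical_samples_give_p_one(self):
        # 4-cycle split into two 2-node communities: within == between == 1
        g = nx.cycle_graph(["a", "b", "c", "d"])
        module = module_from_graph(g)
        partition = {"a": "L", "b": "L", "c": "R", "d": "R"}
        res = community_significance(module, partition).set_index("community")
        assert res.loc["L", "pval"] == 1.0

    def test_singleton_community_untestable(self):
        g = nx.path_graph(["a", "b", "c"])
        res = community_significance(
            module_from_graph(g), {"a": "X", "b": "Y", "c": "Y"})
        row = res.set_index("community").loc["X"]
        assert row["status"] == "untestable"

    def test_unknown_node_in_partition_errors(self):
        g = nx.path_graph(["a", "b"])
        with pytest.raises(ValueError, match="partition"):
            community_significance(module_from_graph(g),
                                   {"a": "X", "b": "X", "zz": "X"})

    def test_null_partition_calibration(self):
        """Random bisection of an Erdos-Renyi graph: cohesion p-values are
        roughly uniform, so about 5% fall below 0.05."""
        rng = np.random.default_rng(0)
        hits, n = 0, 0
        for trial in range(200):
            g = nx.gnp_random_graph(16, 0.35, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            labels = np.array(["A"] * 8 + ["B"] * 8)
            rng.shuffle(labels)
            partition = dict(zip(sorted(g.nodes), labels))
            res = community_significance(module_from_graph(g), partition)
            p = res.set_index("community").loc["A", "pval"]
            if np.isfinite(p):
                n += 1
                hits += p < 0.05
        assert n > 150
        assert hits / n < 0.12  # one-sided test is conservative under null


class TestDegreeBinnedPermutation:
    def graph_and_pvals(self, seed=0):
        g = nx.barabasi_albert_graph(40, 2, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        rng = np.random.default_rng(seed)
        pv = {v: float(rng.uniform()) for v in g.nodes}
        return g, pv

    def test_single_bin_preserves_multiset(self):
        g, pv = self.graph_and_pvals()
        out = degree_binned_permutation(g, pv, n_bins=1, seed=1)
        assert sorted(out.values()) == sorted(pv.values())
        assert set(out) == set(pv)

    def test_degree_sequence_untouched_and_multiset_conserved(self):
        g, pv = self.graph_and_pvals(3)
        before = sorted(dict(g.degree()).values())
        out = degree_binned_permutation(g, pv, n_bins=10, seed=2)
        assert sorted(dict(g.degree()).values()) == before
        assert sorted(out.values()) == sorted(pv.values())

    def test_singleton_bin_is_fixed_point(self):
        # star: hub degree n-1 is alone in the top bin for many bins
        g = nx.star_graph(20)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        pv = {v: 0.5 for v in g.nodes}
        pv["n00"] = 0.001  # the hub
        for seed in range(5):
            out = degree_binned_permutation(g, pv, n_bins=8, seed=seed)
            assert out["n00"] == 0.001

    def test_shuffles_within_bins_only(self):
        g, pv = self.graph_and_pvals(4)
        out = degree_binned_permutation(g, pv, n_bins=6, seed=5)
        # group nodes by degree bin and compare per-bin multisets
        deg = dict(g.degree())
        logd = {v: np.log2(max(d, 1)) for v, d in deg.items()}
        lo, hi = min(logd.values()), max(logd.values())
        edges = np.linspace(lo, hi, 7)
        def bin_of(v):
            return int(np.clip(np.digitize(logd[v], edges[1:-1]), 0, 5))
        for b in range(6):
            members = [v for v in g.nodes if bin_of(v) == b]
            assert sorted(pv[v] for v in members) == \
                sorted(out[v] for v in members)


class TestEdgeSignificance:
    def test_two_node_graph_edge_always_recovered(self, tiny_bundle):
        """With both endpoints significant in every permutation the edge is
        in every null module: p = (1+R)/(1+R) = 1."""
        g = nx.Graph([("GA", "GB")])
        scores = pd.DataFrame({
            "gene": ["GA", "GB"], "hr": [2.0, 2.0],
            "pval": [0.001, 0.002], "lrt_stat": [10, 9],
            "n_mutated": [5, 5], "status": "ok"})
        from survnet import AnalysisBundle
        bundle = AnalysisBundle(tiny_bundle.mutations, tiny_bundle.clinical, g)
        ref = search_fixed_size(scores, g, target_size=2, tol=0)
        R = 7
        sig = edge_significance(bundle, ref, R=R, seed=0, scores=scores,
                                tol=0)
        assert sig.table["pval"].iloc[0] == pytest.approx(1.0)

    def test_pseudo_count_floor_and_range(self, small_cohort):
        scores = cox_lrt_per_gene(small_cohort.bundle)
        ref = search_fixed_size(scores, small_cohort.bundle.graph,
                                target_size=6)
        R = 9
        sig = edge_significance(small_cohort.bundle, ref, R=R, seed=3,
                                scores=scores)
        assert (sig.table["pval"] >= 1 / (1 + R) - 1e-12).all()
        assert (sig.table["pval"] <= 1.0).all()
        assert 0 < sig.aggregated_p <= 1


class TestLooConfidence:
    def test_confidence_bounds_and_signal(self, small_cohort):
        scores = cox_lrt_per_gene(small_cohort.bundle)
        ref = search_fixed_size(scores, small_cohort.bundle.graph,
                                target_size=6)
        conf = loo_edge_confidence(small_cohort.bundle, ref)
        assert ((conf["confidence"] >= 0) & (conf["confidence"] <= 1)).all()

    def test_signal_carried_by_one_type(self):
        """When one of two tumour types carries all the survival signal,
        dropping it loses the module: edge confidence <= 0.5."""
        rng = np.random.default_rng(9)
        cfg = SimulationConfig(n_patients=240, n_genes=40, module_size=5,
                               beta=0.0, lam_mod=0.5, lam_bg=0.1,
                               tumour_types={"A": 0.5, "B": 0.5},
                               type_log_hazards=(0.0,), seed=21)
        cohort = simulate_cohort(cfg)
        clin = cohort.bundle.clinical.table
        burden = cohort.bundle.mutations.counts[
            cohort.module_nodes].sum(axis=1).to_numpy(float)
        is_a = (clin["tumour_type"] == "A").to_numpy()
        # regenerate survival: signal beta=2 in type A; type B is entirely
        # censored, so the run that drops A carries no survival information
        haz = 1e-3 * np.exp(np.where(is_a, 2.0 * burden, 0.0))
        death = rng.exponential(1 / haz)
        new = clin.copy()
        new["time"] = np.maximum(death, 1e-6)
        new["event"] = np.where(is_a, 1, 0)
        from survnet import ClinicalTable, AnalysisBundle
        bundle = AnalysisBundle(cohort.bundle.mutations,
                                ClinicalTable(new), cohort.bundle.graph)
        scores = cox_lrt_per_gene(bundle)
        ref = search_fixed_size(scores, bundle.graph, target_size=5)
        conf = loo_edge_confidence(bundle, ref)
        assert (conf["confidence"] <= 0.5).all()
        assert (conf["confidence"] == 0.5).any()  # recovered when B dropped
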