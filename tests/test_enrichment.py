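"""GSEA, hypergeometric enrichment, ontology propagation, gene ages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survnet import (AgeTable, GeneSetCollection, gsea, hypergeom_enrich,
                     make_ranking, phylostratum_enrich, propagate_ontology,
                     rank_builders)
from survnet.enrichment import RankedList


def ranked_fixture(n=50, seed=0):
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.exponential(1.0, n))[::-1]
    genes = [f"g{i:03d}" for i in range(n)]
    return RankedList(genes, metric, "fixture")


def naive_running_sum(ranked, gene_set, q):
    """Independent O(N) reference: explicit hit/miss walk down the list."""
    hits = [g in gene_set for g in ranked.genes]
    n, m = len(ranked), sum(hits)
    w = np.abs(ranked.metric) ** q
    tot = sum(wi for wi, h in zip(w, hits) if h)
    run, out = 0.0, []
    for i in range(n):
        if hits[i]:
            run += (w[i] / tot) if tot > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        out.append(run)
    return np.array(out)


class TestGsea:
    def test_running_score_matches_naive_oracle(self):
        ranked = ranked_fixture()
        gene_set = set(ranked.genes[3:9]) | set(ranked.genes[40:44])
        for q in (0.0, 1.0):
            res = gsea(ranked, gene_set, weight=q, R=10, seed=0)
            oracle = naive_running_sum(ranked, gene_set, q)
            np.testing.assert_allclose(res.running, oracle, atol=1e-12)
            k = np.argmax(np.abs(oracle))
            assert res.es == pytest.approx(oracle[k])

    def test_running_score_ends_at_zero(self):
        ranked = ranked_fixture(seed=2)
        res = gsea(ranked, set(ranked.genes[::7]), R=5, seed=1)
        assert res.running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_all_hits_at_top_q0(self):
        ranked = ranked_fixture(seed=3)
        res = gsea(ranked, set(ranked.genes[:8]), weight=0.0, R=50, seed=1)
        assert res.es == pytest.approx(1.0)
        assert res.pval < 0.2

    def test_reversal_negates_es_q0(self):
        ranked = ranked_fixture(seed=4)
        gene_set = set(ranked.genes[:6])
        res = gsea(ranked, gene_set, weight=0.0, R=5, seed=0)
        rev = RankedList(ranked.genes[::-1],
                         np.zeros(len(ranked)), "rev")
        res_rev = gsea(rev, gene_set, weight=0.0, R=5, seed=0)
        assert res_rev.es == pytest.approx(-res.es)

    def test_null_pvalues_roughly_uniform(self):
        ranked = ranked_fixture(n=120, seed=5)
        rng = np.random.default_rng(6)
        pvals = []
        for t in range(60):
            gene_set = set(rng.choice(ranked.genes, size=10, replace=False))
            pvals.append(gsea(ranked, gene_set, R=200, seed=1000 + t).pval)
        frac = np.mean(np.array(pvals) < 0.2)
        assert abs(frac - 0.2) < 0.15

    def test_nes_sign_matches_es_and_p_positive(self):
        ranked = ranked_fixture(seed=7)
        res = gsea(ranked, set(ranked.genes[:10]), R=200, seed=0)
        assert np.sign(res.nes) == np.sign(res.es)
        assert res.pval > 0

    def test_disjoint_set_errors(self):
        ranked = ranked_fixture()
        with pytest.raises(ValueError, match="disjoint"):
            gsea(ranked, {"absent"}, R=5)

    def test_whole_list_degenerate(self):
        ranked = ranked_fixture(n=10)
        res = gsea(ranked, set(ranked.genes), R=5)
        assert res.degenerate
        assert res.es == pytest.approx(1.0)


class TestRankings:
    def test_constant_metric_flagged(self):
        r = make_ranking(pd.Series({"b": 1.0, "a": 1.0}))
        assert r.untestable
        assert r.genes == ["a", "b"]  # lexicographic tie-break

    def test_hr_ranking_matches_sort(self):
        scores = pd.DataFrame({
            "gene": ["a", "b", "c"], "hr": [1.5, 3.0, 0.5],
            "pval": [0.1, 0.01, 0.5], "lrt_stat": [1, 2, 3],
            "n_mutated": [3, 3, 3], "status": "ok"})
        out = rank_builders(scores=scores)
        assert out["hr"].genes == ["b", "a", "c"]

    def test_per_patient_rankings(self):
        mm = pd.DataFrame([[3, 1, 0], [0, 0, 5], [2, 2, 2]],
                          index=["P1", "P2", "P3"],
                          columns=["ga", "gb", "gc"])
        out = rank_builders(mutations=mm)
        assert out["patient:P1"].genes == ["ga", "gb", "gc"]
        assert out["patient:P2"].genes == ["gc", "ga", "gb"]
        assert out["patient:P3"].untestable


class TestHypergeom:
    def test_degenerate_urn_p_one(self):
        genes = {f"g{i}" for i in range(10)}
        coll = GeneSetCollection(sets={"t": set(genes)})
        res = hypergeom_enrich(genes, coll, genes)
        assert res["pval"].iloc[0] == pytest.approx(1.0)

    def test_tail_matches_enumeration(self):
        """Exact tail: group 5 from background 50, term 10, overlap 4."""
        bg = [f"g{i:02d}" for i in range(50)]
        term = set(bg[:10])
        group = set(bg[:4]) | {bg[40]}
        coll = GeneSetCollection(sets={"t": term})
        res = hypergeom_enrich(group, coll, bg)
        from math import comb
        expected = sum(comb(10, k) * comb(40, 5 - k) for k in (4, 5)) / comb(50, 5)
        assert res["pval"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_matches_fisher_exact(self):
        bg = [f"g{i:02d}" for i in range(40)]
        term = set(bg[:12])
        group = set(bg[8:18])
        coll = GeneSetCollection(sets={"t": term})
        p = hypergeom_enrich(group, coll, bg)["pval"].iloc[0]
        k = len(term & group)
        table = [[k, len(group) - k],
                 [len(term) - k, 40 - len(term) - len(group) + k]]
        fp = stats.fisher_exact(table, alternative="greater")[1]
        assert p == pytest.approx(fp, abs=1e-10)

    def test_fdr_at_least_p_and_null_calibration(self):
        rng = np.random.default_rng(1)
        bg = [f"g{i:03d}" for i in range(200)]
        hits = 0
        n_sims = 40
        for s in range(n_sims):
            terms = {f"t{j}": set(rng.choice(bg, 10, replace=False))
                     for j in range(20)}
            group = set(rng.choice(bg, 15, replace=False))
            res = hypergeom_enrich(group, GeneSetCollection(sets=terms), bg)
            assert (res["fdr"] >= res["pval"] - 1e-12).all()
            if (res["fdr"] < 0.05).any():
                hits += 1
        assert hits <= int(0.2 * n_sims)


class TestOntology:
    def test_chain_propagation(self):
        coll = GeneSetCollection(sets={"root": {"x"}, "A": {"y"}, "B": {"z"}},
                                 relations=[("root", "A"), ("A", "B")])
        out = propagate_ontology(coll)
        assert out.sets["A"] == {"y", "z"}
        assert out.sets["root"] == {"x", "y", "z"}

    def test_idempotent_and_monotone(self):
        coll = GeneSetCollection(sets={"r": {"a"}, "c": {"b"}},
                                 relations=[("r", "c")])
        once = propagate_ontology(coll)
        twice = propagate_ontology(once)
        assert once.sets == twice.sets
        for t, s in coll.sets.items():
            assert s <= once.sets[t]

    def test_diamond_closure(self):
        rel = [("root", "L"), ("root", "R"), ("L", "leaf"), ("R", "leaf")]
        coll = GeneSetCollection(sets={"leaf": {"g"}, "L": {"l"}, "R": {"r"},
                                       "root": {"t"}}, relations=rel)
        out = propagate_ontology(coll)
        assert out.sets["L"] == {"l", "g"}
        assert out.sets["R"] == {"r", "g"}
        assert out.sets["root"] == {"t", "l", "r", "g"}

    def test_cycle_detected(self):
        coll = GeneSetCollection(sets={"a": {"x"}, "b": {"y"}},
                                 relations=[("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="cycle"):
            propagate_ontology(coll)


class TestPhylostratum:
    def ages_fixture(self):
        order = ["Opisthokonta", "Metazoa", "Deuterostomia"]
        reps = {
            "Opisthokonta": {f"o{i}" for i in range(20)},
            "Metazoa": {f"o{i}" for i in range(20)} | {f"m{i}" for i in range(20)},
            "Deuterostomia": ({f"o{i}" for i in range(20)}
                              | {f"m{i}" for i in range(20)}
                              | {f"d{i}" for i in range(10)}),
        }
        ages = {f"o{i}": "Opisthokonta" for i in range(20)}
        ages.update({f"m{i}": "Metazoa" for i in range(20)})
        ages.update({f"d{i}": "Deuterostomia" for i in range(10)})
        return AgeTable(ages=ages, order=order, repertoires=reps)

    def test_concentrated_group_minimises_p_at_its_stratum(self):
        ages = self.ages_fixture()
        group = {f"m{i}" for i in range(8)}
        res = phylostratum_enrich(group, ages).set_index("term")
        assert res.loc["Metazoa", "pval"] == res["pval"].min()

    def test_cumulative_fractions(self):
        ages = self.ages_fixture()
        group = {"o0", "o1", "m0", "m1", "d0"}
        res = phylostratum_enrich(group, ages).set_index("term")
        assert res.loc["Opisthokonta", "cumulative_fraction"] == pytest.approx(0.4)
        assert res.loc["Metazoa", "cumulative_fraction"] == pytest.approx(0.8)
        assert res.loc["Deuterostomia", "cumulative_fraction"] == pytest.approx(1.0)

    def test_uniform_group_rarely_significant(self):
        ages = self.ages_fixture()
        rng = np.random.default_rng(0)
        all_genes = sorted(ages.ages)
        hits = 0
        for _ in range(40):
            group = set(rng.choice(all_genes, 10, replace=False))
            res = phylostratum_enrich(group, ages)
            hits += bool((res["fdr"] < 0.05).any())
        assert hits <= 8
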