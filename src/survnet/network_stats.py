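"""Post-hoc statistics on an identified module.

Covers: cohesion significance of communities (within- vs between-community
degrees, one-sided Wilcoxon), leave-one-tumour-type-out edge confidence,
degree-binned label permutation nulls with per-edge empirical p-values, and
Fisher's method for aggregating p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalysisBundle, ClinicalTable, MutationMatrix, harmonise
from .module_search import ModuleResult, search_fixed_size
from .survival import cox_lrt_per_gene

logger = logging.getLogger(__name__)


def fisher_aggregate(pvals) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df under the
    global null; returns the upper-tail aggregated p."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def detect_communities(graph: nx.Graph) -> dict[str, str]:
    """Default partition provider: greedy modularity communities.

    Any node -> label mapping can be passed to community_significance
    instead; detection itself is interchangeable, the significance test is
    the bespoke part.
    """
    comms = nx.algorithms.community.greedy_modularity_communities(graph)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c))
    return {v: f"C{i + 1}" for i, c in enumerate(comms) for v in c}


def _wilcoxon_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided rank-sum p (x stochastically greater than y).

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise; fully tied pooled samples carry no evidence
    and return p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    ties = len(np.unique(pooled)) < pooled.size
    small = max(len(x), len(y)) < 10
    method = "exact" if (small and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="greater",
                                    method=method).pvalue)


def community_significance(module: ModuleResult,
                           partition: dict[str, str]) -> pd.DataFrame:
    """Cohesion p-value per community: within-community degrees vs
    between-community degrees, one-sided (within > between)."""
    nodes = set(module.subgraph.nodes)
    extra = sorted(set(partition) - nodes)
    missing = sorted(nodes - set(partition))
    if extra or missing:
        raise ValueError(f"partition mismatch: extra={extra} missing={missing}")
    g = module.subgraph
    rows = []
    for label in sorted(set(partition.values())):
        members = sorted(v for v in nodes if partition[v] == label)
        within = np.array([sum(partition[u] == label for u in g.neighbors(v))
                           for v in members], dtype=float)
        between = np.array([g.degree[v] for v in members], dtype=float) - within
        if len(members) < 2:
            rows.append((label, len(members), np.nan, "untestable"))
            continue
        p = _wilcoxon_greater(within, between)
        rows.append((label, len(members), p, "ok"))
    return pd.DataFrame(rows, columns=["community", "size", "pval", "status"])


def loo_edge_confidence(bundle: AnalysisBundle, reference: ModuleResult,
                        min_mutated: int = 2, tol: int = 2) -> pd.DataFrame:
    """Leave-one-tumour-type-out edge confidence (bootstrap-style support).

    Each run drops one tumour type, re-scores genes and re-identifies a
    module of (approximately) the reference size; an edge's confidence is
    the fraction of runs whose module contains it.
    """
    types = bundle.clinical.tumour_types
    if len(types) < 2:
        raise ValueError("need >= 2 tumour types for leave-one-out")
    edge_hits = {e: 0 for e in reference.edges}
    for t in types:
        clin = bundle.clinical.table
        keep = clin.loc[clin["tumour_type"] != t, "patient"].tolist()
        sub = harmonise(MutationMatrix(bundle.mutations.counts.loc[keep]),
                        ClinicalTable(clin.loc[keep].copy()), bundle.graph)
        try:
            scores = cox_lrt_per_gene(sub, min_mutated=min_mutated)
            module = search_fixed_size(scores, bundle.graph,
                                       target_size=reference.size, tol=tol)
        except (ValueError, RuntimeError) as exc:
            logger.warning("removal run without %s recovered no module: %s", t, exc)
            continue
        got = set(module.edges)
        for e in edge_hits:
            if e in got:
                edge_hits[e] += 1
    n = len(types)
    return pd.DataFrame(
        [(u, v, c / n) for (u, v), c in sorted(edge_hits.items())],
        columns=["gene1", "gene2", "confidence"])


def degree_binned_permutation(graph: nx.Graph, pvals: dict[str, float],
                              n_bins: int = 10,
                              rng: np.random.Generator | None = None,
                              seed: int | None = None) -> dict[str, float]:
    """Degree-approximating label permutation: p-value labels shuffle only
    among nodes of similar degree (log2-spaced bins); topology untouched."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes = sorted(v for v in graph.nodes if v in pvals)
    if not nodes:
        return {}
    deg = np.array([graph.degree[v] for v in nodes], dtype=float)
    logd = np.log2(np.maximum(deg, 1.0))
    lo, hi = logd.min(), logd.max()
    if hi == lo:
        bin_idx = np.zeros(len(nodes), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bin_idx = np.clip(np.digitize(logd, edges[1:-1]), 0, n_bins - 1)
    out: dict[str, float] = {}
    for b in np.unique(bin_idx):
        members = [nodes[i] for i in np.nonzero(bin_idx == b)[0]]
        perm = rng.permutation(len(members))
        for i, v in enumerate(members):
            out[v] = pvals[members[perm[i]]]
    return out


@dataclass
class EdgeSignificance:
    table: pd.DataFrame        # gene1, gene2, pval
    aggregated_p: float
    n_randomisations: int


def edge_significance(bundle: AnalysisBundle, reference: ModuleResult,
                      R: int = 100, n_bins: int = 10, seed: int = 0,
                      scores: pd.DataFrame | None = None,
                      min_mutated: int = 2, tol: int = 2) -> EdgeSignificance:
    """Empirical per-edge p-values against degree-binned permutation nulls.

    R label permutations each yield a null module of the reference size;
    p(e) = (1 + #null modules containing e) / (1 + R) (pseudo-count keeps p
    in (0, 1]); the per-edge p-values combine by Fisher's method.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if scores is None:
        scores = cox_lrt_per_gene(bundle, min_mutated=min_mutated)
    ok = scores[scores["status"] == "ok"]
    pmap = dict(zip(ok["gene"], ok["pval"]))
    rng = np.random.default_rng(seed)
    edge_hits = {e: 0 for e in reference.edges}
    for _ in range(R):
        permuted = degree_binned_permutation(bundle.graph, pmap,
                                             n_bins=n_bins, rng=rng)
        null_scores = pd.DataFrame({
            "gene": sorted(permuted),
            "pval": [permuted[g] for g in sorted(permuted)],
        })
        null_scores["hr"] = np.nan
        null_scores["lrt_stat"] = np.nan
        null_scores["n_mutated"] = 0
        null_scores["status"] = "ok"
        try:
            module = search_fixed_size(null_scores, bundle.graph,
                                       target_size=reference.size, tol=tol)
        except ValueError as exc:
            logger.warning("null run recovered no module: %s", exc)
            continue
        got = set(module.edges)
        for e in edge_hits:
            if e in got:
                edge_hits[e] += 1
    table = pd.DataFrame(
        [(u, v, (1 + c) / (1 + R)) for (u, v), c in sorted(edge_hits.items())],
        columns=["gene1", "gene2", "pval"])
    agg = fisher_aggregate(table["pval"]) if len(table) else 1.0
    return EdgeSignificance(table=table, aggregated_p=agg, n_randomisations=R)
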