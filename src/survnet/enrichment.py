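"""Gene-set interpretation of a module: pre-ranked GSEA with a
gene-set-resampling null, hypergeometric over-representation with BH FDR,
true-path ontology propagation, and phylostratum (gene-age) enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AgeTable, GeneSetCollection

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["term", "overlap", "term_size", "background_size",
                  "group_size", "pval", "fdr", "members"]


@dataclass
class RankedList:
    """Genes ordered by a non-increasing metric; ties break on gene id."""

    genes: list[str]
    metric: np.ndarray
    name: str = "ranking"
    untestable: bool = False

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric lengths differ")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


def make_ranking(metric: pd.Series, name: str = "ranking") -> RankedList:
    """Sort a gene -> metric series into a RankedList (descending metric,
    ties lexicographic).  A constant metric is flagged untestable."""
    s = metric.dropna()
    order = sorted(s.index, key=lambda g: (-s[g], g))
    vals = s.loc[order].to_numpy(float)
    untestable = bool(vals.size) and np.ptp(vals) == 0
    if untestable:
        logger.warning("ranking %r has a constant metric; untestable", name)
    return RankedList(list(order), vals, name=name, untestable=untestable)


def rank_builders(scores: pd.DataFrame | None = None,
                  freqs: pd.DataFrame | None = None,
                  ubiquity: pd.Series | None = None,
                  mutations: pd.DataFrame | None = None) -> dict[str, RankedList]:
    """The ranking families used downstream: Cox HR, cross-tumour mutation
    ubiquity, within-type mutation frequency (one per tumour type) and
    per-patient mutation counts (one per patient)."""
    out: dict[str, RankedList] = {}
    if scores is not None:
        ok = scores[scores["status"] == "ok"].set_index("gene")
        out["hr"] = make_ranking(ok["hr"], "hr")
    if ubiquity is not None:
        out["ubiquity"] = make_ranking(ubiquity, "ubiquity")
    if freqs is not None:
        for t in freqs.columns:
            out[f"freq:{t}"] = make_ranking(freqs[t], f"freq:{t}")
    if mutations is not None:
        for p in mutations.index:
            out[f"patient:{p}"] = make_ranking(mutations.loc[p].astype(float),
                                               f"patient:{p}")
    return out


@dataclass
class GseaResult:
    es: float
    nes: float
    pval: float
    peak_rank: int
    running: np.ndarray
    n_hits: int
    degenerate: bool = False


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int):
    """Signed running-sum extremum for hit positions `pos` (sorted,
    0-based) with normalised hit weights; O(#hits)."""
    m = pos.size
    miss = 1.0 / (n - m)
    cum_w = np.cumsum(weights)
    # value just after hit i, and just before hit i (trough candidates)
    after = cum_w - (pos + 1 - np.arange(1, m + 1)) * miss
    before = np.concatenate([[0.0], cum_w[:-1]]) - (pos - np.arange(m)) * miss
    cands = np.concatenate([after, before])
    idx = int(np.argmax(np.abs(cands)))
    return float(cands[idx])


def gsea(ranked: RankedList, gene_set, weight: float = 1.0,
         R: int = 1000, seed: int = 0) -> GseaResult:
    """Pre-ranked GSEA.

    Hits climb by |metric|^q (normalised over the set), misses fall by
    1/(N - m); the enrichment score is the signed extremum of the running
    sum.  The null resamples R same-size gene sets from the ranked list;
    p = (1 + #same-sign nulls at least as extreme) / (1 + #same-sign nulls)
    and NES = ES / mean |null ES| of the same sign.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    genes = ranked.genes
    n = len(genes)
    hit_idx = np.array([i for i, g in enumerate(genes) if g in set(gene_set)])
    if hit_idx.size == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if hit_idx.size == n:
        # no misses exist: the running sum climbs monotonically to 1
        logger.warning("gene set covers the entire ranked list")
        w = np.abs(ranked.metric) ** weight
        tot = w.sum()
        running = np.cumsum(w / tot if tot > 0 else np.full(n, 1.0 / n))
        return GseaResult(float(running.max()), np.nan, 1.0,
                          int(np.argmax(running)), running, n, True)

    m = hit_idx.size
    w_all = np.abs(ranked.metric) ** weight
    w_hit = w_all[hit_idx]
    tot = w_hit.sum()
    if tot == 0:  # all hit metrics zero: fall back to unweighted increments
        w_hit = np.ones(m)
        tot = float(m)
    incr = w_hit / tot
    # full running vector for the observed set
    steps = np.full(n, -1.0 / (n - m))
    steps[hit_idx] = incr
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])

    rng = np.random.default_rng(seed)
    null_es = np.empty(R)
    for r in range(R):
        pos = np.sort(rng.choice(n, size=m, replace=False))
        w = w_all[pos]
        tw = w.sum()
        wn = w / tw if tw > 0 else np.full(m, 1.0 / m)
        null_es[r] = _es_from_positions(pos, wn, n)
    same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if same.size == 0:
        pval, nes = 1.0, np.nan
    else:
        pval = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
        nes = es / np.mean(np.abs(same))
    return GseaResult(es=es, nes=float(nes), pval=float(pval),
                      peak_rank=peak, running=running, n_hits=m,
                      degenerate=False)


def hypergeom_enrich(group, collection: GeneSetCollection,
                     background) -> pd.DataFrame:
    """Over-representation of each term in `group` against `background`
    (upper-tail hypergeometric), BH-adjusted across terms."""
    background = set(background)
    if not background:
        raise ValueError("empty background")
    group = set(group) & background
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & background
        if not members:
            continue
        overlap = sorted(members & group)
        k, K, n, N = len(overlap), len(members), len(group), len(background)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, N, n, min(p, 1.0), np.nan, ",".join(overlap)))
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    if len(df):
        df["fdr"] = multipletests(df["pval"], method="fdr_bh")[1]
        df = df.sort_values(["pval", "term"], kind="stable").reset_index(drop=True)
    return df


def propagate_ontology(collection: GeneSetCollection) -> GeneSetCollection:
    """True-path propagation: every annotation climbs to all ancestor terms.

    Idempotent and monotone (annotations are never removed).  Raises on a
    cyclic hierarchy, naming an offending edge.
    """
    dag = nx.DiGraph()
    dag.add_nodes_from(collection.sets)
    dag.add_edges_from(collection.relations)  # parent -> child
    try:
        cycle = nx.find_cycle(dag)
        raise ValueError(f"hierarchy contains a cycle through edge {cycle[0]}")
    except nx.NetworkXNoCycle:
        pass
    new_sets = {t: set(collection.sets.get(t, set())) for t in dag.nodes}
    for term in reversed(list(nx.topological_sort(dag))):
        for parent in dag.predecessors(term):
            new_sets[parent] |= new_sets[term]
    return GeneSetCollection(sets={t: s for t, s in new_sets.items() if s},
                             descriptions=dict(collection.descriptions),
                             relations=list(collection.relations))


def phylostratum_enrich(group, ages: AgeTable) -> pd.DataFrame:
    """Per-ancestor over-representation of group genes first created there,
    using that ancestor's gene repertoire as the urn; plus the cumulative
    fraction of group genes created at-or-before each ancestor."""
    group = set(group)
    unmapped = sorted(g for g in group if g not in ages.ages)
    if unmapped:
        logger.warning("%d group gene(s) without age annotation: %s",
                       len(unmapped), unmapped[:5])
    mapped = group - set(unmapped)
    rows = []
    cum = 0
    strata_rank = {a: i for i, a in enumerate(ages.order)}
    for a in ages.order:
        repertoire = ages.repertoires.get(a, set())
        created_here = {g for g in repertoire if ages.ages.get(g) == a}
        group_in_bg = mapped & repertoire
        overlap = sorted(group_in_bg & created_here)
        cum += sum(1 for g in mapped if ages.ages[g] == a)
        if not repertoire:
            logger.warning("ancestor %s has an empty repertoire; skipped", a)
            continue
        p = float(stats.hypergeom.sf(len(overlap) - 1, len(repertoire),
                                     len(created_here), len(group_in_bg)))
        rows.append((a, len(overlap), len(created_here), len(repertoire),
                     len(group_in_bg), min(p, 1.0), np.nan,
                     ",".join(overlap), cum / max(len(mapped), 1)))
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS + ["cumulative_fraction"])
    if len(df):
        df["fdr"] = multipletests(df["pval"], method="fdr_bh")[1]
    return df
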