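"""Maximum-scoring connected subgraph extraction.

P-values become signed node scores, s(v) = log10(tau) - log10(p): positive
below the tolerable threshold tau, negative above.  The search for the
connected subgraph maximising the score sum is the node-weighted
prize-collecting Steiner tree problem; it is solved here with the classic
deterministic minimum-spanning-tree heuristic (metric closure over the
positive "prize" nodes, MST, path expansion, leaf pruning).  An outer
bisection over the observed p-value ladder tunes tau to hit a requested
module size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

P_EPS = 1e-300     # floor under log10(p)
EDGE_DELTA = 1e-9  # per-edge cost epsilon; biases ties toward fewer edges


@dataclass
class ScoredGraph:
    graph: nx.Graph                 # largest connected component, scored
    scores: dict[str, float]        # node -> signed score
    pvals: dict[str, float]         # node -> p-value (NaN if unscored)
    pcut: float


@dataclass
class ModuleResult:
    subgraph: nx.Graph
    pcut: float
    total_score: float
    scores: dict[str, float]
    pvals: dict[str, float]
    warning: str | None = None

    @property
    def size(self) -> int:
        return self.subgraph.number_of_nodes()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.subgraph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.subgraph.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.nodes,
            "score": [self.scores[n] for n in self.nodes],
            "pval": [self.pvals[n] for n in self.nodes],
            "degree": [self.subgraph.degree[n] for n in self.nodes],
        })


def _largest_component(graph: nx.Graph) -> nx.Graph:
    comps = sorted(nx.connected_components(graph),
                   key=lambda c: (-len(c), sorted(c)))
    return graph.subgraph(comps[0]).copy()


def fit_bum(pvals) -> tuple[float, float]:
    """Maximum-likelihood beta-uniform mixture fit of a p-value set.

    Density f(p) = lam + (1 - lam) * a * p^(a-1) with mixing weight
    lam in (0,1) and shape a in (0,1); returns (lam, a).
    """
    from scipy.optimize import minimize
    p = np.clip(np.asarray(list(pvals), dtype=float), P_EPS, 1.0)

    def nll(theta):
        lam, a = theta
        return -np.sum(np.log(lam + (1 - lam) * a * p ** (a - 1)))

    res = minimize(nll, x0=np.array([0.5, 0.5]), method="L-BFGS-B",
                   bounds=[(1e-6, 1 - 1e-6), (1e-6, 1 - 1e-6)])
    return float(res.x[0]), float(res.x[1])


def score_nodes(scores: pd.DataFrame, graph: nx.Graph, pcut: float,
                method: str = "log10") -> ScoredGraph:
    """Transform p-values into signed node scores on the graph's largest
    connected component.

    ``method="log10"`` (default): s(v) = log10(pcut) - log10(max(p, 1e-300));
    a gene exactly at the threshold scores 0 and counts as intolerable.
    ``method="bum"``: beta-uniform-mixture scoring
    s(v) = (a - 1) * (ln p - ln pcut) with the shape a fitted by maximum
    likelihood — the same sign semantics on a data-adaptive scale (note the
    mixture can fit survival-scan p-value distributions poorly).
    Genes that are unscored (absent, skipped or failed fits) receive the
    median score of the intolerable scored nodes, so well-connected genes
    can still serve as linkers.
    """
    if not 0 < pcut < 1:
        raise ValueError("pcut must lie in (0, 1)")
    ok = scores[scores["status"] == "ok"]
    pmap = dict(zip(ok["gene"], ok["pval"]))
    lcc = _largest_component(graph)
    node_p = {v: pmap.get(v, np.nan) for v in lcc.nodes}
    if method == "log10":
        raw = {v: math.log10(pcut) - math.log10(max(p, P_EPS))
               for v, p in node_p.items() if np.isfinite(p)}
    elif method == "bum":
        finite = {v: p for v, p in node_p.items() if np.isfinite(p)}
        _, a = fit_bum(finite.values())
        raw = {v: (a - 1.0) * (math.log(max(p, P_EPS)) - math.log(pcut))
               for v, p in finite.items()}
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    if not any(s > 0 for s in raw.values()):
        raise ValueError("no nodes of interest at this threshold")
    negatives = sorted(s for s in raw.values() if s <= 0)
    fill = float(np.median(negatives)) if negatives else -1.0
    node_s = {v: raw.get(v, fill) for v in lcc.nodes}
    return ScoredGraph(graph=lcc, scores=node_s, pvals=node_p, pcut=pcut)


def _edge_cost(sg: ScoredGraph, u: str, v: str) -> float:
    s = sg.scores
    return max(-s[u], 0.0) / 2 + max(-s[v], 0.0) / 2 + EDGE_DELTA


def _mst_kruskal(nodes, edges):
    """Deterministic Kruskal on (weight, u, v, payload) tuples."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    chosen = []
    for w, u, v, payload in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v, payload))
    return chosen


def _best_subtree(tree: nx.Graph, scores: dict[str, float]) -> set[str]:
    """Maximum-weight connected subtree of `tree` by dynamic programming.

    best_down(v) = s(v) + sum over children of max(best_down(child), 0);
    the optimum is attached at the node maximising best_down, taking every
    child subtree with strictly positive contribution (deterministic)."""
    root = min(tree.nodes)
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for u in sorted(tree.neighbors(v), reverse=True):
            if u not in parent:
                parent[u] = v
                stack.append(u)
    best_down = {}
    for v in reversed(order):
        kids = [u for u in tree.neighbors(v) if parent.get(u) == v]
        best_down[v] = scores[v] + sum(max(best_down[u], 0.0) for u in kids)
    top = max(tree.nodes, key=lambda v: (best_down[v], v))
    keep = {top}
    stack = [top]
    while stack:
        v = stack.pop()
        for u in sorted(tree.neighbors(v)):
            if parent.get(u) == v and best_down[u] > 0:
                keep.add(u)
                stack.append(u)
    return keep


def max_scoring_subgraph(sg: ScoredGraph) -> ModuleResult:
    """MST-based heuristic for the maximum-scoring connected subgraph.

    Steps: per-edge costs from the negative endpoint scores; shortest paths
    between all positive nodes (metric closure); MST of the closure;
    expansion of closure edges into their underlying paths; iterative
    pruning of non-positive leaves; comparison against the best single
    positive node.  Fully deterministic: ties break on lexicographic ids.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(sg.graph.nodes))
    for u, v in sorted(map(sorted, sg.graph.edges())):
        g.add_edge(u, v, cost=_edge_cost(sg, u, v))
    positives = sorted(v for v, s in sg.scores.items() if s > 0)
    if not positives:
        raise ValueError("no positive-score nodes")

    best_single = max(positives, key=lambda v: (sg.scores[v], v))
    if len(positives) == 1:
        sub = g.subgraph([best_single]).copy()
        return ModuleResult(sub, sg.pcut, sg.scores[best_single],
                            sg.scores, sg.pvals)

    # metric closure over positive nodes
    closure_edges = []
    for src in positives:
        dist, paths = nx.single_source_dijkstra(g, src, weight="cost")
        for dst in positives:
            if dst > src and dst in dist:
                closure_edges.append((dist[dst], src, dst, tuple(paths[dst])))
    mst = _mst_kruskal(positives, closure_edges)

    tree = nx.Graph()
    for _, _, path in mst:
        nx.add_path(tree, path)
    if tree.number_of_nodes() == 0:
        tree.add_node(best_single)

    # pruning, generalised: the exact maximum-weight connected subtree of
    # the Steiner tree (tree DP) subsumes iterative removal of non-positive
    # leaves, and is equally deterministic
    keep = _best_subtree(tree, sg.scores)

    # deterministic closure: any adjacent positive node only adds score
    while True:
        addable = sorted(v for v in sg.graph.nodes
                         if v not in keep and sg.scores[v] > 0
                         and any(u in keep for u in sg.graph.neighbors(v)))
        if not addable:
            break
        keep.update(addable)

    # greedy augmentation: attach an excluded prize through its cheapest
    # path whenever the path's net score gain is positive
    while True:
        outside = [p for p in positives if p not in keep]
        if not outside:
            break
        _, paths = nx.multi_source_dijkstra(g, keep, weight="cost")
        best = None
        for p in sorted(outside):
            if p not in paths:
                continue
            new_nodes = [v for v in paths[p] if v not in keep]
            gain = sum(sg.scores[v] for v in new_nodes)
            if gain > 1e-12 and (best is None or gain > best[0]):
                best = (gain, new_nodes)
        if best is None:
            break
        keep.update(best[1])

    # redundancy cleanup: a negative node off the cut set (cycles can make
    # a linker redundant) is dropped, most negative first
    while len(keep) > 1:
        arts = set(nx.articulation_points(sg.graph.subgraph(keep)))
        removable = [v for v in keep if sg.scores[v] < 0 and v not in arts]
        if not removable:
            break
        keep.remove(min(removable, key=lambda v: (sg.scores[v], v)))

    # the module is the induced subgraph on the selected nodes (modules are
    # generally not trees)
    sub = sg.graph.subgraph(keep).copy()
    total = sum(sg.scores[v] for v in sub.nodes)
    if sg.scores[best_single] > total:
        sub = sg.graph.subgraph([best_single]).copy()
        total = sg.scores[best_single]
    return ModuleResult(sub, sg.pcut, float(total), sg.scores, sg.pvals)


def _module_at(scores: pd.DataFrame, graph: nx.Graph, pcut: float):
    try:
        return max_scoring_subgraph(score_nodes(scores, graph, pcut))
    except ValueError:
        return None


def search_fixed_size(scores: pd.DataFrame, graph: nx.Graph,
                      target_size: int, tol: int = 2,
                      max_iter: int = 30) -> ModuleResult:
    """Tune the tolerable p-value threshold to hit a requested module size.

    Bisects over the ladder of observed unique p-values; returns the first
    module within ``tol`` nodes of the target, else the closest one seen
    (ties toward the more stringent threshold).  If the target is not
    reachable a best-effort module carries a warning flag.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    ok = scores[(scores["status"] == "ok")]
    present = ok[ok["gene"].isin(graph.nodes)]
    ladder = np.sort(present["pval"].unique())
    ladder = ladder[(ladder > 0) & (ladder < 1)]
    if ladder.size == 0:
        raise ValueError("no usable p-values to tune over")
    # candidate thresholds sit strictly between consecutive observed
    # p-values (geometric midpoints; p = tau itself scores 0), plus one
    # candidate just above the largest p so every gene can turn positive
    mids = np.sqrt(ladder[:-1] * ladder[1:]) if ladder.size > 1 else np.array([])
    top = min(1.0 - 1e-12, float(ladder[-1]) * 1.001)
    cands = np.unique(np.append(mids, top))

    best = None  # (|size-target|, tau, module)

    def consider(tau, module):
        nonlocal best
        if module is None:
            return None
        key = (abs(module.size - target_size), tau)
        if best is None or key < (best[0], best[1]):
            best = (key[0], tau, module)
        return module.size

    lo, hi = 0, len(cands) - 1
    for _ in range(max_iter):
        if lo > hi:
            break
        mid = (lo + hi) // 2
        tau = float(cands[mid])
        size = consider(tau, _module_at(scores, graph, tau))
        if size is not None and abs(size - target_size) <= tol:
            break
        if size is None or size < target_size:
            lo = mid + 1
        else:
            hi = mid - 1

    if best is None:
        raise ValueError("no threshold produced a module")
    _, tau, module = best
    if abs(module.size - target_size) > tol:
        module.warning = (f"target size {target_size} +/- {tol} unreachable; "
                          f"closest module has {module.size} nodes")
        logger.warning(module.warning)
    return module


def write_module_graphml(module: ModuleResult, path) -> None:
    g = nx.Graph()
    for v in module.nodes:
        g.add_node(v, score=float(module.scores[v]),
                   pval=float(module.pvals.get(v, np.nan)))
    g.add_edges_from(module.edges)
    nx.write_graphml(g, path)
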