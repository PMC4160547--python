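"""Tumour-type relationships derived from the module.

Two complementary views: a self-organising 2D landscape trained on
degree-penalised per-edge mutation-frequency differences, and a bootstrap
neighbour-joining tree over per-type mutation-frequency profiles.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .module_search import ModuleResult

logger = logging.getLogger(__name__)


def edge_transform(module: ModuleResult, freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-edge, per-tumour-type feature e^k = |f_i^k/d_i - f_j^k/d_j|.

    f are within-type mutation frequencies of the edge's end nodes, d their
    degrees in the module subgraph (not the full network): frequency
    differences are penalised by connectivity, so hub edges contribute less.
    """
    missing = sorted(set(module.nodes) - set(freqs.index))
    if missing:
        raise ValueError(f"module genes missing from frequency matrix: {missing}")
    if module.size < 2:
        logger.warning("single-node module: empty edge-feature matrix")
        return pd.DataFrame(columns=freqs.columns)
    deg = dict(module.subgraph.degree())
    rows, index = [], []
    for u, v in module.edges:
        rows.append(np.abs(freqs.loc[u].to_numpy() / deg[u]
                           - freqs.loc[v].to_numpy() / deg[v]))
        index.append(f"{u}|{v}")
    return pd.DataFrame(rows, index=index, columns=freqs.columns)


@dataclass
class Landscape:
    rows: int
    cols: int
    codebook: np.ndarray            # (rows * cols, n_features)
    assignments: dict[str, int]     # sample -> best-matching cell index
    quantisation_errors: list[float]  # recorded at the end of each phase
    epochs: tuple[int, int]
    seed: int
    degenerate: bool = False

    def cell_coords(self, cell: int) -> tuple[int, int]:
        return divmod(cell, self.cols)

    def to_frame(self) -> pd.DataFrame:
        coords = {s: self.cell_coords(c) for s, c in self.assignments.items()}
        return pd.DataFrame(
            [(s, c, coords[s][0], coords[s][1])
             for s, c in sorted(self.assignments.items())],
            columns=["sample", "cell", "row", "col"])


def _grid_distances(rows: int, cols: int) -> np.ndarray:
    r, c = np.divmod(np.arange(rows * cols), cols)
    return np.sqrt((r[:, None] - r[None, :]) ** 2
                   + (c[:, None] - c[None, :]) ** 2)


def _quantisation_error(X: np.ndarray, codebook: np.ndarray) -> float:
    d = np.linalg.norm(X[:, None, :] - codebook[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def som_landscape(features: pd.DataFrame, rows: int = 6, cols: int = 6,
                  epochs: tuple[int, int] = (100, 400),
                  seed: int = 0) -> Landscape:
    """Train a self-organising map of tumour types on the edge features.

    Samples are the tumour types (columns of the edge-feature matrix).  The
    codebook is initialised on the plane of the first two principal
    components, then trained online in a rough and a fine phase (Gaussian
    neighbourhood, linearly decaying radius and learning rate).  With the
    grid, epochs and seed fixed the assignment is deterministic.
    """
    samples = list(features.columns)
    X = features.to_numpy(float).T            # (n_samples, n_features)
    if len(samples) < 2 or rows * cols < 2:
        raise ValueError("need >= 2 samples and >= 2 grid cells")
    n, p = X.shape
    rng = np.random.default_rng(seed)

    degenerate = bool(np.ptp(X, axis=0).max() == 0) if X.size else True

    # PCA-plane initialisation; falls back to small seeded noise when the
    # samples are degenerate
    mean = X.mean(axis=0)
    Xc = X - mean
    codebook = np.tile(mean, (rows * cols, 1))
    if not degenerate:
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        k = min(2, vt.shape[0])
        r, c = np.divmod(np.arange(rows * cols), cols)
        axes = [(r / max(rows - 1, 1) - 0.5), (c / max(cols - 1, 1) - 0.5)]
        for i in range(k):
            scale = 2.0 * s[i] / max(np.sqrt(n - 1), 1.0)
            codebook = codebook + np.outer(axes[i] * scale, vt[i])
    else:
        codebook = codebook + rng.normal(scale=1e-9, size=codebook.shape)

    grid_d = _grid_distances(rows, cols)
    diag = np.sqrt((rows - 1) ** 2 + (cols - 1) ** 2)
    phases = [
        (epochs[0], diag / 2.0, 1.0, 0.5, 0.05),   # rough
        (epochs[1], 1.0, 0.1, 0.05, 0.01),         # fine
    ]
    qerrors = []
    for n_epochs, r0, r1, lr0, lr1 in phases:
        total = max(n_epochs, 1)
        for epoch in range(n_epochs):
            frac = epoch / total
            radius = max(r0 + (r1 - r0) * frac, 1e-3)
            lr = lr0 + (lr1 - lr0) * frac
            for i in rng.permutation(n):
                d = np.linalg.norm(codebook - X[i], axis=1)
                bmu = int(np.argmin(d))
                h = np.exp(-(grid_d[bmu] ** 2) / (2 * radius ** 2))
                codebook += (lr * h)[:, None] * (X[i] - codebook)
        qerrors.append(_quantisation_error(X, codebook))

    assignments = {}
    for i, sample in enumerate(samples):
        d = np.linalg.norm(codebook - X[i], axis=1)
        assignments[sample] = int(np.argmin(d))
    if degenerate:
        logger.warning("all samples identical: every type maps to one cell")
    return Landscape(rows=rows, cols=cols, codebook=codebook,
                     assignments=assignments, quantisation_errors=qerrors,
                     epochs=epochs, seed=seed, degenerate=degenerate)


@dataclass
class SupportTree:
    tree: TreeNode
    supports: dict[frozenset, float]   # non-trivial bipartition -> support
    newick: str
    boot_reps: int


def _bipartitions(tree: TreeNode, leaves: frozenset) -> set[frozenset]:
    """Canonical non-trivial bipartitions (smaller side, ties by sorted
    tuple) of an unrooted tree given as a rooted TreeNode."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            canon = min((side, other),
                        key=lambda s: (len(s), tuple(sorted(s))))
            out.add(canon)
    return out


def _nj_from_matrix(dm: np.ndarray, ids: list[str]) -> TreeNode:
    # neighbour joining needs strictly valid dissimilarities; jitter-free
    return nj(DistanceMatrix(dm, ids))


def nj_tree(freqs: pd.DataFrame, boot_reps: int = 100,
            seed: int = 0) -> SupportTree:
    """Neighbour-joining tree of tumour types from module-gene mutation
    frequencies, with gene-resampling bootstrap supports.

    Distances are Euclidean between per-type frequency columns; supports
    are bipartition recovery fractions over ``boot_reps`` resamples of the
    gene rows.
    """
    types = list(freqs.columns)
    if len(types) < 2:
        raise ValueError("need >= 2 tumour types")
    X = freqs.to_numpy(float)

    def dist(M):
        d = np.linalg.norm(M[:, None, :] - M[None, :, :], axis=2)
        return (d + d.T) / 2.0

    if len(types) == 2:
        d = float(np.linalg.norm(X[:, 0] - X[:, 1]))
        newick = f"({types[0]}:{d / 2:.6g},{types[1]}:{d / 2:.6g});"
        tree = TreeNode.read(io.StringIO(newick))
        return SupportTree(tree=tree, supports={}, newick=newick,
                           boot_reps=boot_reps)

    ref = _nj_from_matrix(dist(X.T), types)
    leaves = frozenset(types)
    ref_bip = _bipartitions(ref, leaves)
    counts = {b: 0 for b in ref_bip}
    rng = np.random.default_rng(seed)
    for _ in range(boot_reps):
        rows = rng.integers(0, X.shape[0], size=X.shape[0])
        bt = _nj_from_matrix(dist(X[rows].T), types)
        got = _bipartitions(bt, leaves)
        for b in counts:
            if b in got:
                counts[b] += 1
    supports = {b: c / boot_reps for b, c in counts.items()}

    # stamp supports onto internal node names for newick output
    for node in ref.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min((side, leaves - side),
                    key=lambda s: (len(s), tuple(sorted(s))))
        if canon in supports:
            node.name = f"{supports[canon]:.2f}"
    newick = str(ref).strip()
    return SupportTree(tree=ref, supports=supports, newick=newick,
                       boot_reps=boot_reps)
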