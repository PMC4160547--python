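"""Synthetic cohorts with a planted survival-associated connected module.

The generator draws an interaction graph, plants a connected gene module,
gives module genes an elevated Poisson mutation rate, and draws exponential
survival times whose hazard is proportional to exp(beta * total module
mutations + clinical covariate effects).  Because the data-generating model
is proportional hazards, Cox parameter-recovery tests against it are
well-posed.  Censoring is independent exponential, calibrated so the
expected censored fraction matches the configured rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (AnalysisBundle, ClinicalTable, MutationMatrix,
                        harmonise, write_network)
from .module_search import search_fixed_size
from .survival import cox_lrt_per_gene

DEFAULT_TYPES = {"BRCA": 0.4, "GBM": 0.3, "KIRC": 0.2, "LUAD": 0.1}
# per-type baseline log-hazard offsets, applied in alphabetical label order
TYPE_LOG_HAZARDS = (0.0, 0.4, -0.3, 0.2)


@dataclass
class SimulationConfig:
    n_patients: int = 600
    n_genes: int = 500
    tumour_types: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPES))
    network_model: str = "ba"          # "ba" (Barabasi-Albert) or "er"
    ba_m: int = 2
    er_p: float = 0.01
    module_size: int = 15
    beta: float = 1.0                  # log-hazard per module mutation
    lam_mod: float = 0.3               # Poisson rate, module genes
    lam_bg: float = 0.05               # Poisson rate, background genes
    censoring: float = 0.3             # target censored fraction
    age_beta: float = 0.0              # log-hazard per year of (age - 60)
    gender_beta: float = 0.0           # log-hazard for male vs female
    #: per-type baseline log-hazard offsets, cycled over alphabetical labels
    type_log_hazards: tuple = TYPE_LOG_HAZARDS
    baseline_hazard: float = 1e-3      # events per day
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size exceeds n_genes")
        if min(self.lam_mod, self.lam_bg) < 0:
            raise ValueError("mutation rates must be >= 0")
        if abs(sum(self.tumour_types.values()) - 1.0) > 1e-9:
            raise ValueError("tumour-type proportions must sum to 1")


@dataclass
class SimulatedCohort:
    bundle: AnalysisBundle
    module_nodes: list[str]
    module_edges: list[tuple[str, str]]
    beta: float
    hazards: np.ndarray
    config: SimulationConfig


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def _planted_module(graph: nx.Graph, size: int,
                    rng: np.random.Generator) -> list[str]:
    """Pick a connected subgraph of `size` nodes by seeded BFS."""
    nodes = sorted(graph.nodes)
    for _ in range(10):
        start = nodes[rng.integers(len(nodes))]
        seen, frontier = [start], [start]
        seen_set = {start}
        while frontier and len(seen) < size:
            nxt = frontier.pop(0)
            for nb in sorted(graph.neighbors(nxt)):
                if nb not in seen_set:
                    seen_set.add(nb)
                    seen.append(nb)
                    frontier.append(nb)
                    if len(seen) == size:
                        break
        if len(seen) == size:
            return seen
    raise RuntimeError("could not grow a connected module of the requested size")


def _censor_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate whose expected censored fraction (over the
    cohort's heterogeneous hazards) equals `target`."""
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = float(np.mean(mid / (mid + hazards)))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes))
    genes = [_gene_name(i + 1, width) for i in range(cfg.n_genes)]

    if cfg.network_model == "ba":
        raw = nx.barabasi_albert_graph(cfg.n_genes, cfg.ba_m,
                                       seed=int(rng.integers(2**31)))
    elif cfg.network_model == "er":
        raw = nx.gnp_random_graph(cfg.n_genes, cfg.er_p,
                                  seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown network model {cfg.network_model!r}")
    graph = nx.relabel_nodes(raw, {i: genes[i] for i in range(cfg.n_genes)})
    graph.remove_nodes_from([n for n, d in graph.degree() if d == 0])

    module = _planted_module(graph, cfg.module_size, rng)
    module_set = set(module)
    module_edges = sorted(tuple(sorted(e))
                          for e in graph.subgraph(module).edges)

    lam = np.where([g in module_set for g in genes], cfg.lam_mod, cfg.lam_bg)
    counts = rng.poisson(lam, size=(cfg.n_patients, cfg.n_genes))
    patients = [f"P{i + 1:04d}" for i in range(cfg.n_patients)]
    counts_df = pd.DataFrame(counts, index=patients, columns=genes)

    labels = sorted(cfg.tumour_types)
    probs = np.array([cfg.tumour_types[t] for t in labels])
    t_idx = rng.choice(len(labels), size=cfg.n_patients, p=probs)
    age = rng.normal(60.0, 10.0, size=cfg.n_patients)
    male = rng.integers(0, 2, size=cfg.n_patients)
    offs = cfg.type_log_hazards or (0.0,)
    type_off = np.array([offs[i % len(offs)] for i in range(len(labels))])

    module_burden = counts_df[module].sum(axis=1).to_numpy(float)
    log_h = (np.log(cfg.baseline_hazard)
             + cfg.beta * module_burden
             + cfg.age_beta * (age - 60.0)
             + cfg.gender_beta * male
             + type_off[t_idx])
    hazards = np.exp(log_h)
    death = rng.exponential(1.0 / hazards)
    lam_c = _censor_rate(hazards, cfg.censoring)
    censor = (rng.exponential(1.0 / lam_c, size=cfg.n_patients)
              if lam_c > 0 else np.full(cfg.n_patients, np.inf))
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    clinical = ClinicalTable(pd.DataFrame({
        "patient": patients,
        "time": np.maximum(time, 1e-6),
        "event": event,
        "age": np.round(age, 1),
        "gender": np.where(male == 1, "male", "female"),
        "tumour_type": [labels[i] for i in t_idx],
    }))
    bundle = harmonise(MutationMatrix(counts_df), clinical, graph)
    return SimulatedCohort(bundle=bundle, module_nodes=sorted(module),
                           module_edges=module_edges, beta=cfg.beta,
                           hazards=hazards, config=cfg)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, str]:
    """Emit the cohort as the three standard TSVs + GraphML + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
        "network": outdir / "network.graphml",
        "truth": outdir / "truth.json",
    }
    cohort.bundle.mutations.to_tsv(paths["mutations"])
    cohort.bundle.clinical.to_tsv(paths["clinical"])
    write_network(cohort.bundle.graph, str(paths["network"]))
    cfg = asdict(cohort.config)
    with open(paths["truth"], "w") as fh:
        json.dump({"planted_genes": cohort.module_nodes,
                   "planted_edges": [list(e) for e in cohort.module_edges],
                   "beta": cohort.beta, "seed": cohort.config.seed,
                   "config": cfg}, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def recovery_harness(cohort: SimulatedCohort, target_size: int | None = None,
                     min_mutated: int = 2, tol: int = 2) -> dict[str, float]:
    """Score -> fixed-size search -> compare with the planted module.

    Returns precision, recall and F1 over module nodes.
    """
    if target_size is None:
        target_size = len(cohort.module_nodes)
    scores = cox_lrt_per_gene(cohort.bundle, min_mutated=min_mutated)
    module = search_fixed_size(scores, cohort.bundle.graph,
                               target_size=target_size, tol=tol)
    found = set(module.nodes)
    truth = set(cohort.module_nodes)
    tp = len(found & truth)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "size": float(len(found))}
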