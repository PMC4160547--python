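"""statsmodels-style front door.

``SurvivalNetworkModel`` holds the harmonised inputs; ``fit`` runs the
per-gene Cox LRT scan and the maximum-scoring subgraph search and returns a
``SurvivalNetworkResults`` carrying the gene score table, the module and
its diagnostics, with the interpretation stages (robustness, randomisation,
enrichment, landscape, tree) as results methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import enrichment as _enr
from . import landscape as _ls
from . import network_stats as _ns
from . import survival as _sv
from .datatypes import (AnalysisBundle, ClinicalTable, MutationMatrix,
                        harmonise, load_clinical, load_mutation_matrix,
                        load_network)
from .module_search import ModuleResult, score_nodes, max_scoring_subgraph, \
    search_fixed_size


class SurvivalNetworkModel:
    """Patient-survival gene-network model over a mutation matrix, clinical
    survival table and gene interaction graph."""

    def __init__(self, bundle: AnalysisBundle):
        self.bundle = bundle
        self._design = None

    @classmethod
    def from_dataframes(cls, mutations: pd.DataFrame, clinical: pd.DataFrame,
                        graph: nx.Graph) -> "SurvivalNetworkModel":
        return cls(harmonise(MutationMatrix(mutations),
                             ClinicalTable(clinical), graph))

    @classmethod
    def from_files(cls, mutations_tsv, clinical_tsv,
                   network_path) -> "SurvivalNetworkModel":
        return cls(harmonise(load_mutation_matrix(mutations_tsv),
                             load_clinical(clinical_tsv),
                             load_network(network_path)))

    @property
    def design(self) -> _sv.CovariateDesign:
        if self._design is None:
            self._design = _sv.build_design(self.bundle)
        return self._design

    def score_genes(self, min_mutated: int = 2,
                    binarise: bool = False) -> pd.DataFrame:
        return _sv.cox_lrt_per_gene(self.bundle, min_mutated=min_mutated,
                                    binarise=binarise, design=self.design)

    def fit(self, pcut: float | None = None, size: int | None = None,
            tol: int = 2, min_mutated: int = 2, binarise: bool = False,
            scoring: str = "log10") -> "SurvivalNetworkResults":
        """Score genes and extract the module.

        Exactly one of ``pcut`` (tolerable p-value threshold) or ``size``
        (desired module node count, tuned by threshold bisection) must be
        given; default is ``pcut=0.05``.  ``scoring`` selects the node-score
        transform ("log10" or "bum") for threshold-based fits.
        """
        if pcut is not None and size is not None:
            raise ValueError("give either pcut or size, not both")
        scores = self.score_genes(min_mutated=min_mutated, binarise=binarise)
        if size is not None:
            module = search_fixed_size(scores, self.bundle.graph,
                                       target_size=size, tol=tol)
        else:
            sg = score_nodes(scores, self.bundle.graph,
                             0.05 if pcut is None else pcut, method=scoring)
            module = max_scoring_subgraph(sg)
        return SurvivalNetworkResults(self, scores, module)


@dataclass
class SurvivalNetworkResults:
    model: SurvivalNetworkModel
    gene_scores: pd.DataFrame
    module: ModuleResult

    # -- derived tables ----------------------------------------------------
    def mutation_frequency(self) -> pd.DataFrame:
        return _sv.mutation_frequency(self.model.bundle)

    def ubiquity(self) -> pd.Series:
        return _sv.ubiquity_table(self.mutation_frequency())

    def combination_curve(self, genes: list[str] | None = None) -> pd.DataFrame:
        genes = self.module.nodes if genes is None else genes
        return _sv.cox_combination(self.model.bundle, self.gene_scores,
                                   genes, design=self.model.design)

    # -- network statistics ------------------------------------------------
    def communities(self) -> tuple[dict[str, str], pd.DataFrame]:
        partition = _ns.detect_communities(self.module.subgraph)
        return partition, _ns.community_significance(self.module, partition)

    def edge_confidence(self, tol: int = 2) -> pd.DataFrame:
        return _ns.loo_edge_confidence(self.model.bundle, self.module, tol=tol)

    def edge_significance(self, R: int = 100, n_bins: int = 10,
                          seed: int = 0) -> _ns.EdgeSignificance:
        return _ns.edge_significance(self.model.bundle, self.module, R=R,
                                     n_bins=n_bins, seed=seed,
                                     scores=self.gene_scores)

    # -- enrichment --------------------------------------------------------
    def gsea_hr(self, weight: float = 1.0, R: int = 1000,
                seed: int = 0) -> _enr.GseaResult:
        ranking = _enr.rank_builders(scores=self.gene_scores)["hr"]
        return _enr.gsea(ranking, set(self.module.nodes), weight=weight,
                         R=R, seed=seed)

    def enrich(self, collection, background=None) -> pd.DataFrame:
        bg = (set(self.model.bundle.mutations.gene_ids)
              if background is None else set(background))
        return _enr.hypergeom_enrich(set(self.module.nodes), collection, bg)

    def phylostratum(self, ages) -> pd.DataFrame:
        return _enr.phylostratum_enrich(set(self.module.nodes), ages)

    # -- landscape ---------------------------------------------------------
    def edge_features(self) -> pd.DataFrame:
        return _ls.edge_transform(self.module, self.mutation_frequency())

    def landscape(self, rows: int = 6, cols: int = 6,
                  epochs: tuple[int, int] = (100, 400),
                  seed: int = 0) -> _ls.Landscape:
        return _ls.som_landscape(self.edge_features(), rows=rows, cols=cols,
                                 epochs=epochs, seed=seed)

    def nj_tree(self, boot_reps: int = 100, seed: int = 0) -> _ls.SupportTree:
        freqs = self.mutation_frequency().loc[self.module.nodes]
        return _ls.nj_tree(freqs, boot_reps=boot_reps, seed=seed)

    # -- reporting ---------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        b = self.model.bundle
        ok = self.gene_scores[self.gene_scores["status"] == "ok"]
        lines = [
            "Survival network results",
            "=" * 24,
            f"patients: {b.n_patients}   genes scored: {len(ok)} "
            f"(of {len(self.gene_scores)})",
            f"tumour types: {', '.join(b.clinical.tumour_types)}",
            f"module: {self.module.size} genes, {len(self.module.edges)} edges, "
            f"total score {self.module.total_score:.3f} at p-cut "
            f"{self.module.pcut:.3g}",
        ]
        if self.module.warning:
            lines.append(f"warning: {self.module.warning}")
        frame = self.module.to_frame().sort_values("pval").head(top)
        hr = ok.set_index("gene")["hr"]
        frame["hr"] = [hr.get(g, float("nan")) for g in frame["gene"]]
        lines.append("")
        lines.append(frame.to_string(index=False,
                                     float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
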