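"""Domain containers and file I/O.

Everything downstream works on three harmonised inputs: a patient x gene
somatic-mutation count matrix, a per-patient clinical survival table and an
undirected gene interaction graph.  Gene-set collections (GMT) and gene-age
tables feed the enrichment stages.

Gene and patient identifiers are case-sensitive strings; no identifier
mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("patient", "time", "event", "age", "gender", "tumour_type")


@dataclass
class MutationMatrix:
    """Patients x genes non-negative integer mutation counts.

    ``counts`` is a DataFrame indexed by patient id with gene-id columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.counts.index, self.counts.columns
        dup_p = idx[idx.duplicated()].unique().tolist()
        dup_g = cols[cols.duplicated()].unique().tolist()
        if dup_p or dup_g:
            raise ValueError(
                f"duplicate identifiers: patients={dup_p} genes={dup_g}"
            )
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric mutation counts")
        if values.size:
            if np.any(values < 0):
                raise ValueError("negative count in mutation matrix")
            if not np.allclose(values, np.round(values)):
                raise ValueError("non-integer count in mutation matrix")
        self.counts = self.counts.astype(np.int64)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_nonzero(self) -> int:
        return int((self.counts.to_numpy() != 0).sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="patient")


@dataclass
class ClinicalTable:
    """One row per patient: survival time (days, > 0), event (1 = death
    observed, 0 = censored), age (years), gender and tumour type.

    Gender and tumour-type labels are kept verbatim as pandas categories.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CLINICAL_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"missing clinical column(s): {missing}")
        t = t.loc[:, list(CLINICAL_COLUMNS)].copy()
        dup = t["patient"][t["patient"].duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate patient identifiers: {dup}")
        t["time"] = pd.to_numeric(t["time"])
        t["event"] = pd.to_numeric(t["event"])
        t["age"] = pd.to_numeric(t["age"])
        if (t["time"] <= 0).any():
            bad = t.loc[t["time"] <= 0, "patient"].tolist()
            raise ValueError(f"survival time must be > 0 (patients {bad})")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")
        t["event"] = t["event"].astype(np.int64)
        t["gender"] = t["gender"].astype("category")
        t["tumour_type"] = t["tumour_type"].astype("category")
        t = t.set_index("patient", drop=False)
        t.index.name = None
        self.table = t

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient"])

    @property
    def tumour_types(self) -> list[str]:
        return list(self.table["tumour_type"].cat.categories)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AnalysisBundle:
    """Harmonised mutation matrix + clinical table + interaction graph."""

    mutations: MutationMatrix
    clinical: ClinicalTable
    graph: nx.Graph

    def __post_init__(self) -> None:
        if self.mutations.patient_ids != self.clinical.patient_ids:
            raise ValueError("bundle patients are not aligned")

    @property
    def n_patients(self) -> int:
        return len(self.mutations.patient_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and an optional acyclic
    parent -> child term hierarchy."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    #: directed (parent, child) term relations
    relations: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class AgeTable:
    """Gene -> phylostratum (ancestor) assignments.

    ``order`` lists ancestors oldest to youngest; ``repertoires`` maps each
    ancestor to its full gene repertoire (the enrichment background).
    """

    ages: dict[str, str]
    order: list[str]
    repertoires: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ancestor order contains duplicates")
        unknown = sorted({a for a in self.ages.values()} - set(self.order))
        if unknown:
            raise ValueError(f"ancestors missing from order: {unknown}")


# ---------------------------------------------------------------------------
# readers / writers


def load_mutation_matrix(path) -> MutationMatrix:
    """Read a TSV with a gene-id header row and patient ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MutationMatrix(df)


def load_clinical(path) -> ClinicalTable:
    """Read a clinical TSV; columns matched by name, any order."""
    return ClinicalTable(pd.read_csv(path, sep="\t"))


def load_network(path) -> nx.Graph:
    """Read an undirected gene graph from GraphML or a 2-column edge list.

    Self-loops are dropped (logged), duplicate edges collapse, and isolated
    nodes are removed: they can never join a connected module.
    """
    path = str(path)
    if path.endswith((".graphml", ".xml")):
        raw = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in raw.nodes)
        g.add_edges_from((str(u), str(v)) for u, v in raw.edges)
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1], dtype=str)
        if df.empty:
            raise ValueError("empty network file")
        g = nx.Graph()
        g.add_edges_from(df.itertuples(index=False, name=None))
    loops = list(nx.selfloop_edges(g))
    if loops:
        logger.info("dropping %d self-loop(s)", len(loops))
        g.remove_edges_from(loops)
    isolated = [n for n, d in g.degree() if d == 0]
    if isolated:
        logger.info("dropping %d isolated node(s)", len(isolated))
        g.remove_nodes_from(isolated)
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty after cleaning")
    return g


def write_network(g: nx.Graph, path) -> None:
    path = str(path)
    if path.endswith((".graphml", ".xml")):
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            for u, v in sorted(map(sorted, g.edges())):
                fh.write(f"{u}\t{v}\n")


def load_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, members = parts[0], parts[1], parts[2:]
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    if not sets:
        raise ValueError("no gene sets parsed from GMT")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def load_age_table(ages_path, repertoire_gmt_path) -> AgeTable:
    """Two-column TSV (gene, ancestor) plus a repertoire GMT whose line
    order gives the ancestor order, oldest first."""
    df = pd.read_csv(ages_path, sep="\t", header=None, names=["gene", "ancestor"],
                     dtype=str)
    rep = load_gmt(repertoire_gmt_path)
    order = list(rep.sets)
    return AgeTable(
        ages=dict(zip(df["gene"], df["ancestor"])),
        order=order,
        repertoires={k: set(v) for k, v in rep.sets.items()},
    )


def harmonise(mm: MutationMatrix, clin: ClinicalTable,
              graph: nx.Graph) -> AnalysisBundle:
    """Restrict to patients with both mutation and survival information.

    Patient order follows the mutation matrix.  Genes are retained even if
    absent from the graph; restriction to the graph happens at module search.
    """
    keep = [p for p in mm.patient_ids if p in set(clin.patient_ids)]
    if not keep:
        raise ValueError("no patients shared between mutation matrix and clinical table")
    dropped_mm = len(mm.patient_ids) - len(keep)
    dropped_cl = len(clin.patient_ids) - len(keep)
    if dropped_mm or dropped_cl:
        logger.info("harmonise: dropped %d matrix-only and %d clinical-only patients",
                    dropped_mm, dropped_cl)
    counts = mm.counts.loc[keep]
    table = clin.table.loc[keep].copy()
    table["tumour_type"] = table["tumour_type"].cat.remove_unused_categories()
    table["gender"] = table["gender"].cat.remove_unused_categories()
    return AnalysisBundle(MutationMatrix(counts), ClinicalTable(table), graph)
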