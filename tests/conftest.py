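import networkx as nx
import numpy as np
import pandas as pd
import pytest

from survnet import (ClinicalTable, MutationMatrix, SimulationConfig,
                     harmonise, simulate_cohort)


def make_clinical(patients, times, events, types, genders=None, ages=None):
    n = len(patients)
    return ClinicalTable(pd.DataFrame({
        "patient": patients,
        "time": times,
        "event": events,
        "age": ages if ages is not None else np.linspace(50, 70, n),
        "gender": genders if genders is not None else ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "tumour_type": types,
    }))


@pytest.fixture(scope="session")
def small_cohort():
    """120 patients, 60 genes, planted 6-gene module with a strong effect."""
    cfg = SimulationConfig(n_patients=120, n_genes=60, module_size=6,
                           beta=1.2, lam_mod=0.4, lam_bg=0.08, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Hand-built 8-patient bundle over a 5-gene path graph."""
    rng = np.random.default_rng(5)
    genes = ["GA", "GB", "GC", "GD", "GE"]
    patients = [f"P{i}" for i in range(1, 9)]
    counts = pd.DataFrame(rng.poisson(0.6, size=(8, 5)),
                          index=patients, columns=genes)
    clinical = make_clinical(patients,
                             times=[100, 210, 150, 400, 90, 330, 60, 500],
                             events=[1, 1, 0, 1, 1, 0, 1, 1],
                             types=["GBM", "GBM", "GBM", "GBM",
                                    "BRCA", "BRCA", "BRCA", "BRCA"])
    g = nx.path_graph(genes)
    return harmonise(MutationMatrix(counts), clinical, g)
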