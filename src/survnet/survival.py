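"""Per-gene Cox likelihood-ratio scoring, gene-combination curves, mutation
frequencies and the cross-tumour mutation-ubiquity statistic.

Each gene's mutation-count vector is tested by comparing the full Cox model
(age + gender + tumour type + gene) against the clinical baseline
(age + gender + tumour type) with a likelihood-ratio test; the LRT statistic
is referred to chi-square with 1 df and the hazard ratio is exp(beta_gene).
Mutation counts enter untransformed as integers; a binarise option exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._coxph import _EfronData, fit_cox
from .datatypes import AnalysisBundle

logger = logging.getLogger(__name__)

PVAL_FLOOR = 1e-300

SCORE_COLUMNS = ["gene", "hr", "pval", "lrt_stat", "n_mutated", "status"]


@dataclass
class CovariateDesign:
    """Clinical baseline design: centred age, a gender indicator, tumour-type
    dummies against the alphabetically first reference level.

    Zero-variance columns are dropped with a warning; reference-level choice
    does not affect the gene term's LRT or HR.
    """

    matrix: np.ndarray
    names: list[str]
    time: np.ndarray
    event: np.ndarray
    data: _EfronData
    base_beta: np.ndarray
    base_loglik: float


def build_design(bundle: AnalysisBundle) -> CovariateDesign:
    clin = bundle.clinical.table
    time = clin["time"].to_numpy(float)
    event = clin["event"].to_numpy(int)
    if len(np.unique(time[event == 1])) < 2:
        raise ValueError("need >= 2 distinct event times")
    cols: list[np.ndarray] = []
    names: list[str] = []
    age = clin["age"].to_numpy(float)
    cols.append(age - age.mean())
    names.append("age")
    genders = sorted(clin["gender"].cat.categories)
    if len(genders) >= 2:
        cols.append((clin["gender"] == genders[-1]).to_numpy(float))
        names.append(f"gender[{genders[-1]}]")
    types = sorted(clin["tumour_type"].cat.categories)
    for t in types[1:]:
        cols.append((clin["tumour_type"] == t).to_numpy(float))
        names.append(f"tumour_type[{t}]")
    keep = [i for i, c in enumerate(cols) if np.ptp(c) > 0]
    if len(keep) < len(cols):
        dropped = [names[i] for i in range(len(cols)) if i not in keep]
        logger.warning("dropping zero-variance covariate(s): %s", dropped)
    X = np.column_stack([cols[i] for i in keep]) if keep else np.empty((len(time), 0))
    names = [names[i] for i in keep]
    data = _EfronData(time, event)
    if X.shape[1]:
        base = fit_cox(X, time, event, data=data)
        if not base.converged:
            raise RuntimeError("baseline Cox model failed to converge")
        base_beta, base_ll = base.beta, base.loglik
    else:
        from ._coxph import null_loglik
        base_beta = np.zeros(0)
        base_ll = null_loglik(time, event, data=data)
    return CovariateDesign(X, names, time, event, data, base_beta, base_ll)


def _lrt_one(design: CovariateDesign, x: np.ndarray):
    """Fit baseline + one extra column; return (hr, pval, lrt, ok)."""
    Xf = np.column_stack([design.matrix, x])
    init = np.append(design.base_beta, 0.0)
    fit = fit_cox(Xf, design.time, design.event, init=init, data=design.data)
    if not fit.converged:
        return np.nan, np.nan, np.nan, False
    lrt = max(0.0, 2.0 * (fit.loglik - design.base_loglik))
    pval = max(float(stats.chi2.sf(lrt, df=1)), PVAL_FLOOR)
    hr = float(np.exp(fit.beta[-1]))
    return hr, pval, lrt, True


def cox_lrt_per_gene(bundle: AnalysisBundle, min_mutated: int = 2,
                     binarise: bool = False,
                     design: CovariateDesign | None = None) -> pd.DataFrame:
    """Score every gene in the mutation matrix by Cox LRT.

    Returns a table with columns gene, hr, pval, lrt_stat, n_mutated and
    status in {ok, skipped, failed}; genes mutated in fewer than
    ``min_mutated`` patients (or with a constant mutation vector) are
    skipped, non-converged fits are flagged failed — never fabricated.
    """
    if design is None:
        design = build_design(bundle)
    counts = bundle.mutations.counts
    rows = []
    for gene in counts.columns:
        x = counts[gene].to_numpy(float)
        if binarise:
            x = (x > 0).astype(float)
        n_mut = int((x > 0).sum())
        if n_mut < min_mutated or np.ptp(x) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, n_mut, "skipped"))
            continue
        hr, pval, lrt, ok = _lrt_one(design, x)
        rows.append((gene, hr, pval, lrt, n_mut, "ok" if ok else "failed"))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def cox_combination(bundle: AnalysisBundle, scores: pd.DataFrame,
                    genes: list[str],
                    design: CovariateDesign | None = None) -> pd.DataFrame:
    """Sequential gene-combination curve.

    Genes are ordered by ascending single-gene p-value (most significant
    first, ties broken by gene id); prefix k is scored on the aggregated
    per-patient mutation count summed over its k genes.
    """
    if not genes:
        raise ValueError("empty gene list")
    missing = sorted(set(genes) - set(bundle.mutations.gene_ids))
    if missing:
        raise ValueError(f"genes absent from mutation matrix: {missing}")
    if design is None:
        design = build_design(bundle)
    sc = scores.set_index("gene").loc[list(genes)]
    # most significant first; unscored genes (NaN p) last; ties by gene id
    order = sorted(genes, key=lambda g: (float(sc.loc[g, "pval"])
                                         if np.isfinite(sc.loc[g, "pval"]) else np.inf, g))
    counts = bundle.mutations.counts
    agg = np.zeros(bundle.n_patients)
    rows = []
    for k, gene in enumerate(order, start=1):
        agg = agg + counts[gene].to_numpy(float)
        if np.ptp(agg) == 0:
            rows.append((k, gene, np.nan, np.nan, np.nan, "skipped"))
            continue
        hr, pval, lrt, ok = _lrt_one(design, agg)
        rows.append((k, gene, hr, pval, lrt, "ok" if ok else "failed"))
    return pd.DataFrame(rows, columns=["k", "gene_added", "hr", "pval",
                                       "lrt_stat", "status"])


def mutation_frequency(bundle: AnalysisBundle) -> pd.DataFrame:
    """Genes x tumour types matrix of within-type mutation frequency:
    the fraction of that type's patients carrying >= 1 mutation."""
    clin = bundle.clinical.table
    mutated = (bundle.mutations.counts > 0)
    out = {}
    for t in sorted(clin["tumour_type"].cat.categories):
        members = clin["tumour_type"] == t
        out[t] = mutated.loc[members.to_numpy()].mean(axis=0)
    return pd.DataFrame(out)


def mutation_ubiquity(freqs) -> float:
    """Cross-tumour mutation ubiquity of one gene.

    u = (sum(f) / sqrt(sum(f^2)) - 1) / (sqrt(n) - 1) over the n per-type
    mutation frequencies f.  u = 0 when the gene is mutated in a single
    tumour type only; u = 1 when mutated in every type at identical
    frequency.  An all-zero profile returns 0 by convention.
    """
    f = np.asarray(freqs, dtype=float)
    n = f.size
    if n < 2:
        raise ValueError("ubiquity needs >= 2 tumour types")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    fmax = float(f.max())
    if fmax == 0.0:
        return 0.0
    f = f / fmax  # u is scale-invariant; rescaling avoids underflow
    ssq = float(np.sum(f * f))
    return float((f.sum() / np.sqrt(ssq) - 1.0) / (np.sqrt(n) - 1.0))


def ubiquity_table(freqs: pd.DataFrame) -> pd.Series:
    """Per-gene ubiquity over a genes x tumour-types frequency matrix."""
    return freqs.apply(lambda row: mutation_ubiquity(row.to_numpy()), axis=1)
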