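# survnet

Discovery and interpretation of **patient-survival gene networks** from
somatic mutations, clinical survival data and a gene interaction network.

Cancer cohorts spanning several tumour types often carry a common core of
mutated genes whose mutation status correlates with patient survival.
`survnet` finds that core as a *connected* subnetwork — not a flat gene list
— and then asks how trustworthy and how interpretable it is.  It is aimed at
computational biologists working with cohort-level mutation matrices
(patients × genes, integer counts), right-censored survival tables and any
undirected gene interaction network.

## The method

1. **Per-gene scoring.** For each gene *g*, two Cox proportional-hazards
   models are compared: the clinical baseline
   `h(t) = h0(t)·exp(β₁·age + β₂·gender + Σ βₖ·tumour-type)` and the full
   model adding the gene's per-patient mutation-count vector *x_g*.  The
   likelihood-ratio statistic `Λ_g = 2(ℓ_full − ℓ_base)` is referred to
   χ²₁, giving a p-value `p_g`, and `HR_g = exp(β_g)` is the hazard ratio
   per additional mutation.  Ties are handled with the Efron approximation.
2. **Module search.** Given a tolerable threshold τ, node scores are
   `s(v) = log₁₀ τ − log₁₀ p_v` — positive below the threshold, negative
   above.  The maximum-scoring connected subgraph (the node-weighted
   prize-collecting Steiner tree problem) is extracted with a deterministic
   minimum-spanning-tree heuristic: metric closure over positive nodes,
   MST, path expansion, exact subtree pruning and deterministic local
   improvement.  An outer bisection over the observed p-value ladder tunes
   τ to a requested module size.
3. **Interpretation.**
   * *Robustness*: leave-one-tumour-type-out reruns give each edge a
     bootstrap-style confidence.
   * *Significance*: degree-binned label permutations give each edge an
     empirical p-value, combined across edges by Fisher's method
     (`−2Σln p ~ χ²₂ₖ`).
   * *Enrichment*: pre-ranked GSEA against Cox-HR / mutation-frequency /
     ubiquity / per-patient rankings; hypergeometric over-representation of
     GMT gene sets with BH FDR; phylostratum (gene-age) enrichment.
   * *Landscape*: per-edge features `e^k = |f_i^k/d_i − f_j^k/d_j|`
     (mutation frequency penalised by module degree) train a self-organising
     map of tumour types; a bootstrap neighbour-joining tree summarises
     per-type frequency profiles.
   * The cross-tumour **mutation ubiquity** of a gene with per-type
     frequencies `f₁…f_n` is `u = (Σf / √(Σf²) − 1)/(√n − 1)`, 0 when a
     single type is mutated and 1 when all types are mutated at the same
     frequency.

## Worked example

```python
from survnet import SimulationConfig, simulate_cohort, SurvivalNetworkModel

cohort = simulate_cohort(SimulationConfig(
    n_patients=300, n_genes=120, module_size=8, beta=1.0, seed=42))
res = SurvivalNetworkModel(cohort.bundle).fit(size=8)
print(res.summary(top=5))
sig = res.edge_significance(R=50, seed=42)
print(f"aggregated edge p = {sig.aggregated_p:.3g}")
g = res.gsea_hr(R=500, seed=42)
print(f"GSEA vs HR ranking: ES {g.es:.3f}, NES {g.nes:.2f}, p {g.pval:.3g}")
```

prints

```
Survival network results
========================
patients: 300   genes scored: 120 (of 120)
tumour types: BRCA, GBM, KIRC, LUAD
module: 8 genes, 9 edges, total score 16.757 at p-cut 0.000568

gene  score      pval  degree    hr
G010  5.698 1.139e-09       1 2.097
G008  3.335  2.63e-07       1 1.864
G001  2.589 1.464e-06       2 1.758
G073  2.326 2.686e-06       1 1.881
G093  2.214  3.47e-06       2 1.808

aggregated edge p = 0.129
GSEA vs HR ranking: ES 0.929, NES 2.62, p 0.00256
```

The 8-gene module recovered here matches the planted module exactly
(`G001 G003 G004 G008 G009 G010 G073 G093`).  Each listed gene raises the
hazard about 1.8–2.1-fold per mutation after adjusting for age, gender and
tumour type.  The GSEA result says the module sits sharply at the top of
the genome-wide hazard-ratio ranking (ES 0.93, p ≈ 0.003).  The aggregated
edge p-value is modest on this small scale-free toy graph: degree-binned
permutation nulls frequently rebuild modules through the same hubs, which
is exactly the conservatism the null is designed to have.

The same workflow is available from the shell:

```sh
survnet simulate --seed 42 -o cohort/
survnet score --mutations cohort/mutations.tsv --clinical cohort/clinical.tsv \
              --network cohort/network.graphml -o scores.tsv
survnet module --scores scores.tsv --network cohort/network.graphml --size 8 \
               -o module.graphml
survnet run --pipeline-config pipeline.yaml -o out/   # full workflow + manifest
```

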