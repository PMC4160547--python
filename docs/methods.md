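# Methods

This note records the models, algorithmic choices and defaults behind
`survnet`, and what the synthetic-data tests do and do not establish.

## Survival scoring

**Model.** For each gene the full Cox proportional-hazards model
(age + gender + tumour type + gene mutation count) is tested against the
clinical baseline by a likelihood-ratio test on one degree of freedom.
Mutation counts enter untransformed as integers — the per-patient count is
the dose — with a `binarise` option for presence/absence coding.  The
hazard ratio is `exp(beta_gene)`, the multiplicative hazard change per
additional mutation.

**Fitting.** The partial likelihood uses the Efron tie correction (accurate
for the moderate tie counts that day-resolution survival data produce) and
is maximised by damped Newton-Raphson on the analytic gradient and Hessian
(`survnet._coxph`).  The implementation is vectorised over event groups so
that the per-gene scan — thousands of fits inside the robustness and
randomisation loops — runs in milliseconds per gene; it agrees with
lifelines to ~1e-12 in coefficients and log-likelihood on the same data
(asserted in the test suite, which keeps lifelines as an independent
oracle).  The linear predictor is centred before exponentiation; the
partial likelihood is invariant to that shift.

**Covariate encoding.** Age is centred; gender is a single indicator;
tumour type is dummy-coded against the alphabetically first level.
Reference-level choice does not affect the gene term's LRT or HR.
Zero-variance covariates are dropped with a warning (e.g. a single-gender
cohort).

**Edge cases.** Genes mutated in fewer than `min_mutated` patients
(default 2 — one mutated patient cannot support a slope) or with constant
count vectors are flagged `skipped`; non-converged fits (including monotone
likelihood under separation, detected as |beta| > 50) are flagged `failed`.
Flags are never replaced by fabricated numbers.  P-values are floored at
1e-300 so downstream log transforms stay finite.

**Combination curves.** Genes are ranked by ascending single-gene p-value
(ties by gene id) and added one at a time; prefix k is scored by the same
LRT machinery on the aggregated count vector (the element-wise sum over the
k genes).  The k = 1 point reproduces the single-gene fit exactly.

**Mutation ubiquity.** `u = (Σf/√(Σf²) − 1)/(√n − 1)` over the n per-type
mutation frequencies.  The statistic is scale-invariant and
permutation-invariant, 0 for a single-type profile, exactly 1 for a
constant non-zero profile.  All-zero profiles return 0 (with a warning
path) rather than NaN so rankings stay total; n = 1 is rejected because
the normalising denominator degenerates.

## Module search

**Scoring transform.** `s(v) = log10(tau) − log10(p_v)`: zero at the
threshold, +1 one decade below, −1 one decade above.  Its sign semantics
(positive = of interest, negative = tolerable linker penalty) are what
the search consumes.  A beta-uniform-mixture variant is available behind
a flag (`method="bum"`: shape `a` fitted by maximum likelihood,
`s = (a−1)(ln p − ln tau)`, same sign rule on a data-adaptive scale), but
the mixture can fail to fit survival-scan p-value distributions, so the
decade-scaled transform is the default.  Unscored or failed genes sitting on the
graph receive the median score of the scored intolerable nodes — hubs with
no usable fit can still act as linkers.  The search operates on the
largest connected component.

**Heuristic.** The maximum-scoring connected subgraph problem is the
node-weighted prize-collecting Steiner tree problem (NP-hard); the solver
is the classic deterministic MST heuristic with strengthened, equally
deterministic post-processing:

1. edge cost `c(u,v) = max(−s(u),0)/2 + max(−s(v),0)/2 + 1e-9` (the
   epsilon biases ties toward fewer edges);
2. metric closure (all-pairs shortest paths) over the positive nodes;
3. Kruskal MST of the closure with lexicographic tie-breaks;
4. expansion of closure edges into their underlying paths;
5. exact maximum-weight connected subtree of the expanded tree by dynamic
   programming (subsumes iterative pruning of non-positive leaves);
6. deterministic local improvement on the induced subgraph: absorb
   adjacent positive nodes; attach any excluded positive node whose
   cheapest connecting path has positive net score; drop negative nodes
   made redundant by cycles (non-articulation points), most negative
   first;
7. comparison against the best single positive node.

Every step breaks ties lexicographically, so identical inputs give
identical modules.  The returned module is the induced subgraph on the
selected nodes (modules are generally not trees), always connected, with
no non-positive leaf.  On random graphs of ≤ 12 nodes the heuristic stays
within the 0.9 × exhaustive-optimum bound asserted in the acceptance
tests; it is not guaranteed optimal in general.

**Size control.** `search_fixed_size` bisects over candidate thresholds
placed at geometric midpoints of consecutive observed p-values (a gene
exactly at tau scores 0 and is intolerable), plus one candidate just above
the largest p.  Module size is not strictly monotone in tau, so the search
tracks the best size seen and returns within ±`tol` nodes (default ±2,
`max_iter` 30), ties resolved toward the more stringent threshold; an
unreachable target returns the closest module with a warning flag.

## Network statistics

* **Community significance.** Detection is delegated to any
  modularity-based partitioner (default: networkx greedy modularity)
  behind a plain node→label mapping; the bespoke part is the test:
  per community, within-community degrees versus between-community
  degrees, one-sided Wilcoxon rank-sum (within > between), exact
  enumeration for small tie-free samples and the tie-corrected normal
  approximation otherwise.  Fully tied samples carry no evidence and
  return p = 1; communities of one node are flagged untestable.
* **Leave-one-type-out confidence.** Each tumour type is dropped in turn;
  genes are re-scored and a module of the reference size re-identified;
  an edge's confidence is the fraction of runs containing it.  A run that
  fails (no positives, no events) recovers nothing and is logged.
* **Degree-binned permutation.** Gene labels (p-values) shuffle only
  within log2-spaced degree bins (default 10), preserving topology and
  the p-value multiset exactly; "similar degree swaps with similar
  degree" is the operational reading of degree-approximating
  randomisation.  Each of R permutations (default 100) is followed by a
  fixed-size search at the reference size, re-tuned per permutation;
  `p(e) = (1 + hits)/(1 + R)` (pseudo-count, never exactly 0) and the
  per-edge p-values combine by Fisher's method.  Under a global null the
  procedure is conservative — hub edges reappear in null modules often,
  which is the intended guard against hub-driven artefacts.

## Enrichment

* **GSEA.** Pre-ranked, metric-weighted with exponent q = 1 by default
  (q = 0 gives the unweighted Kolmogorov-Smirnov walk).  Hits climb by
  `|metric|^q` normalised over the set; misses fall by `1/(N − m)`; the
  running sum starts and ends at 0 and the enrichment score is its signed
  extremum.  The null resamples same-size gene sets from the ranked list
  (not phenotype permutation); `p = (1 + #same-sign nulls ≥ |ES|)/(1 +
  #same-sign nulls)` and `NES = ES / mean |null ES|` of the same sign.
  Whole-list sets are flagged degenerate.  Ranking builders cover Cox HR,
  ubiquity, per-type frequency and per-patient counts; ties break
  lexicographically and constant metrics are flagged untestable.
* **Over-representation.** Upper-tail hypergeometric per term (identical
  to one-sided Fisher's exact on the 2×2 table), BH FDR across terms.
* **Ontology.** True-path propagation (annotations climb to all
  ancestors; idempotent, monotone, cycles rejected).  Parent-child
  *conditional* enrichment variants are deliberately out of scope.
* **Gene ages.** Per ancestor, over-representation of group genes first
  created there against that ancestor's repertoire as the urn, plus the
  cumulative fraction of group genes created at-or-before each ancestor.

## Landscape

* **Edge features.** `e^k = |f_i^k/d_i − f_j^k/d_j|` per module edge and
  tumour type, with degrees taken from the module subgraph: frequency
  contrasts are discounted on hubs, so the features encode connectivity as
  well as frequency.
* **SOM.** 6 × 6 rectangular grid by default; codebook initialised on the
  first-two-principal-component plane; two online phases (rough: 100
  epochs, radius from half the grid diagonal down to 1, learning rate
  0.5→0.05; fine: 400 epochs, radius 1→0.1, rate 0.05→0.01) with a
  Gaussian neighbourhood.  The schedule is pinned for reproducibility:
  assignments are deterministic given (features, grid, epochs, seed).
  Quantisation error is recorded at each phase end.  Samples are the
  tumour types themselves (sample-training semantics).
* **NJ tree.** Euclidean distances between per-type frequency columns of
  the module genes; Saitou-Nei neighbour joining via scikit-bio; supports
  are bipartition recovery fractions over gene-resampling bootstrap
  (default 100 replicates), stamped on internal nodes in the newick
  output.  Two types yield a single-edge tree; three types have a unique
  unrooted topology and no non-trivial bipartitions.

## Synthetic cohorts

The generator emulates the structure of a pan-cancer mutation/survival
cohort: sparse integer mutation counts (Poisson, background rate 0.05 per
gene per patient, module rate 0.3), a scale-free interaction graph
(Barabasi-Albert, m = 2; Erdos-Renyi available), a connected planted
module grown by seeded BFS (15 genes by default), and exponential survival
with hazard `h0·exp(beta·module burden + covariate effects)` — a correctly
specified proportional-hazards model, so parameter-recovery tests are
meaningful.  Defaults: 600 patients, 500 genes, beta = 1 per mutation,
four tumour types at proportions 0.4/0.3/0.2/0.1 (uneven on purpose, to
exercise leave-one-type-out asymmetry) with baseline log-hazard offsets
(0, 0.4, −0.3, 0.2), age ~ N(60, 10), gender Bernoulli(1/2), independent
exponential censoring calibrated by bisection to a 30% censored fraction.
Identical seeds give byte-identical cohort files.

What this does *not* emulate: mutational signatures, gene length and
copy-number effects, subclonal structure, inter-gene mutation correlation,
or informative censoring.  Passing recovery tests therefore demonstrate
correctness of the machinery under the stated model, not performance on
real cohorts.

Problem sizes used in the heavier checks are deliberate choices: the
null-calibration experiment uses 200 genes × 200 patients; effect recovery
averages 50 single-gene replicates; the power sweep runs 12 paired
replicates (common seeds across beta values, a variance-reduction design)
per beta in {0, 0.5, 1, 2} at the default cohort size; the heuristic
oracle sweep uses 100 random graphs of 6–12 nodes against exhaustive
enumeration.

## Known limitations

* The Cox scan fits genes marginally; correlated genes are scored
  individually, and the combination curve is the only joint view.
* The subgraph heuristic has no approximation guarantee; the 0.9 bound is
  an empirically asserted property at small scale.
* Fisher's aggregation assumes independent edge p-values; shared-null
  dependence between edges of one module makes the aggregate optimistic
  in principle, while the permutation null's hub conservatism pushes the
  other way.
* The SOM landscape is a visual embedding; cell adjacency is not a
  statistical statement.
* GSEA p-values are bounded below by 1/(1 + R); NES comparisons across
  sets with very few same-sign nulls are unstable and surface as NaN.
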