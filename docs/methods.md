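# Methods

`xtalk` implements an integrative network workflow for paired
normal/tumor expression cohorts: state-dependent consensus co-expression
networks, rule-based pathway cross-talk detection with an interface gene
network (PathGeNet), normal-vs-tumor network comparison with
betweenness-ranked key genes, a GRN-based gene dysregulation score, and
Cox risk-score survival stratification. This note records the model, the
defaults and the design choices.

## State-dependent co-expression and the consensus rule

Within each dataset and each state (normal, tumor), every gene pair is
scored by the sample Pearson correlation r; the two-sided p-value comes
from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. A pair is
co-expressed when |r| ≥ 0.7 and p < 0.05 (raw, uncorrected — thresholds
are configurable, and no multiplicity correction is applied because the
downstream cross-talk rule, not the per-pair test, is the inferential
unit). The consensus network for a state keeps the pairs that pass in
*every* dataset with the same sign of r; the stored r is the arithmetic
mean (sign-safe under the consensus filter) and the stored p the worst
per-dataset p. Zero-variance genes are dropped from pairing with a
logged warning.

## Pathway cross-talk criteria

Pathways are gene sets (GMT input), filtered to those with ≥5 genes
measured in the common gene universe, not in an excluded category (e.g.
human-disease collections), and sharing ≥2 genes with at least one other
retained pathway. The overlap rule is applied once over the survivors of
the first two filters, not iterated to a fixpoint: re-applying it could
only cascade deletions through pathways whose partners were removed for
unrelated reasons, which the cross-talk criteria below do not require.

For an unordered pathway pair (A, B), genes are classified as
A-exclusive, B-exclusive or shared. The pair is in cross-talk when the
consensus network satisfies either

* **criterion (i), bridge_pair** — at least two *distinct* co-expressed
  pairs, each joining an A-exclusive to a B-exclusive gene. The two
  pairs may share a gene: the rule exists to prevent a single chance
  pair from creating an edge, and requiring gene-disjoint pairs would
  be a stronger condition than that purpose needs; or
* **criterion (ii), shared_gene** — a shared gene co-expressed with at
  least one A-exclusive and one B-exclusive gene (a path a–s–b through
  the overlap).

When both hold the edge is labelled `bridge_pair` and its evidence is
the union of all supporting pairs from both criteria. The PathGeNet is
the union of evidence pairs over all cross-talk edges, so it is a
subgraph of the consensus network by construction. Pathway node counts
are reported over non-isolated nodes.

## Network comparison and key genes

Normal and tumor networks (pathway- or gene-level) are compared by exact
set algebra on unordered edges: state-specific and conserved edge sets
partition the union. Key genes are the top-k (default 10) nodes of a
connected component ranked by unnormalised Brandes betweenness with unit
edge weights; only ranks are interpreted, which makes the choice of
normalisation constant irrelevant. Ties at the cut are broken
lexicographically and logged. Components are ordered by size, then by
smallest member, for determinism.

## GRN dysregulation score

For a directed edge i→j, the per-sample regulation strength is
r_ij = log₂(E_i/E_j) on linear-scale expression; log2-scale matrices are
exponentiated first (applying the ratio to already-logged values would
be a double log). The edge dysregulation strength is
ds_ij = r̄_ij(tumor) − r̄_ij(normal), with a two-sided Welch t-test on
the per-sample r_ij as the significance rule (the field uses varying
unstated rules; Welch is the weakest-assumption two-sample choice). A
gene's score d_i sums |ds_ij| over all incident significant edges
(upstream and downstream); the absolute value prevents opposite-signed
dysregulation from cancelling, and a signed variant is available.
Z standardises d over all scored genes within a dataset (sample sd).
Z is invariant to the log base, which rescales every ds by one constant.
Edges labelled `predicted` are excluded at GRN ingestion.

A structural caveat: for N scored genes, max |z| ≤ √(N−1), and the
null distribution of the maximum grows heavier-tailed with N because d
is a significance-gated sum (a point mass at 0 plus rare positive
contributions). At the desk-scale default GRN (29 genes) an extreme
|z| ≥ 5 is essentially impossible under the null; at genome scale the
z ≥ 5 cutoff is a ranking device, not a calibrated error rate.

## Survival stratification

Eq.-(4)-style risk scores are the linear predictor Σ Expᵢ·βᵢ with β from
a multivariate Cox proportional-hazards fit (lifelines, ridge penaliser
0.01 for numerical stability). Samples are split at the median score
(ties go to low-risk); Kaplan-Meier curves per group use the native
product-limit estimator and separation is tested with the native
two-group log-rank statistic (hypergeometric variance, χ² on 1 df).

`evaluate_cluster` defaults to **split-sample validation**: β is fitted
on a random half of the cohort and the median split and log-rank test
are computed on the held-out half. Refitting and testing on the same
cohort makes the risk score the direction of maximal association with
the observed survival and the log-rank p-value anti-conservative;
under the split the grouping of the test half is independent of its
survival under the null, so the test is exactly valid.
`validation="resubstitution"` reproduces the classical single-cohort
workflow for comparability, and externally supplied coefficients skip
fitting and evaluate the full cohort.

## Synthetic studies and what they show

The generator emulates a multi-dataset paired-state design with planted,
fully recorded ground truth. Defaults: 3 datasets × 20 samples per
state; 8 pathways of 15 genes chained with 2-gene overlaps (so every
pathway passes the retention rule without creating unplanted evidence);
within-block correlation ρ = 0.9 via a one-factor Gaussian; residual sd
0.5 log2 units. Planted cross-talks cover both criteria, a
negative-sign block, and state rewiring (tumor-only, normal-only and
conserved pairs); blocks recruit only pathway-exclusive genes except the
designated shared gene of a criterion-(ii) plant. The GRN is 3 hubs × 6
targets plus an 8-gene cascade and 3 predicted-labelled edges; hub
targets are shifted ±1 log2 unit in tumor (alternating sign), which also
provides the planted up/down DE signature. The survival cohort has 200
patients, a 5-gene cluster with per-gene log-hazard β = 0.5 on unit-sd
expression, exponential baseline hazard 0.1 and exponential censoring
(rate 0.045, ≈30% censored) — cohort size in the range of typical
validation cohorts for this design. `generate_null_study` keeps every
layout and disables all planting (ρ = 0, no shifts, β = 0).

The generator draws independent Gaussian noise within blocks and states;
it does not emulate microarray heteroscedasticity, batch effects,
probe-level artefacts, or correlated censoring. Passing recovery and
calibration tests therefore demonstrates correctness of the algorithms
under the generating model, not robustness to real-data artefacts.

## Numerical choices and degenerate inputs

* Duplicate gene rows collapse by mean at ingestion (order-independent).
* Degenerate Welch tests (zero variance in both groups) return p = 1
  when means agree and p = 0 otherwise.
* |r| = 1 returns p = 0 exactly; correlations are clipped to [−1, 1]
  before the t-transform.
* All-zero dysregulation score vectors (no significant edge anywhere)
  yield z ≡ 0 with a warning rather than 0/0.
* Log-rank with zero total variance returns χ² = 0, p = 1.
* Gene symbols are upper-cased at every ingestion point.
* Problem sizes in the test suite and acceptance script (50 recovery
  seeds, 200 null survival seeds, 100 null GRN seeds, desk-scale gene
  counts) are chosen so a complete validation run finishes in well under
  a minute while keeping binomial uncertainty on the measured rates
  within the asserted bands.

## Known limitations

* Raw (uncorrected) per-pair and per-edge p-values follow the original
  workflow; both thresholds are parameters.
* The DE stage is a Welch t-test on supplied log2 matrices, a documented
  stand-in for moderated-variance pipelines (limma/DESeq2), which the
  package accepts as precomputed 3-column tables instead.
* The pathway overlap-retention rule is one documented reading of an
  ambiguous selection criterion (pair filter vs node filter).
* Resubstitution survival evaluation is provided for comparability but
  its p-values are optimistic; use the split default for inference.
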