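# Methods

## Overview

`mooscreen` screens the compounds of a multi-herb formula for the minimal
subset likely to carry its therapeutic effect on a disease. The pipeline
runs in the order the method is defined: ADMET rule screen → C-T-P
network construction → per-target multiobjective scoring → network
pruning → baseline comparison → enrichment → coverage-based compound
selection → pathway importance ranking. Everything operates in gene-symbol
space; reconciling identifiers from interaction, disease-gene and
expression sources is the caller's responsibility (symbols are uppercased
on input).

## Compound screen

A compound is certified "potentially active" only when all ten inclusive
upper bounds hold simultaneously: MW ≤ 500 g/mol, nHD ≤ 5, nHA ≤ 10,
logP ≤ 5, nRot ≤ 10, TPSA ≤ 140 Å², and predicted F20, BBB, hERG and HHT
model outputs each ≤ 0.7. The four model outputs are treated as opaque
probabilities and compared to 0.7 as printed — no re-interpretation of
the predictor's semantics. The screen is a strict conjunction; no
"one-violation tolerated" Lipinski variant is offered. A compound missing
a property cannot be certified under the default `missing_policy="fail"`;
`pass` and `ignore-rule` are available for exploratory use.

## Network construction

Targets are whatever appears on the target side of the compound–target
edge list (so a target unreached by any screened compound is not a
network node). A listed pathogenic gene joins the network only with
evidence: at least one retained gene–gene edge, or being a target itself.
This mirrors the observable gap between the number of disease genes a
database search returns and the number that end up in a published
interaction network. Gene–gene edges are undirected, canonicalized
lexicographically, self-loops dropped, multi-edges collapsed.

**Pruning rule.** When the network is reconstructed around the kept
targets, a pruned ECP (a target that is also pathogenic) leaves the
network entirely — its pathogenic identity does not retain it. We chose
this reading because it is the only one under which ECP retention
discriminates between optimizers: if pruned ECPs lingered as pathogenic
nodes via their remaining interactions, every model would trivially
retain nearly all of them and the headline comparison metric would be
vacuous. Non-ECP pathogenic genes persist while they keep ≥ 1 edge;
isolated ones are dropped (this choice is recorded in the run manifest).

## Target scores

* **Expression.** Pathogenic targets score their own `|log2 FC|`; other
  targets average `|log2 FC|` over their interacting pathogenic genes
  (`n_t` in the denominator; a missing fold change contributes 0 to the
  numerator and is logged). No pathogenic interactor → 0.
* **Correlation.** Pathogenic targets score 1; others average `|Pearson r|`
  over interacting pathogenic genes. Undefined pairs (zero variance, gene
  absent) are excluded from numerator *and* denominator — a missing
  correlation is never silently 0.
* **Degree.** Product of the min–max-scaled degree in `N_CT` and in
  `N_TP`, both scaled over the target nodes present in the respective
  view. A target absent from `N_TP` gets second factor 0. A view whose
  member targets all share one degree (span 0) contributes factor 1 for
  every member: a constant component carries no ranking information and
  must not veto the product; the degenerate case is flagged.
* **Pathway.** With `P_T(t)` the (size-≥ 10-filtered) gene sets containing
  `t` and `P_T(T)` their union over all targets, the score is
  `|P_T(t) ∩ P_T(T)| / |P_T(t) ∪ P_T(T)|`. Since `P_T(t) ⊆ P_T(T)` this
  reduces to `|P_T(t)|/|P_T(T)|`; we implement the formula literally
  rather than reinterpreting it as a pairwise Jaccard between targets.

Min–max normalization maps each raw component to [0, 1] (constant
component → all 1, flagged); `Score_t` is the unweighted sum, in [0, 4].
Selection keeps `ceil(0.5·|T|)` targets, ties broken deterministically by
(score, N_CT degree, lexicographic id). The fraction, tie policy and
missing-value rules are exposed in the run config.

## Differential expression and correlation

When no precomputed table is supplied, log-scale expression is compared
between groups with a Welch two-sample t-test and Benjamini–Hochberg
correction (via statsmodels); `logFC = mean(case) − mean(control)` on the
log2 input scale, significance at `|logFC| > 1` and FDR < 0.05. A supplied
DE table always takes precedence — the score only consumes logFC values,
so any upstream moderated fit can be slotted in. Pearson correlations
default to all samples pooled (`sample_policy` configurable to
case-only/control-only); fewer than 3 samples under a policy is an error.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
`P[X ≥ k]` with BH FDR across tested terms, sorted by (p, term id). The
reference universe is an explicit choice recorded in the manifest; the
default is the union of all gene-set members and network genes. Sets with
fewer than 10 members are removed at read time.

## Baselines and comparison metrics

Degree, closeness and betweenness are computed on the full undirected
C-T-P graph (compounds included) — the same substrate the multiobjective
score sees — then restricted to targets and passed through the identical
normalize/select/reconstruct path, so the comparison isolates the scoring
function. Closeness uses the reachable-set (Wasserman–Faust)
normalization, well-defined on disconnected graphs. The centralities are
evaluated with python-igraph for speed; the tests cross-check them against
networkx and a hand BFS. Average regulating intensity defaults to mean
`|r|` over retained gene–gene edges (the "intensity" reading; a signed
mean is available via `signed=True`). Reference KEGG/GO-BP term lists are
enriched from the original network's ECPs; each model's lists from its
optimized network's genes.

## Compound selection

`Score_c` sums the kept targets' scores per compound. For combinations
the default **union** mode sums `Score_t` over the union of member target
sets — a weighted maximum-coverage objective in which shared targets count
once, making the "optimal combination of size k" non-trivial. The
alternative literal reading (**additive**: sum of `Score_c`, shared
targets counted per compound) is retained; in that mode the optimum is
exactly the top-k compounds by score, which the tests assert. The exact
solver enumerates `C(n, k)` combinations behind a guard; the default
greedy solver builds a nested chain by maximal marginal gain
(deterministic tie-break: gain, compound score, id), which for the
monotone submodular union objective is within `1 − 1/e` of the optimum at
every size. Selection returns the smallest prefix whose coverage reaches
the threshold (default 90%) of the all-candidates coverage, plus the full
per-size curve. Exhaustive enumeration at realistic candidate counts
(hundreds of compounds) is infeasible, which is why greedy is the default
and the exact solver is a verification tool for small instances.

## Pathway importance

`Importance_p = (1/m) Σ Score_t` over the `m` scored member targets — the
mean, following the defining formula; a `sum` mode (no `1/m`) is exposed
because the quantity is described both ways in common usage. Pathways
with no scored target are excluded.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, so
every stage runs without any database access:

* **Scale (defaults).** 30 compounds × 120 targets × 160 pathogenic genes
  with ECP fraction 0.25, plus 100 unrelated background genes — a
  deliberately scaled-down cohort that keeps replicate experiments cheap;
  `paper_scale_profile()` reproduces the published network's scale
  (167 / 1,467 / 1,758 with 534 ECPs, compound degrees ~10–160,
  gene–gene density giving ≈ 45k interactions), and `tiny_profile()` is a
  ≤ 10-compound smoke profile.
* **Screen.** Properties are sampled inside the ten thresholds for
  passing compounds and with 1–3 planted violations otherwise
  (`admet_pass_rate` = 0.6 by default so the filter stage is exercised
  while the network stays populated; the paper-scale profile sets 1.0
  because it models the *post-screen* compound set).
* **Wiring.** Compound–target degrees follow a truncated discrete power
  law (exponent 2.0, minimum 3, cap 15% of targets). A few planted "key"
  compounds (default 3) are wired preferentially to ECPs. Gene–gene
  interactions are Erdős–Rényi over targets ∪ pathogenic genes at density
  0.02.
* **Expression.** Log2-scale Gaussian expression (baseline N(7, 1), unit
  within-group noise) with planted group shifts: |log2 FC| ≈ 2.0 for
  ECPs, ≈ 1.0 for other pathogenic genes, N(0, 0.4) background — values
  typical of strongly dysregulated disease genes over microarray-level
  noise. Each target with a pathogenic interactor shares a latent factor
  with one designated partner at Pearson `ecp_cor_strength` (default
  0.6); pairs planted for non-pathogenic targets are recorded as ground
  truth (pathogenic targets' own group shift attenuates their pooled
  correlation, so they are planted but not used for parameter-recovery
  checks). 20 samples per group by default.
* **Gene sets.** Half of each collection is "disease" sets drawing ~50%
  of members from ECPs ∪ pathogenic genes, half uniform background; all
  sizes ≥ 10.

What the generator does **not** emulate: real chemistry (SMILES are
placeholders), count-based expression noise (only logFC and Pearson r are
consumed downstream), scale-free gene–gene topology, annotation bias, or
correlated multi-target pharmacology. Passing tests therefore demonstrate
that the implementation recovers planted structure under the model's own
assumptions — not that the method's biological conclusions transfer to
any particular real dataset.

## Numerical choices and determinism

All randomness flows through one seeded NumPy generator; identical config
and seed give byte-identical output files, and the run manifest records
input checksums, resolved config and seed. Floating-point output is
written at 10 significant digits. Ties are broken lexicographically
everywhere a ranking is emitted. Degenerate inputs (empty views, constant
scores, zero-variance genes, undefined correlations) are flagged rather
than silently coerced. The exact-enumeration guard refuses > 2 × 10⁶
combinations per size.

## Problem sizes used in the checks

The test suite exercises: hand-computable fixtures (≤ 5 targets) asserted
to 1e−12; the hypergeometric tail against exact rational enumeration for
universes ≤ 25; selection against exhaustive enumeration for ≤ 12
compounds; 50 seeded replicates of the default-scale generator for the
baseline comparison; 20 replicates for key-compound recovery; and one
end-to-end run at the published network's scale. These sizes were chosen
so the properties are statistically meaningful while the whole suite
stays interactive.

## Known limitations

* The union-mode combination search is greedy; its `1 − 1/e` guarantee is
  for coverage at each size, not a certificate of the exact minimal set.
* The pathway score collapses to a membership ratio; if the intended
  statistic were a pairwise Jaccard between targets, rankings would
  differ (the literal formula is implemented).
* Correlations pool case and control samples by default; group-specific
  co-expression is only accessible via `sample_policy`.
* The DE fallback is an unmoderated Welch test; small cohorts benefit
  from supplying a moderated DE table instead.
* Symbol-space matching silently misses genes whose sources disagree on
  symbols.
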