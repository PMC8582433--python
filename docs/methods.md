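# Methods

This note documents the models implemented in `netdriver`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that affect reproducibility.

## Network prior and hub reweighting

The driver search operates on a directed graph of gene–gene
interactions whose edge weights are probabilities in (0, 1] that the
interaction is usable by a path. Unweighted priors are initialized at
weight 1 (`default_weight`, configurable; 0.8 is a useful setting for
unweighted priors because weight-1 edges are a fixed point of the
reweighting below and would otherwise make it a no-op). Undirected
priors are expanded to two directed edges because the degree model is
defined on out-degrees.

A discrete power law `P(d) ∝ d^(−α)` is fitted by maximum likelihood to
the positive out-degrees (support starts at `xmin`, by default the
smallest positive out-degree observed; zero-degree nodes are outside
the support). The degenerate case of a single repeated degree value has
a divergent ML exponent and is handled as its limit: a point mass at
`xmin`, so `cdf_90 = xmin`. Otherwise `cdf_90` is the smallest degree
whose fitted CDF reaches 0.90, computed from the fitted distribution
(not the empirical one), with ties broken toward the smaller degree.
Each edge (i, j) is then relaxed toward 1:

    s(i)    = 1 + exp(3 · (out_degree(i)/cdf_90 − 1))
    w'(i,j) = 1 − (1 − 1/s(i)) · (1 − w(i,j))

`w' ≥ w` always, and for fixed `w < 1` the boost shrinks strictly as
the out-degree grows — hubs are downweighted *relative* to the rest of
the network while still able to contribute. The transform is applied
exactly once per pipeline run; reapplying it would compound the boost.

## Cohort processing

Variant records carry VAF, read coverage, an impact score in [0, 1]
(FATHMM-style pathogenicity; CADD-scale scores are first mapped through
the sigmoid `p = 1/(1 + 1.04^(−x+10))` when `score_scale: cadd` is
set), and a consequence class. Filtering keeps records with
`coverage ≥ 5`, `VAF ≥ 0.1` (thresholds are "below", i.e. records
exactly at the threshold survive), a present impact score, and a
consequence outside {silent, intron, intergenic, upstream, downstream,
3'UTR, 5'UTR}. All thresholds are configurable.

Sample QC happens on the mutation *burden* (`tmb`, the pre-filter
per-sample record count — burden is a property of the tumor, not of
the filter settings, and using the pre-filter count also makes outlier
flagging commute with variant filtering). Samples whose log10 burden
falls outside the Tukey whiskers `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
(type-7 linear-interpolation quartiles; the whisker rule is invariant
to the logarithm base) are dropped. Among the survivors, log10
post-filter counts are z-scored; samples with z > 3.5 are flagged
hypermutators and receive a correction factor
`median(count)/count` clamped to (0, 1] — the magnitude is not pinned
down by the published description, and this choice scales a
hypermutator's path contributions inversely with its excess burden.
All other samples have correction 1.

The per-mutation relevance score is the plain product
`impact × VAF × correction`. Each factor is already a probability-like
weight in [0, 1]; no other functional form is implied by the published
description, and the product keeps the "path score is a probability"
semantics intact. Callers can precompute their own relevance maps if a
different combination is wanted.

## Pathfinding

For each mutated gene on the network, the search retains the
`max_paths_per_source = 25` best-scoring *simple* paths of at most
`max_edges = 4` edges with score at least `min_path_prob = 0.2`, ending
at another mutated gene. A path's score is its edge-probability product
times the terminal weight: the maximum of `relevance(m_a) ×
relevance(m_b)` over mutation pairs at the two endpoints lying in
*different* samples (0, and hence no path, if the endpoint genes only
co-occur in the same samples). The threshold applies to this full
relevance-weighted score, not the bare edge product. Because the
optimal pair always uses each gene's best or second-best per-sample
relevance, terminal weights are O(1) after a top-2 precomputation.

The enumeration is best-first branch-and-bound: a priority queue is
ordered by prefix product × an admissible completion bound computed by
reverse dynamic programming over remaining hop counts (the bound
ignores the simple-path constraint, so it never underestimates).
The queue is abandoned once no prefix can reach
`max(min_path_prob, k-th best retained score)`; ties at the retention
cap break lexicographically on the edge sequence, making the output
deterministic. Disabling the bound changes runtime only; the tests
assert equality with exhaustive enumeration.

Paths are simple because revisiting a node can only lower the product
while adding no new terminal; cycles would also make "the path exists"
events degenerate. Mutations are collapsed to genes before pathfinding
(the network has gene resolution; per-variant trees would duplicate
identical path sets).

## Path-existence probabilities and subnetwork selection

Each source gene's retained paths become one disjunctive formula: one
clause per path, the clause being the conjunction of the path's edges
(independent Bernoullis with the edge probabilities, 0 when the edge is
absent from the candidate subnetwork) and one auxiliary independent
Bernoulli carrying the terminal weight. Duplicate edge sets collapse to
the larger terminal weight. This preserves "path score = product of
edge weights × terminal weight" inside the at-least-one-path event.
P(formula fires | S) is computed exactly by weighted model counting:
clauses with absent edges are dropped, weight-1 edges are certain and
leave the counting problem, and the remainder is evaluated by Shannon
expansion on the most-shared edge with connected-component
decomposition and memoization. Formulas here are small (≤ 25 clauses of
≤ 4 edges), so exact counting is cheap; an inclusion–exclusion oracle
verifies it to 1e−12 in the tests. Each formula's relevant edges are
numbered into a bit-vector; probabilities are cached keyed by the
bitmask of relevant edges present in S, so the many subnetworks visited
during optimization (and across the whole penalty scan) reuse results.
Per-formula evaluations are independent and could run concurrently;
results are identical to sequential evaluation, and the cache is
semantically transparent (asserted bitwise in the tests).

The subnetwork score is `Σ_g P(path of g exists | S) − penalty · |S|`,
summed over source *genes*. It is maximized by greedy steepest-ascent
over single-edge removals/re-additions restricted to the union of all
clause edges (no other edge can change the probability term). Per-edge
move gains are maintained incrementally — toggling an edge only
perturbs the formulas containing it. The search runs from three start
points (full candidate union, empty set, one random subset; `restarts`
configurable) with seeded random tie-breaking; the best local optimum
wins, ties going to the earlier start. On instances small enough for
exhaustive 2^12 subset enumeration the search attains the global
optimum in ≥ 29/30 random instances.

The penalty is scanned over a log grid of 10 values from 0.001 to 0.5
(configurable; the published description uses "a range of edge
penalties" without printing one). Per penalty, `runs_per_penalty = 3`
replicate optimizations run with seeds derived from (master seed,
penalty value, replicate index) — hence invariant to the order of the
penalty list. A penalty is accepted iff the best run scores > 0, the
mean pairwise Jaccard index of the replicate *edge sets* is ≥ 0.5
(edge sets, not gene sets: the stability objects are networks), and
the best subnetwork has ≤ 80 edges. The final network is the union of
accepted best subnetworks (the best of equal-scoring runs is the first
in seed order); genes are ranked by the highest accepted penalty at
which they appear, and nodes are labeled mutated or connector according
to presence in the cohort's gene set. Connected components (direction
ignored) are reported ranked by the number of cohort samples with at
least one mutation in the component, ties broken by node count then by
lexicographically smallest node.

## Group-wise mutation-rate comparison

The test compares mutated-sample counts between two groups under
sample-specific null probabilities. With no confounders the null
probability is the pooled frequency `(m₁+m₂)/(n₁+n₂)`; with
confounders it is a logistic regression of the per-sample 0/1
indicator on the confounder vector, fitted on all samples of both
groups pooled. The fit standardizes regressors and applies a small
ridge (λ = 1e−4 on slopes) because rare genes in modest cohorts
routinely separate; constant indicators, all-constant confounders, or
failed fits fall back to the pooled frequency. TMB enters untransformed
by default (log10 switchable).

Group counts are Poisson binomial (exact pmf by iterative convolution);
the joint pmf is the product of the group pmfs. One-sided p-values sum
the joint pmf over outcome pairs at least (right) or at most (left) as
extreme as the observed ratio, compared by cross-multiplication
`v₁·m₂ ≥ v₂·m₁` so zero denominators need no special casing; ties —
including the observed state — count toward both sides, giving
`p_right + p_left − P(ties) = 1`. The full O(n₁·n₂) state sum is exact
and fast into the thousands of samples; no normal approximation is
used. Gene sets combine per-gene fitted probabilities into a
per-sample `1 − Π(1 − pᵢ)` of at least one hit, with observed counts
being samples carrying any member. Benjamini–Hochberg adjustment is
left to the caller (raw p-values are reported, as in the enrichment
analyses this mirrors).

**Calibration.** With the true per-sample probabilities the test is
exactly calibrated (measured rejection 0.050 at α = 0.05 under the
null). The operational test plugs in *estimated* probabilities fitted
on the data under test, which absorbs part of any random group
imbalance and makes it mildly conservative: under a confounded null
(200 samples/group, group-2 TMB doubled, no group effect) the measured
corrected-test rejection at α = 0.05 is ≈ 0.028–0.03, versus ≈ 0.89
for the uncorrected test — the correction removes essentially all of
the confounder-driven false-positive inflation at the cost of slight
conservatism. This plug-in behavior is inherent to the procedure, not
a numerical artifact.

## Driver categorization and benchmarking

Enrichment-signal classes combine four significance flags (raw and
TMB-corrected right-sided tests in two metastatic-vs-primary
comparisons; α = 0.05 by default, strict `<`): *strong* =
corrected-significant in both cohorts; *intermediate* = raw-significant
in both and corrected in exactly one; *weak* = raw-and-corrected
significant in exactly one cohort; *no_sign_with_tmb* = raw in both but
corrected in neither; *no_enrichment* otherwise. The mapping is total
over the 16 flag combinations.

Evolution classes use patients with ≥ 2 metastatic lesions. "Majority"
is strictly > 50% throughout. A gene is *primary_early* when > 50% of
its mutated patients carry it in the matched primary (when available —
patients without a matched primary can qualify through all-lesion
truncality) and in all metastatic lesions; *transitional* when > 50%
of mutated patients lack it in the matched primary but carry it
truncally (> 50% of lesions); *late* otherwise; *not_observed* when no
patient carries it. Truncality is evaluated per variant when variant
ids are provided, else per gene.

The benchmark metric is the true-positive ratio `|top-k ∩ gold|/k`
against a user-supplied gold-standard list; a rank-tie block straddling
the k boundary is included whole (the effective k grows accordingly),
since penalty-ranked lists contain large tied tiers.

## Synthetic data

The generators exist so every component is testable without
access-restricted cohorts; they emulate statistical structure, not
biology. `generate_network` builds a preferential-attachment graph
(heavy-tailed degrees, as assumed by the degree model), directed both
ways, with edge weights uniform on [0.5, 1]. `generate_cohort` plants
one connected module (random BFS from a random node, guaranteeing
connectivity) and, per sample: one planted-gene hit with probability
`hit_rate` (impact ~ Beta(5, 1), i.e. damaging; VAF ~ U(0.2, 0.9);
coverage ≥ 30; missense), plus Poisson(`background_rate`) background
mutations on non-planted genes (impact ~ Beta(1, 3), mostly benign; a
mixture of consequence classes so the variant filters are exercised);
a `hypermut_fraction` of samples gets a 20-fold background rate.
Defaults: 120 samples, module of 6, hit rate 0.7, background 8, 5%
hypermutators, on a 250-gene prior — sized so the full pipeline runs in
seconds while leaving background genes with non-trivial path scores.
`generate_grouped_cohort` draws TMB lognormal (median 300, σ_log 0.6),
multiplies group 2's TMB by `tmb_shift`, and mutates each gene with
probability `logistic(−3 + 0.002·TMB + β_group·[group 2])`; the truth
object records every β. All generators are pure functions of their
parameters and seed.

Not emulated: mutational signatures and trinucleotide context,
copy-number and structural variation, purity/ploidy effects on VAF
(assumed corrected upstream), gene length and regional mutability, and
correlated co-mutation structure. Passing the recovery experiments
therefore shows the pipeline separates a connected recurrent module
from Poisson background on a scale-free prior — not that it handles
every failure mode of real cohorts.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 200 random vectors
(n ≤ 12) against full-outcome enumeration for the Poisson binomial;
1000 random 2×2 configurations against one-sided Fisher; 2000 null
replicates at 200 samples/group for calibration; 500 random formulas
(≤ 15 clauses, ≤ 20 edges) against inclusion–exclusion; 50 random
≤ 30-node graphs against exhaustive path enumeration; 30 instances of
≤ 12 candidate edges against exhaustive subset optimization; and 20
synthetic cohorts at the default generator settings for planted-module
recovery. These sizes keep every oracle exact while the whole suite
remains a desk-scale computation.

Numerical details worth knowing: probability comparisons in the local
search use a 1e−12 improvement threshold; equal-gain moves are broken
by a seeded RNG over the sorted tied edges; p-values are clipped to
[0, 1] against convolution round-off; the search's incremental gains
are recomputed exactly (from the cached per-formula probabilities)
when reporting final scores; empty final networks (no accepted
penalty) are a warning, not an error; and all derived seeds are taken
modulo 2^31.

## Known limitations

The subnetwork optimizer is a local search: on large instances the
replicate-stability criterion (Jaccard ≥ 0.5) is the guard against
reporting unstable local optima, not a global-optimality proof. The
plug-in null makes the corrected group test mildly conservative (see
Calibration). The terminal-weight "max over distinct-sample pairs"
rule and the product relevance form are interpretation choices exposed
for sensitivity analysis. The gene ranking is tier-structured (many
genes share a penalty level), so downstream metrics must handle tied
blocks, as `tp_ratio` does.
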