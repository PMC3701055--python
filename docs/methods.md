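# Methods

This note documents the models implemented in `grninfer`, their
assumptions, the defaults and the numerical conventions, in enough detail
to reproduce or audit any number the toolkit prints.

## Problem setting

The input is a genes × samples matrix of normalized expression values
(unitless; microarray or RNA-seq after the user's own normalization) and an
optional list of transcription factors (TFs). The output of every
inference method is a *ranked edge list*: (regulator, target, score)
triples sorted by descending confidence, ties broken lexicographically on
(regulator, target). The lexicographic tie-break matters: integer ranks
feed the Borda integration, so the order must be reproducible. Undirected
methods store each unordered pair once, smaller identifier first. Gene
identifiers match by exact, case-sensitive string comparison; an optional
two-column alias map (`io.read_alias_map`) supports probeset↔gene-id
translation without any database machinery.

Scores always increase with confidence. Methods whose natural output is a
p-value report 1 − p.

Missing expression values are never imputed: a gene with any missing or
non-numeric cell is either dropped with a logged count (default) or
triggers a parse error naming the offending cell, per the reader's
`drop_missing` flag.

## Inference algorithms

**Relevance network (RN).** Pairwise Pearson correlation; pairs with
r ≥ pos_threshold or r ≤ neg_threshold are kept, scored by |r| with the
sign retained as edge metadata. The defaults (0.9, −1.0) keep only strong
positive co-expression — a negative threshold of exactly −1 excludes every
anti-correlated pair. For rank integration and AUC evaluation an
`emit_all` mode scores every pair by |r| and leaves truncation downstream.
Zero-variance genes receive score 0 against all partners (logged).

**Shrinkage GGM.** The sample correlation matrix R is shrunk toward the
identity, R* = (1 − λ\*)R + λ\*I, with the closed-form intensity
λ\* = Σᵢ≠ⱼ V̂ar(rᵢⱼ) / Σᵢ≠ⱼ rᵢⱼ², clipped to [0, 1] — the analytic
(Ledoit–Wolf-style) choice that guarantees a positive-definite estimate
even when genes outnumber samples. Partial correlations come from the
inverse, pcorᵢⱼ = −Ωᵢⱼ/√(ΩᵢᵢΩⱼⱼ), and edges are ranked by |pcor|. The
empirical-Bayes local-fdr layer sometimes attached to this estimator is
omitted deliberately: under its two-groups model it is monotone in |pcor|
and cannot change a ranking.

**CLR.** Mutual information between all pairs, then background
correction: zᵢ(j) = max(0, (MIᵢⱼ − μᵢ)/σᵢ) with μᵢ, σᵢ over row i
excluding the diagonal (population σ), combined symmetrically as
√(zᵢ(j)² + zⱼ(i)²). Rows are processed independently, making the score
invariant to adding a constant to one gene's MI row; a constant background
(σᵢ = 0) yields zᵢ ≡ 0, logged. The default MI estimator is a B-spline
smoothed histogram (order 3, 10 bins; each min-max-scaled sample spreads
one unit of mass over adjacent bins through the clamped B-spline basis),
which reduces hard-binning sensitivity. A Gaussian closed form
(−½ ln(1 − r²)) is available as a fast alternative. MI is reported in
nats and clipped at 0.

**GENIE3.** One extremely-randomized-trees regression per target gene on
the candidate TFs (excluding the target itself); the TF→target score is
the TF's total variance-reduction importance. Defaults follow the
method's reference description: 1000 trees, √p candidate features per
split. Targets are standardized before fitting and each target's
importances are renormalized to sum 1 before pooling, so every target
contributes equal mass and high-variance targets cannot dominate the
global ranking. The tree ensembles are scikit-learn's
`ExtraTreesRegressor`.

**TIGRESS.** Per target, R half-samples (⌊n/2⌋ without replacement); on
each, every candidate TF column is rescaled by an independent
Uniform[α, 1] weight and least-angle regression runs L steps
(scikit-learn's `lars_path`). The selection frequency of a TF within the
first ℓ steps, averaged over resamples, gives its stability curve; "area"
scoring (default) averages the curve over ℓ = 1..L, "frequency" uses step
L alone — with L = 1 the two coincide. Defaults follow the reference
description: R = 1000, α = 0.2, L = 5. With α = 1 the weight
randomization degenerates to all-ones and only the half-sampling remains.
L is clipped (with a warning) when it exceeds the candidate count.

**PLPC — bounded-order PC-stable.** The causal learner proceeds in three
phases:

1. *Skeleton.* Starting from the complete graph, for each conditioning
   size ℓ = 0..`max_order` every currently adjacent pair (i, j) is tested
   for conditional independence given all subsets S with |S| = ℓ drawn
   from the level-frozen adjacency sets of i and of j (smaller side first,
   subsets in lexicographic order). Edges failing a test are deleted only
   after the level completes — the PC-stable discipline, which makes the
   set of surviving edges independent of gene ordering and of how the pair
   list is partitioned across workers. The CI test is Fisher's z on
   Gaussian partial correlations: z = ½ ln((1+r)/(1−r)),
   √(n−|S|−3)·|z| ~ N(0, 1) under independence, independence declared when
   p > α. When n − |S| − 3 ≤ 0 the test is undecidable and the edge is
   conservatively retained (logged). Partial correlations come from the
   inverse of the correlation submatrix on {i, j} ∪ S, with a
   pseudo-inverse fallback for singular submatrices.
2. *V-structures.* Every unshielded triple i–k–j with k outside the
   recorded separating set of (i, j) is oriented i→k←j. Overlapping
   v-structures that would direct an edge both ways are reverted to
   undirected and logged rather than silently resolved.
3. *Meek rules.* R1–R4 applied to a fixpoint; a rule never overrides an
   existing orientation, so no new v-structure or directed cycle can
   appear. (R4 cannot fire from v-structure initialization alone; it is
   included for completeness.)

Recorded separating sets — unlike the skeleton — would normally depend on
the enumeration order of the genes, so the skeleton phase internally
relabels genes into sorted-identifier order. This pins down the sepsets
and hence the v-structures, making the *entire* PDAG invariant to any
permutation of the input and to the worker count, which is the testable
content of "order-independent and parallel".

Defaults α = 0.01, max_order = 8. Bounding the conditioning order is what
keeps the search tractable for thousands of genes; whenever max_order is
at least the maximum vertex degree the bound is never active and the
result coincides with unrestricted PC-stable (verified in the tests
against a brute-force implementation and an exact d-separation oracle).

Edge confidence for ranking and integration is 1 − pmax, where pmax is
the largest p-value seen among a surviving pair's CI tests: an edge that
never came close to removal scores near 1. Orientations ride along as
edge metadata (serialized as a 4th TSV column in {`--`, `->`, `<-`}), so
downstream consumers that only understand ranked pairs still work.

## Ensemble integration

Borda count: each of the K input lists is truncated to its top_k best
edges; every edge present in at least one list is rescored by its average
rank, with absent edges taking the penalty rank top_k + 1 (the longest
truncated list defines the penalty when top_k is unbounded). "Average
rank" and "sum of ranks" induce the same order for edges present in all
lists; the penalty convention also covers edges missing from some lists.
The integrative score is the negated average rank (monotone, so the usual
larger-is-better convention holds). Directed and undirected inputs mix:
with any undirected input the composite is keyed by unordered pair and an
edge is directed iff at least one method oriented it and none oriented it
oppositely; conflicts are logged per edge.

## Evaluation

The evaluable universe is the set of pairs labeled in the gold standard —
unlabeled pairs are ignored, not counted as negatives (the community
benchmark convention for partially known regulons). The prediction is
truncated to its top_k most confident edges (default 100 000); ROC and
precision–recall curves are swept over pruning thresholds, edges with tied
scores entering together; both areas are trapezoidal. Gold pairs absent
from the truncated list complete the curves under the assumption that the
remainder is randomly ordered: a straight segment to (1, 1) on the ROC
(exactly its expectation) and the closed-form expected precision profile
on the PR curve. The recall-0 endpoint of the PR curve is anchored at the
first achieved precision. When a directed gold standard is evaluated
against an undirected prediction, a pair matches either orientation, the
better-ranked one winning.

Directionality bookkeeping mirrors the edges(directed) / TP(correct)
table layout: skeleton true positives ignore direction;
`directed_precision` is correctly-directed TPs over all directed
predictions (reported as 0 with a degeneracy flag when nothing was
oriented); `orientation accuracy` — the headline causal claim — is
correctly-directed TPs over *directed* TPs.

## Cross-species comparison

Reciprocal best hits: hits with E > 1e-6 are discarded; per query, hits
sort by descending bit score, then ascending E-value, then subject id (the
tertiary tie-break is needed because only exact ties are specified by the
RBH rule); the top `max_hits` subjects are kept, extended by exact
(bit score, E-value) ties, which are treated as co-orthologs. A
duplicated genome (soybean-style paleopolyploid) may keep its best two
hits. A pair is an ortholog iff each member is among the other's best
hits. Metagenes are the connected components of the union ortholog graph
spanning ≥ 2 species, with deterministic ids from sorted member lists;
components exceeding a species' member allowance are kept but flagged —
anomalies are surfaced, never silently merged or split. Network
comparison translates each species' nodes to metagene ids (untranslatable
edges dropped and counted) and overlays edge sets with per-source scores.

## Annotation enrichment

Per term, a 2×2 table (in subnetwork vs not × has term vs not) over the
chosen universe, tested with the 1-df Pearson chi-square, no continuity
correction, upper-tail p. Terms with a zero marginal are skipped and
logged. Benjamini–Hochberg adjusted p-values are added as a convenience
column — the raw p is always reported, and the adjustment is an extension
beyond the plain chi-square test. The universe defaults to the analyzed
gene list and is an explicit argument, since chip-wide vs list-wide
universes answer different questions.

## Synthetic benchmark generator

The generator emulates a community-challenge-style setting: a known
directed network with TF-only regulators, steady-state expression, and a
gold standard over the TF × gene universe. Genes are indexed in
topological order with the TFs first, so acyclicity and the
TF-only-out-edges rule hold by construction (the weight matrix of a DAG
is nilpotent — spectral radius 0). Topologies: Erdős–Rényi over the
admissible pairs, or a heavy-tailed (Zipf) per-TF out-degree draw at the
same expected edge count for hub-dominated networks. Expression is drawn
by ancestral sampling of the linear-Gaussian structural equation model
x_g = Σ_p w_pg x_p + ε_g with roots N(0, 1) and ε_g ~ N(0, σ²); samples
are i.i.d. Negatives in the gold standard are restricted to TF→gene
pairs, matching the universe the methods search.

Default condition (used by the benchmark and the acceptance script):
50 genes, 20 TFs, 200 samples, mean out-degree 2, |w| ∈ [0.5, 1] with
random sign, σ = 0.5 — a small but non-trivial network where an informative
method should clearly beat chance and a label-shuffle control should not.

What this deliberately does not emulate: kinetic/ODE dynamics, saturation
and mRNA decay, perturbation (knockout/knockdown) experiments,
heteroscedastic or non-Gaussian noise, feedback loops, batch structure.
Passing the benchmark therefore shows that an algorithm recovers linear
steady-state dependency structure at realistic sparsity and noise — not
that it handles the full complexity of real transcriptomes.

## Benchmark and acceptance-script settings

The 10-seed benchmark runs GENIE3 with 100 trees, TIGRESS with 100
resamples and PLPC at conditioning order 3 — sizes chosen so a full run
completes in about two minutes on one CPU while leaving each method's
reference defaults untouched for real analyses; the tests that depend on
ensemble size assert stability (doubling trees moves AUROC by little), so
the reduced sizes do not change any conclusion. The composite integrates
the three methods with the best mean AUROC. The shuffle control permutes
gene labels, breaking every gene-to-gold association while preserving the
data distribution.

## Numerical conventions and degenerate inputs

* Writers print scores with 10 significant digits; writer/reader pairs are
  inverses to better than 1e-9.
* Correlations are clipped to [−1, 1]; Fisher's z clips |r| at 1 − 1e-15.
* Zero-variance genes: correlation 0 (logged), GENIE3 importance 0,
  TIGRESS score 0.
* Empty results (all pairs filtered, empty seed intersection) are valid
  empty outputs with warnings, not errors; contradictory inputs
  (conflicting gold labels, labels outside {0, 1}, duplicate gene ids,
  swapped RN thresholds) are errors.
* All parallelism derives per-task seeds from (base seed, task id) via
  SHA-256, so results are bit-identical for any worker count or
  scheduling order.

## Known limitations

* Linear-Gaussian assumptions throughout the CI machinery; heavy-tailed
  or strongly nonlinear regulation degrades PLPC and GGM first.
* PLPC's 1 − pmax confidences are heavily tied near 1 for clearly
  dependent pairs; within-method resolution is coarser than the
  regression methods' importance scores.
* The bounded conditioning order trades completeness for speed: true
  edges shielded only by conditioning sets larger than `max_order` cannot
  be removed, inflating the skeleton on dense graphs.
* RBH orthology is a heuristic; paralog-rich families beyond the
  two-best-hit allowance are flagged rather than resolved.
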