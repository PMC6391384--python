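# Methods

This note documents the models, numerical choices and known limitations of
`netsynergy`. It describes what the code computes; every empirical figure
mentioned here is recomputed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Co-mutation root selection

For driver gene *D* and candidate gene *g*, samples are cross-classified as
(D-mutant vs wild-type) × (g-mutant vs not) and tested with a two-sided
Fisher's exact test. A gene is retained when its odds ratio exceeds 1 and
p ≤ α (default 0.05). Whether the original analysis used a one- or
two-sided test is not determinable; two-sided is the default and the
`alternative` argument exposes the choice. When a table cell is zero the
odds-ratio sign is decided on the Haldane–Anscombe-corrected table
(+0.5 per cell); the p-value is always from the uncorrected table.

Loss-of-function handling: a retained gene whose mutation records are
majority (> 50%) truncating/LOF is flagged `lof_excluded` — reported, but
never passed to the optimizer. The 50% cutoff realizes a qualitative rule
(truncated proteins cannot relay interaction flow) that has no published
numeric threshold; it is exposed as `lof_majority`.

Calibration: Fisher's exact test is conservative on discrete tables, and
the one-directional OR filter removes about half of the two-sided
rejections, so under label permutation the per-gene retention rate is well
*below* α. The calibration tests therefore assert the honest one-sided
bound (empirical rate ≤ α, and > 0 at cohort scale), not approximate
equality to α.

## Differential expression signature

Log2-scale tumor/normal matrices; per shared gene the signature is the
mean difference (log₂ fold change) and a Welch two-sample t-test with
Benjamini–Hochberg adjustment across genes. This deliberately replaces a
moderated-t pipeline: downstream stages consume only the (log2fc, padj)
contract, and the optimizer uses fold changes, not test statistics. Genes
constant in both groups with zero difference get p = 1 by convention
(zero variance, zero effect: no evidence either way); constant but
different, p = 0. Under a global null the BH step-up rarely rejects, so
the null-scenario discovery count is far below fdr·m; the calibration test
asserts the upper bound.

## Subnetwork objective and solvers

Objective: `Σ_{e∈E′} c_e − λ Σ_{i∈V′} b_i` over root-connected subgraphs,
with `c_e = 1 − evidence` (evidence clamped to [0, 1]; files with scores
above 1 are rescaled by their maximum) and prizes
`b_i = max(log2fc, 0) · 1[padj < fdr]` — down-regulated or non-significant
genes can appear in `V′` only as zero-prize connectors. λ defaults to
0.025; the per-node gain λ·b must out-pay edge costs, so λ sets the
network size.

For a *fixed* node set the optimal edge set is a minimum spanning forest
anchored at the roots (all costs ≥ 0, so cycles never pay; a zero-cost
virtual super-root joined to every root turns root-connectivity into plain
spanning connectivity). Both solvers exploit this reduction.

**Exact solver** (`exact_subnetwork`, ≤ 16 nodes): enumerate node subsets
containing the roots, Kruskal each, keep the minimum. Ties break toward
fewer edges, then the lexicographically smallest node set. In the test
suite it is itself validated against a structurally independent oracle
that enumerates raw *edge subsets*.

**Heuristic** (`build_subnetwork`): deterministic grow-and-prune.

1. *Growth*: every positive-prize gene is attached to the root set along
   shortest paths (Prim-style growth over the implicit metric closure), so
   several prized genes can share — and jointly pay for — one expensive
   bridge edge. Growth runs under two metrics: raw edge cost, and a
   prize-discounted surrogate `max(c_e − λ·b_v, 0)` that prefers
   prize-dense corridors; both results are carried forward and the better
   final objective wins. A simple marginal-gain greedy was tried first and
   rejected: adding only the single most profitable node or path can never
   amortize a bridge whose cost exceeds any one increment.
2. *Strong pruning*: on the grown forest, a bottom-up pass computes each
   subtree's net value λ·Σb − Σc and drops every subtree that fails to pay
   for its connecting edge (subtrees containing roots are kept
   unconditionally). This is optimal for the tree it is given.
3. *MST re-wiring* of the kept node set, alternated with pruning until
   stable (cheaper connections can expose further prunes).
4. *Local search*, first-improvement, lexicographic scan order: single-node
   removals and additions (each candidate re-wired by MST before
   evaluation, so mid-path connectors can be dropped), bounded-length
   (≤ 3 new nodes) path additions for prize pockets behind cost barriers,
   and — when the instance has at most 20 non-root genes — a
   variable-neighborhood step that toggles up to three nodes at once.

Everything is deterministic; no randomness is used anywhere in the solver,
so "same seed, same output" holds trivially. On random small instances the
heuristic matches the enumerated optimum (the acceptance script reports
the worst relative gap over 100 fresh instances); no optimality guarantee
is claimed for large instances.

`knockout` rebuilds the network with one gene deleted and reports the node
Jaccard overlap with the original — the single-gene stability statistic.
`rewire` is the degree-preserving double-edge-swap null model; evidence
values travel with the surviving edge slot so the cost distribution is
preserved along with the degree sequence.

## Connectivity scoring

Profiles are ranked by descending Z (ties broken by gene symbol). With the
t query genes at positions V(1) < … < V(t) among n profile genes,

```
a = max_j [ j/t − (V(j)−1)/n ]       b = max_j [ V(j)/n − (j−1)/t ]
score = a  if a > b  else  −b
```

This form is symmetric under profile reversal and attains ±(1 − (t−1)/n)
when the query is packed at the top/bottom. When the two deviations tie
exactly the negative branch is taken. Query genes absent from the profile
universe are dropped (logged); an empty intersection drops the drug. A
signed two-sample KS variant (`variant="ks2samp"`) is provided for
sensitivity analysis only.

Normalization is per sign — positives divided by the maximum positive, 
negatives by |most negative| — preserving rank order within each sign;
whether the original normalization was per-sign or global is unstated, so
per-sign (the connectivity-map convention) is the default. Selection keeps
normalized scores ≤ −0.50. Weights `w_i = 1 + (1 − r_i/n_d)` are assigned
at selection time and **frozen**: the later in-network target filter
deselects drugs but never recomputes ranks, n_d or weights (the
alternative — recomputation — changes weights; a regression test pins the
frozen behavior).

## Centralities and pair synergy

Betweenness (unnormalized path counting) and closeness (BFS, with the
reachable-fraction correction on disconnected graphs) are computed on the
unweighted subnetwork; PageRank uses damping 0.85, tolerance 1e-9, and
uniform teleportation over all of `V′`, so it sums to 1 even when the
subnetwork is disconnected. Each metric is min–max scaled to [0, 1] across
`V′` (a constant metric scales to all-zero) and `cs` is their
equal-weight mean; the weight vector is configurable because only "a
weighted sum" is specified. Singleton networks get betweenness 0,
closeness 0, pagerank 1, cs 0 by convention.

`s_ij = w_i·w_j·Σ_{t∈T_ij} cs_t` with `T_ij` the *union* of the two
drugs' in-network targets — a shared target counts once (summing per drug
would double-count it; the union reading was chosen and is flagged as an
interpretation). Zero-score pairs are suppressed from the output by
default (`keep_zero` restores them).

Drug communities: Pearson correlation of Z-score columns; affinity
propagation (damping 0.9, preference = median similarity, fixed
random_state) is the default, with PAM (hand-written k-medoids:
deterministic BUILD + best-improvement SWAP), average-linkage
hierarchical, and DBSCAN on correlation distance as alternatives.
Zero-variance profiles have undefined correlation and become singleton
communities. Predicted pairs must span two communities.

## Screen validation

TP: predicted pair in the screen with Bliss > 0. FP: Bliss < 0. Bliss = 0
is excluded from both and counted separately so the books balance. FN:
screen pairs with Bliss > 0, both drugs in the method's single-drug pool,
pair not predicted. An empty evaluable set yields NaN metrics with an
explicit flag; a non-empty evaluable set with a zero denominator yields
0. Both F1 variants are reported: `f1` is the harmonic mean, `f1_geom`
the geometric mean of precision and recall (geometric ≥ harmonic always).
In the synthetic benchmark the screen covers all pool pairs, which makes
the FN universe large and recall structurally small (~0.02); precision is
the meaningful comparison metric across pipeline variants.

Baselines (`baseline_run`): `roots_only` uses the root-induced subgraph
with no optimizer; `deg_only` the PPI induced on the top up-regulated
genes, count-matched to the full subnetwork; `rewired` shuffles the PPI
(1000 double-edge swaps) before inference; `random_pairs` samples
size-matched pairs uniformly from the pool. For median-precision
comparisons a variant that predicts nothing evaluable counts as precision
0 (it made no correct prediction).

## Synthetic benchmark: what it emulates, and what it does not

Defaults (the reference conditions): 1000 genes, preferential-attachment
PPI (m = 2), 40-gene disease module, 40-gene decoy cluster, 200 scattered
up-regulated bystanders, log₂ effect 3.0 with noise σ = 0.5 at n = 10
samples per expression arm, 60-sample mutation cohort (driver frequency
0.5; planted roots mutated at 0.7 given the driver vs 0.05 otherwise;
5% background mutation rate, 20% of it truncating), 50 drugs with 5
planted reversers in two mechanism groups, 3 false reversers, reverser
Z-shift −3, and a Bliss screen whose cross-group reverser pairs are
positive with probability 0.9 against a 0.25 background rate (so measured
precision has a ceiling below 1 and the FP/FN bookkeeping is exercised).

Scale reasoning, fixed once: with λ = 0.025 and planted log2FC ≈ 3 a
prized gene is worth λ·b ≈ 0.075. Module-internal edge evidence is drawn
Beta(40, 2) (cost ≈ 0.05 — worth paying) and background evidence
Beta(4, 2) (cost ≈ 0.33 — not worth paying), placing the published λ in
its informative regime rather than re-tuning λ to the generator.

Design features that make each pipeline stage *necessary*:

* the decoy cluster is up-regulated and internally connected but not
  root-connected, and the false reversers suppress it — only the
  root-anchored optimizer rejects them, which is what degrades the
  DEG-only ablation;
* the scattered bystanders mean that most up-regulated genes are not in
  the disease network, so destroying the network (rewiring) dilutes the
  query signature and degrades predictions even though prizes survive;
* the two reverser mechanism groups (each suppressing one module half)
  give the cross-community constraint planted structure to find, and
  their profiles decorrelate into separate communities;
* one planted co-mutated gene is 100% truncating: it passes the Fisher
  screen and must be caught by the LOF exclusion;
* reverser targets sit on high-degree module genes *excluding* the roots
  (drugs hit downstream hubs, not the mutated drivers), which is why the
  roots-only ablation loses the targets and collapses.

Not emulated: real melanoma biology, batch effects, moderated-Z profile
estimation, dose dependence, correlated mutation processes, or any
literature signal. Passing the planted-recovery experiments shows the
machinery is wired correctly and that network integration helps under the
stated generative assumptions — not that the method's precision on real
cohorts matches any particular value.

## Problem sizes and determinism

The reference experiments use the default scenario (seed 7) for recovery
checks, 20 simulated cohorts for the baseline medians, 200 permutations /
replicates for the calibration and enrichment tests, 100 random ≤ 8-node
instances for solver-oracle comparison, and 1000 random draws for the KS
oracle — sizes chosen so the whole suite runs in about a minute on one
CPU while keeping Monte-Carlo error far from the decision boundaries.
Every stochastic step takes an explicit seed; generation is byte-stable
under a fixed seed, and the solver and ranking stages are seed-free
deterministic (ties broken lexicographically everywhere).

## Known limitations

* The heuristic solver has no approximation guarantee; its quality is
  certified only against enumeration on small instances.
* Fisher + BH screening is conservative; power claims hold only at the
  generator's planted odds.
* The frozen-rank weighting means w_i depends on the pre-filter selection
  pool, so adding irrelevant drugs to the compendium can shift weights.
* Affinity propagation can fail to converge on adversarial similarity
  matrices; unconverged drugs are isolated into singleton communities
  rather than guessed.
* The CLI stage files for networks do not persist edge evidence; the
  standalone `predict` subcommand therefore computes centralities on the
  (unweighted) stored topology, which matches the in-pipeline behavior
  because all three centralities are unweighted.
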