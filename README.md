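# netsynergy

Genotype-specific protein subnetwork inference and network-based ranking of
synergistic drug combinations.

`netsynergy` is for computational biologists who want to go from a tumor
cohort (mutations + expression) and a drug perturbation compendium to a
ranked list of candidate drug *pairs*, with every stage inspectable and
testable. It models the setting where a cancer subtype is defined by a
driver mutation (e.g. a BRAF-, NRAS- or NF1-mutant melanoma cohort): the
subtype's co-mutated genes seed a disease protein subnetwork, drugs are
scored for how strongly they reverse that subnetwork's expression
signature, and pairs of reversers are ranked by the network importance of
their combined targets.

## The method

**1. Root genes.** For a chosen driver gene, every other mutated gene is
tested for co-occurrence in a 2×2 Fisher's exact test; genes with
log OR > 0 and p ≤ 0.05 are roots. Genes whose mutations are majority
loss-of-function are excluded as roots — an undirected interaction network
presumes a functional protein product.

**2. Disease subnetwork.** Given the background PPI `G = (V, E)` with edge
costs `c_e = 1 − evidence` and node prizes `b_i` (the log₂ fold change of
significantly up-regulated genes, 0 otherwise), the subnetwork
`G′ = (V′, E′)` is the root-connected subgraph minimizing

```
min_{E′⊆E, V′⊆V}  Σ_{e∈E′} c_e  −  λ · Σ_{i∈V′} b_i        (λ = 0.025)
```

solved by a deterministic grow-and-prune heuristic, with an exhaustive
exact solver as a small-instance oracle.

**3. Connectivity.** Each drug's genome-wide Z-score profile is ranked by
descending Z and scored against the subnetwork's up-regulated genes with a
connectivity-map KS enrichment statistic (negative = the drug reverses the
disease signature). Scores are normalized per sign to [−1, 1]; drugs at
≤ −0.50 are selected and rank-weighted `w_i = 1 + (1 − r_i/n_d) ∈ [1, 2)`.

**4. Pair synergy.** For selected drugs with targets inside `V′`, a pair
scores

```
s_ij = w_i · w_j · Σ_{t ∈ T_ij} cs_t
```

where `T_ij` is the union of the pair's in-network targets and `cs_t` the
mean of min–max-scaled betweenness, closeness and PageRank of target `t`
in `G′`. Pairs must span two different drug communities (affinity
propagation on the Pearson correlation of drug profiles); the final list
is sorted by `s_ij` descending.

**5. Validation.** Against a Bliss-independence synergy screen: predicted
pairs with positive Bliss are true positives, negative are false
positives; positive-Bliss screen pairs missed despite both drugs being in
the pool are false negatives. Precision, recall and both harmonic and
geometric F1 are reported.

A synthetic generator (`netsynergy.synthetic`) produces all inputs with
planted ground truth — scale-free PPI, co-mutated roots, an up-regulated
disease module, decoy and bystander up-genes, planted reverser drugs and a
matching Bliss screen — so the whole pipeline runs and is benchmarked with
no external data.

## Worked example

```bash
netsynergy run-all --simulate --seed 7 --out demo/
```

generates the default planted dataset (1000 genes, 40-gene disease module,
50 drugs of which 5 are planted signature reversers in two mechanism
groups) and runs every stage. It prints

```
network 43 genes; 10 reversers; 6 pair(s)
```

— the inferred subnetwork holds 43 genes (33 of the 40 planted module
genes plus the roots and a few chance attachments), 10 drugs pass the
−0.50 connectivity cutoff, and 6 cross-community pairs survive the target
filter. `demo/pairs.tsv` begins

```
rank  drugA   drugB   synergy      communityA  communityB  n_targets_in_net
1     DRUG02  DRUG05  2.574716422  0           1           4
2     DRUG02  DRUG04  2.267062303  0           1           3
3     DRUG01  DRUG05  2.05330593   0           1           4
```

These are exactly the planted cross-group reverser pairs (DRUG01–03
suppress one half of the module, DRUG04–05 the other), ranked by the
centrality mass of their combined targets times their reversal weights.
`demo/report.json` adjudicates them against the simulated screen:

```
"tp": 6, "fp": 0, "precision": 1.0, "recall": 0.0196
```

All six predictions are synergistic in the screen (precision 1.0); recall
is small by construction because the synthetic screen scores all 1225
drug pairs while the method deliberately predicts only a handful.

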