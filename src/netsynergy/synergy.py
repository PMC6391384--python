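"""Pair synergy scoring: drug targets × subnetwork centrality × communities.

A drug pair is scored

    s_ij = w_i · w_j · Σ_{t ∈ T_ij} cs_t

where w are the connectivity rank weights, T_ij the union of the two drugs'
targets that map into the subnetwork (shared targets counted once), and
cs_t a combined centrality: the equal-weight mean of betweenness, closeness
and PageRank, each min–max scaled to [0, 1] across the subnetwork. Final
candidates are restricted to pairs whose drugs fall in different
expression-profile communities, then ranked by s_ij descending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN, AffinityPropagation

from .connectivity import DrugRanking
from .io import DrugProfileSet, normalize_symbol
from .subnetwork import Subnetwork

logger = logging.getLogger("netsynergy")

__all__ = [
    "CentralityTable",
    "PairPrediction",
    "centrality_table",
    "filter_targeted_drugs",
    "synergy_score",
    "drug_communities",
    "rank_combinations",
    "predict_combinations",
]


@dataclass
class CentralityTable:
    """Per-gene betweenness/closeness/PageRank and their combined score cs."""

    table: pd.DataFrame  # index: gene; columns betweenness, closeness, pagerank, cs

    def cs(self, gene: str) -> float:
        return float(self.table.at[normalize_symbol(gene), "cs"])

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = col.min(), col.max()
    if hi - lo < 1e-15:
        return pd.Series(0.0, index=col.index)
    return (col - lo) / (hi - lo)


def centrality_table(
    net: Subnetwork | nx.Graph,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    damping: float = 0.85,
    tol: float = 1e-9,
) -> CentralityTable:
    """Unweighted shortest-path betweenness and closeness plus PageRank.

    PageRank uses uniform teleportation over the whole node set, so it sums
    to 1 even on a disconnected subnetwork. A singleton network gets
    betweenness 0, closeness 0, pagerank 1 and cs 0 by convention.
    """
    g = net.as_graph() if isinstance(net, Subnetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network has no centralities")
    bet = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g)
    if g.number_of_edges() == 0:
        pr = {n: 1.0 / g.number_of_nodes() for n in g}
    else:
        pr = nx.pagerank(g, alpha=damping, tol=tol, max_iter=500)
    table = pd.DataFrame(
        {"betweenness": bet, "closeness": clo, "pagerank": pr}
    ).sort_index()
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    scaled = table.apply(_minmax)
    table["cs"] = scaled.to_numpy() @ w
    return CentralityTable(table)


def filter_targeted_drugs(
    ranking: DrugRanking,
    targets: dict[str, set[str]],
    net: Subnetwork,
) -> tuple[DrugRanking, dict[str, frozenset[str]]]:
    """Restrict selected drugs to those with ≥1 target inside the subnetwork.

    Ranks, weights and n_d stay frozen at selection time; only the selected
    flag changes. Returns the restricted ranking and each surviving drug's
    effective (in-network) target set.
    """
    in_net: dict[str, frozenset[str]] = {}
    for drug in ranking.selected:
        hits = frozenset(normalize_symbol(g) for g in targets.get(drug, ())) & net.nodes
        if hits:
            in_net[drug] = frozenset(hits)
    return ranking.restrict(in_net), in_net


def synergy_score(
    drug_i: str,
    drug_j: str,
    ranking: DrugRanking,
    ct: CentralityTable,
    targets: dict[str, frozenset[str]],
) -> float:
    """s_ij = w_i · w_j · Σ cs over the union of the pair's in-network targets."""
    if drug_i == drug_j:
        raise ValueError("a drug cannot be paired with itself")
    combined = set(targets.get(drug_i, ())) | set(targets.get(drug_j, ()))
    combined &= ct.genes
    total_cs = sum(ct.cs(t) for t in combined)
    return ranking.weight(drug_i) * ranking.weight(drug_j) * total_cs


def _pam(dist: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic: greedy BUILD initialization followed by best-improvement
    SWAP until convergence.
    """
    n = dist.shape[0]
    k = min(k, n)
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(cur - dist[:, c], 0).sum() if c not in medoids else -1.0
                for c in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        best_delta, best_swap = 0.0, None
        base = dist[:, medoids].min(axis=1).sum()
        for mi, m in enumerate(medoids):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids[:mi] + [c] + medoids[mi + 1 :]
                delta = dist[:, trial].min(axis=1).sum() - base
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, c)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = sorted(medoids)
    return np.argmin(dist[:, medoids], axis=1)


def drug_communities(
    profiles: DrugProfileSet,
    method: str = "affinity",
    seed: int = 0,
    k: int = 10,
    damping: float = 0.9,
    eps: float = 3.0,
    min_samples: int = 5,
) -> dict[str, int]:
    """Cluster drugs by the Pearson correlation of their expression profiles.

    Default is affinity propagation on the similarity matrix (damping 0.9,
    preference = median similarity, seeded); alternatives: ``pam`` (k
    medoids), ``hierarchical`` (average linkage, k clusters) and ``dbscan``
    on correlation distance. Constant-profile drugs have undefined
    correlation and are assigned singleton communities.
    """
    drugs = profiles.drugs
    if len(drugs) < 2:
        raise ValueError("need at least two drugs to cluster")
    z = profiles.z.to_numpy(dtype=float)
    sd = z.std(axis=0)
    usable = [d for d, s in zip(drugs, sd) if s > 1e-12]
    degenerate = [d for d in drugs if d not in set(usable)]
    for d in degenerate:
        logger.warning("drug %s has a constant profile; assigned its own community", d)

    labels: dict[str, int] = {}
    if len(usable) >= 2:
        zu = profiles.z[usable].to_numpy(dtype=float)
        sim = np.corrcoef(zu, rowvar=False)
        sim = np.clip(sim, -1.0, 1.0)
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        if method == "affinity":
            ap = AffinityPropagation(
                damping=damping,
                affinity="precomputed",
                preference=float(np.median(sim)),
                random_state=seed,
                max_iter=500,
            ).fit(sim)
            lab = ap.labels_
            if np.any(lab < 0):  # non-convergence: isolate the unassigned
                nxt = lab.max() + 1
                for i in np.flatnonzero(lab < 0):
                    lab[i] = nxt
                    nxt += 1
        elif method == "pam":
            lab = _pam(dist, k)
        elif method == "hierarchical":
            cond = squareform(dist, checks=False)
            lab = fcluster(linkage(cond, method="average"), t=min(k, len(usable)), criterion="maxclust")
        elif method == "dbscan":
            lab = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(dist).labels_
            nxt = lab.max() + 1
            for i in np.flatnonzero(lab < 0):  # noise points become singletons
                lab[i] = nxt
                nxt += 1
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        labels.update({d: int(l) for d, l in zip(usable, lab)})
    elif len(usable) == 1:
        labels[usable[0]] = 0
    nxt = max(labels.values(), default=-1) + 1
    for d in degenerate:
        labels[d] = nxt
        nxt += 1
    return labels


@dataclass(frozen=True)
class PairPrediction:
    drug_a: str
    drug_b: str
    score: float
    targets: frozenset[str]
    community_a: int
    community_b: int
    rank: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


def rank_combinations(
    scores: dict[tuple[str, str], float],
    communities: dict[str, int],
    pair_targets: dict[tuple[str, str], frozenset[str]] | None = None,
    keep_zero: bool = False,
) -> list[PairPrediction]:
    """Cross-community pairs ranked by synergy score descending.

    Pairs whose drugs share a community are dropped (mechanistic-redundancy
    filter), as are zero-score pairs unless ``keep_zero``. Ties break on the
    canonical pair name, so the output is a strict total order.
    """
    rows = []
    for (a, b), s in scores.items():
        a, b = (a, b) if a <= b else (b, a)
        if a == b:
            raise ValueError("self-pair in synergy scores")
        if communities[a] == communities[b]:
            continue
        if s <= 0 and not keep_zero:
            continue
        rows.append((a, b, float(s)))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    out = []
    for rank, (a, b, s) in enumerate(rows, start=1):
        tset = pair_targets.get((a, b), frozenset()) if pair_targets else frozenset()
        out.append(
            PairPrediction(a, b, s, tset, communities[a], communities[b], rank)
        )
    return out


def predict_combinations(
    net: Subnetwork,
    ranking: DrugRanking,
    profiles: DrugProfileSet,
    cluster_method: str = "affinity",
    seed: int = 0,
    centrality_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    keep_zero: bool = False,
) -> tuple[list[PairPrediction], CentralityTable, dict[str, int]]:
    """Full prediction stage: target filter → centralities → pair scores →
    community-constrained ranking."""
    filtered, in_net = filter_targeted_drugs(ranking, profiles.targets, net)
    ct = centrality_table(net, weights=centrality_weights)
    communities = drug_communities(profiles, method=cluster_method, seed=seed)
    eligible = filtered.selected
    scores: dict[tuple[str, str], float] = {}
    pair_targets: dict[tuple[str, str], frozenset[str]] = {}
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            key = (a, b) if a <= b else (b, a)
            scores[key] = synergy_score(a, b, filtered, ct, in_net)
            pair_targets[key] = frozenset((in_net[a] | in_net[b]) & ct.genes)
    preds = rank_combinations(scores, communities, pair_targets, keep_zero=keep_zero)
    return preds, ct, communities
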