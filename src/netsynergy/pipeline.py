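"""End-to-end orchestration: roots → signature → subnetwork → connectivity →
pair prediction → screen validation, plus the ablation variants used in the
robustness experiments."""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import pandas as pd

from . import connectivity as conn
from . import synergy as syn
from .genomics import RootGeneSet, comutation_roots, differential_signature
from .io import (
    BlissMatrix,
    DrugProfileSet,
    ExpressionSignature,
    MutationTable,
    PPINetwork,
    canonical_pair,
)
from .subnetwork import Subnetwork, build_subnetwork, rewire
from .validation import ValidationReport, evaluate

logger = logging.getLogger("netsynergy")

__all__ = ["PipelineConfig", "PipelineInputs", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    lam: float = 0.025
    cutoff: float = -0.50
    alpha: float = 0.05
    fdr: float = 0.05
    ks_variant: str = "cmap"
    cluster_method: str = "affinity"
    centrality_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    rewire_swaps: int = 1000
    keep_zero: bool = False

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "cutoff": self.cutoff,
            "alpha": self.alpha,
            "fdr": self.fdr,
            "ks_variant": self.ks_variant,
            "cluster_method": self.cluster_method,
            "centrality_weights": list(self.centrality_weights),
            "rewire_swaps": self.rewire_swaps,
            "keep_zero": self.keep_zero,
        }


@dataclass
class PipelineInputs:
    ppi: PPINetwork
    mutations: MutationTable
    tumor: pd.DataFrame
    normal: pd.DataFrame
    profiles: DrugProfileSet
    driver: str
    bliss: BlissMatrix | None = None


@dataclass
class PipelineResult:
    mode: str
    roots: RootGeneSet
    signature: ExpressionSignature
    network: Subnetwork
    up_set: set[str]
    ranking: conn.DrugRanking
    communities: dict[str, int]
    predictions: list[syn.PairPrediction]
    report: ValidationReport | None = None
    centralities: syn.CentralityTable | None = None


def _induced_subnetwork(ppi: PPINetwork, genes, roots, lam, prizes) -> Subnetwork:
    """A 'subnetwork' that is just the PPI induced on a fixed gene set (the
    no-optimizer baselines); root-connectivity is not enforced here."""
    nodes = frozenset(g for g in genes if g in ppi.graph)
    edges = frozenset(
        canonical_pair(u, v) for u, v in ppi.graph.subgraph(nodes).edges
    )
    cost = sum(ppi.graph[u][v]["cost"] for u, v in edges)
    prize = sum(prizes.get(n, 0.0) for n in nodes)
    return Subnetwork(
        parent=ppi,
        nodes=nodes,
        edges=edges,
        roots=tuple(sorted(set(roots) & nodes)),
        lam=lam,
        prizes=dict(prizes),
        objective=cost - lam * prize,
    )


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    mode: str = "full",
    seed: int = 0,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    roots = comutation_roots(inputs.mutations, inputs.driver, alpha=cfg.alpha)
    signature = differential_signature(inputs.tumor, inputs.normal, fdr=cfg.fdr)
    prizes = signature.prizes(fdr=cfg.fdr)

    ppi = inputs.ppi
    if mode == "rewired":
        ppi = rewire(ppi, cfg.rewire_swaps, seed=seed)

    if mode == "roots_only":
        active = [r for r in roots.active if r in ppi.graph]
        network = _induced_subnetwork(ppi, active, active, cfg.lam, prizes)
    elif mode == "deg_only":
        full = build_subnetwork(
            inputs.ppi, signature, roots, lam=cfg.lam, fdr=cfg.fdr
        )
        k = len(full.nodes)
        t = signature.table
        up = t[(t["padj"] < cfg.fdr) & (t["log2fc"] > 0)]
        top = list(up.sort_values(["log2fc"], ascending=False).index[:k])
        network = _induced_subnetwork(ppi, top, [], cfg.lam, prizes)
    elif mode in ("full", "rewired", "random_pairs"):
        network = build_subnetwork(
            ppi, signature, roots, lam=cfg.lam, fdr=cfg.fdr
        )
    else:
        raise ValueError(f"unknown pipeline mode {mode!r}")

    up_set = signature.up_genes(fdr=cfg.fdr) & set(network.nodes)
    if up_set:
        raw = conn.score_drugs(inputs.profiles, up_set, variant=cfg.ks_variant)
        normalized = conn.normalize_scores(raw)
        ranking = conn.select_and_weight(normalized, cutoff=cfg.cutoff, raw=raw)
    else:
        logger.warning("no significant up-regulated genes in the network; empty ranking")
        empty = pd.Series(dtype=float)
        ranking = conn.select_and_weight(empty, cutoff=cfg.cutoff)

    if network.nodes and ranking.n_selected:
        predictions, ct, communities = syn.predict_combinations(
            network,
            ranking,
            inputs.profiles,
            cluster_method=cfg.cluster_method,
            seed=seed,
            centrality_weights=cfg.centrality_weights,
            keep_zero=cfg.keep_zero,
        )
    else:
        predictions, ct, communities = [], None, {}

    if mode == "random_pairs":
        rng = random.Random(seed)
        pool = sorted(inputs.profiles.drugs)
        all_pairs = [(a, b) for i, a in enumerate(pool) for b in pool[i + 1 :]]
        m = min(len(predictions), len(all_pairs))
        sampled = rng.sample(all_pairs, m) if m else []
        predictions = [
            syn.PairPrediction(a, b, 0.0, frozenset(), -1, -2, r + 1)
            for r, (a, b) in enumerate(sampled)
        ]

    report = None
    if inputs.bliss is not None:
        report = evaluate(predictions, inputs.bliss, pool=inputs.profiles.drugs)
    return PipelineResult(
        mode=mode,
        roots=roots,
        signature=signature,
        network=network,
        up_set=up_set,
        ranking=ranking,
        communities=communities,
        predictions=predictions,
        report=report,
        centralities=ct,
    )
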