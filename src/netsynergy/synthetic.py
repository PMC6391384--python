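"""Synthetic benchmark generator with planted ground truth.

Emulates the statistical structure of the pipeline's real-world inputs so
every stage — and the end-to-end planted-recovery experiment — runs without
external data:

* a scale-free (preferential-attachment) background PPI with Beta-distributed
  evidence scores; edges inside the planted disease module draw from a
  high-evidence Beta, reflecting well-replicated interactions, which places
  the default objective tradeoff λ = 0.025 in its informative regime
  (a module gene's prize λ·b ≈ 0.075 exceeds a module edge cost ≈ 0.05 but
  not a background edge cost ≈ 0.33);
* a tumor cohort in which planted root genes are strongly co-mutated with
  the driver against a sparse mutation background, plus one co-mutated but
  loss-of-function (truncating) gene that must be excluded from the roots;
* tumor/normal expression with the disease module up-shifted, together with
  an equally up-shifted but root-disconnected "decoy" cluster of bystander
  genes that only the network-integrated analysis can reject;
* drug Z-score profiles containing two mechanism groups of planted
  signature reversers (each suppressing one half of the module, so their
  pairs span distinct profile communities) and "false reversers" that
  suppress the decoy cluster instead; reverser targets sit on high-degree
  module genes;
* a Bliss screen over all drug pairs in which cross-group reverser pairs
  are synergistic with high probability and background pairs at a base
  rate, so precision has a well-defined ceiling below 1.

Identical seeds reproduce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    BlissMatrix,
    DrugProfileSet,
    MutationTable,
    PPINetwork,
    write_bliss,
    write_drug_profiles,
    write_mutations,
    write_ppi,
)

__all__ = ["SyntheticScenario", "GroundTruth", "SyntheticData", "generate", "write_dataset"]


@dataclass
class SyntheticScenario:
    """Parameters of the planted benchmark. Defaults are the reference
    conditions used throughout the test-suite experiments."""

    seed: int = 7
    # background network
    n_genes: int = 1000
    ppi_attachment: int = 2  # preferential-attachment edges per new node
    evidence_beta: tuple[float, float] = (4.0, 2.0)  # background edges
    module_evidence_beta: tuple[float, float] = (40.0, 2.0)  # disease-module edges
    # planted disease module and bystander decoy cluster
    module_size: int = 40
    decoy_size: int = 40
    n_scattered_up: int = 200  # up-regulated bystander genes outside any cluster
    effect: float = 3.0  # log2 fold up-shift of module, decoy and scattered genes
    sigma: float = 0.5  # per-gene expression noise (log2 scale)
    n_expr: int = 10  # samples per expression arm
    # mutation cohort
    n_mut_samples: int = 60
    driver_freq: float = 0.5
    comut_prob_driver: float = 0.7  # planted-root mutation rate in driver-mutant samples
    comut_prob_wt: float = 0.05
    background_mut_rate: float = 0.05
    lof_fraction: float = 0.2  # truncating fraction among background mutations
    n_mut_genes: int = 100
    n_comut_roots: int = 4
    # drugs
    n_drugs: int = 50
    n_reversers_a: int = 3  # suppress module half 1
    n_reversers_b: int = 2  # suppress module half 2
    n_false_reversers: int = 3  # suppress the decoy cluster
    reverser_strength: float = 3.0
    targets_per_drug: int = 2
    # screen
    bliss_positive_planted: float = 0.9
    bliss_positive_background: float = 0.25
    bliss_scale: tuple[float, float] = (5.0, 30.0)

    def validate(self) -> None:
        if self.module_size + self.decoy_size + self.n_scattered_up > self.n_genes:
            raise ValueError("planted module + decoys larger than the gene universe")
        n_planted_drugs = self.n_reversers_a + self.n_reversers_b + self.n_false_reversers
        if n_planted_drugs > self.n_drugs:
            raise ValueError("more planted drugs than drugs")
        for rate in (
            self.driver_freq,
            self.comut_prob_driver,
            self.comut_prob_wt,
            self.background_mut_rate,
            self.lof_fraction,
            self.bliss_positive_planted,
            self.bliss_positive_background,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("all rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    driver: str
    planted_roots: list[str]
    lof_comut_gene: str
    module: list[str]
    module_half1: list[str]
    module_half2: list[str]
    decoys: list[str]
    scattered_up: list[str]
    reversers_a: list[str]
    reversers_b: list[str]
    false_reversers: list[str]
    planted_pairs: list[tuple[str, str]]

    @property
    def reversers(self) -> list[str]:
        return self.reversers_a + self.reversers_b


@dataclass
class SyntheticData:
    scenario: SyntheticScenario
    ppi: PPINetwork
    mutations: MutationTable
    tumor: pd.DataFrame
    normal: pd.DataFrame
    profiles: DrugProfileSet
    bliss: BlissMatrix
    truth: GroundTruth


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _bfs_ball(graph: nx.Graph, seed_node: str, size: int, forbidden: set[str]) -> list[str]:
    """Deterministic BFS ball of ``size`` nodes avoiding ``forbidden``."""
    ball: list[str] = [seed_node]
    inball = {seed_node}
    frontier = [seed_node]
    while frontier and len(ball) < size:
        nxt = []
        for node in frontier:
            for nbr in sorted(graph[node]):
                if nbr in inball or nbr in forbidden:
                    continue
                inball.add(nbr)
                ball.append(nbr)
                nxt.append(nbr)
                if len(ball) >= size:
                    return ball
        frontier = nxt
    return ball


def generate(scenario: SyntheticScenario | None = None) -> SyntheticData:
    sc = scenario or SyntheticScenario()
    sc.validate()
    rng = np.random.default_rng(sc.seed)

    # --- background PPI -----------------------------------------------------
    g0 = nx.barabasi_albert_graph(
        sc.n_genes, sc.ppi_attachment, seed=int(rng.integers(2**31))
    )
    graph = nx.relabel_nodes(g0, {i: _gene_name(i) for i in g0.nodes})

    # planted module: BFS ball around a moderately connected node (hubs make
    # the ball too star-like; leaves make it too stringy)
    by_degree = sorted(graph.nodes, key=lambda n: (-graph.degree[n], n))
    module_seed = by_degree[len(by_degree) // 4]
    module = _bfs_ball(graph, module_seed, sc.module_size, forbidden=set())
    if len(module) < sc.module_size:
        raise ValueError("could not grow the planted module to the requested size")
    module_set = set(module)
    half1 = module[: sc.module_size // 2]  # BFS core
    half2 = module[sc.module_size // 2 :]  # BFS shell

    # decoy cluster: a second connected ball, disjoint from the module
    decoys: list[str] = []
    for cand in by_degree:
        if cand in module_set or any(n in module_set for n in graph[cand]):
            continue
        decoys = _bfs_ball(graph, cand, sc.decoy_size, forbidden=module_set)
        if len(decoys) >= sc.decoy_size:
            break
    if len(decoys) < sc.decoy_size:
        raise ValueError("could not place a decoy cluster disjoint from the module")
    decoy_set = set(decoys)

    # up-regulated bystanders scattered outside both clusters: genes the
    # disease changes without their being part of the root-connected module
    scatter_pool = sorted(set(graph.nodes) - module_set - decoy_set)
    scattered = sorted(
        rng.choice(scatter_pool, size=sc.n_scattered_up, replace=False)
    )
    scattered_set = set(scattered)

    # evidence scores: module-internal edges from the high-confidence Beta
    a0, b0 = sc.evidence_beta
    a1, b1 = sc.module_evidence_beta
    records = []
    for u, v in sorted(map(lambda e: tuple(sorted(e)), graph.edges)):
        if u in module_set and v in module_set:
            ev = rng.beta(a1, b1)
        else:
            ev = rng.beta(a0, b0)
        records.append((u, v, float(ev)))
    ppi = PPINetwork.from_edges(records)

    # --- roots and mutation cohort -----------------------------------------
    def top_degree(genes, exclude=frozenset()):
        return [g for g in sorted(genes, key=lambda n: (-graph.degree[n], n)) if g not in exclude]

    driver = top_degree(half1)[0]
    n_h1 = sc.n_comut_roots // 2
    roots_h1 = top_degree(half1, exclude={driver})[:n_h1]
    roots_h2 = top_degree(half2)[: sc.n_comut_roots - n_h1]
    planted_roots = roots_h1 + roots_h2
    # one co-mutated gene whose mutations are all truncating: passes the
    # co-mutation test but must be excluded as a loss-of-function root
    lof_comut = top_degree(half2, exclude=set(planted_roots))[0]

    samples = [f"M{i:03d}" for i in range(1, sc.n_mut_samples + 1)]
    driver_status = rng.random(sc.n_mut_samples) < sc.driver_freq
    background_pool = sorted(set(graph.nodes) - module_set - decoy_set - scattered_set)
    n_background = sc.n_mut_genes - len(planted_roots) - 2  # driver + lof gene
    bg_mut_genes = list(
        rng.choice(background_pool, size=max(n_background, 0), replace=False)
    )
    mut_rows = []
    for s, has_driver in zip(samples, driver_status):
        if has_driver:
            mut_rows.append((s, driver, "missense", False))
        p_comut = sc.comut_prob_driver if has_driver else sc.comut_prob_wt
        for gene in planted_roots:
            if rng.random() < p_comut:
                mut_rows.append((s, gene, "missense", False))
        if rng.random() < p_comut:
            mut_rows.append((s, lof_comut, "truncating", True))
        for gene in bg_mut_genes:
            if rng.random() < sc.background_mut_rate:
                truncating = rng.random() < sc.lof_fraction
                mut_rows.append(
                    (s, gene, "truncating" if truncating else "missense", truncating)
                )
    mutations = MutationTable(
        pd.DataFrame(mut_rows, columns=["sample", "gene", "mclass", "lof"])
    )

    # --- expression ---------------------------------------------------------
    genes = sorted(graph.nodes)
    baseline = rng.uniform(6.0, 10.0, size=len(genes))
    up_shifted = module_set | decoy_set | scattered_set
    shift = np.array([sc.effect if g in up_shifted else 0.0 for g in genes])
    normal = baseline[:, None] + rng.normal(0.0, sc.sigma, size=(len(genes), sc.n_expr))
    tumor = (baseline + shift)[:, None] + rng.normal(
        0.0, sc.sigma, size=(len(genes), sc.n_expr)
    )
    tumor_df = pd.DataFrame(
        tumor, index=genes, columns=[f"T{i:02d}" for i in range(1, sc.n_expr + 1)]
    )
    normal_df = pd.DataFrame(
        normal, index=genes, columns=[f"N{i:02d}" for i in range(1, sc.n_expr + 1)]
    )

    # --- drugs --------------------------------------------------------------
    drugs = [f"DRUG{i:02d}" for i in range(1, sc.n_drugs + 1)]
    na, nb, nf = sc.n_reversers_a, sc.n_reversers_b, sc.n_false_reversers
    reversers_a = drugs[:na]
    reversers_b = drugs[na : na + nb]
    false_rev = drugs[na + nb : na + nb + nf]
    decoy_h1 = decoys[: sc.decoy_size // 2]
    decoy_h2 = decoys[sc.decoy_size // 2 :]

    z = rng.normal(0.0, 1.0, size=(len(genes), sc.n_drugs))
    zdf = pd.DataFrame(z, index=genes, columns=drugs)
    suppressed = {d: half1 for d in reversers_a}
    suppressed.update({d: half2 for d in reversers_b})
    for i, d in enumerate(false_rev):
        suppressed[d] = decoy_h1 if i % 2 == 0 else decoy_h2
    for d, gene_set in suppressed.items():
        zdf.loc[gene_set, d] = -sc.reverser_strength + rng.normal(
            0.0, 0.5, size=len(gene_set)
        )

    # reverser targets: high-degree genes of the suppressed half, excluding
    # root genes (drugs hit downstream hubs, not the mutated drivers)
    exclude = set(planted_roots) | {driver, lof_comut}
    targets: dict[str, set[str]] = {}
    for group, region in (
        (reversers_a, half1),
        (reversers_b, half2),
        (false_rev[0::2], decoy_h1),
        (false_rev[1::2], decoy_h2),
    ):
        hubs = top_degree(region, exclude=exclude)
        for i, d in enumerate(group):
            k = sc.targets_per_drug
            targets[d] = {hubs[(i * k + j) % len(hubs)] for j in range(k)}
    for d in drugs:
        if d not in targets:
            targets[d] = set(
                rng.choice(genes, size=sc.targets_per_drug, replace=False)
            )
    profiles = DrugProfileSet(zdf, targets)

    # --- Bliss screen -------------------------------------------------------
    planted_pairs = sorted(
        tuple(sorted((a, b))) for a in reversers_a for b in reversers_b
    )
    planted_set = set(planted_pairs)
    lo, hi = sc.bliss_scale
    bliss_scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(drugs):
        for b in drugs[i + 1 :]:
            key = tuple(sorted((a, b)))
            p_pos = (
                sc.bliss_positive_planted
                if key in planted_set
                else sc.bliss_positive_background
            )
            sign = 1.0 if rng.random() < p_pos else -1.0
            bliss_scores[key] = float(sign * rng.uniform(lo, hi))
    bliss = BlissMatrix(bliss_scores)

    truth = GroundTruth(
        driver=driver,
        planted_roots=planted_roots,
        lof_comut_gene=lof_comut,
        module=sorted(module),
        module_half1=sorted(half1),
        module_half2=sorted(half2),
        decoys=sorted(decoys),
        scattered_up=scattered,
        reversers_a=reversers_a,
        reversers_b=reversers_b,
        false_reversers=false_rev,
        planted_pairs=[tuple(p) for p in planted_pairs],
    )
    return SyntheticData(sc, ppi, mutations, tumor_df, normal_df, profiles, bliss, truth)


def write_dataset(data: SyntheticData, outdir) -> Path:
    """Write all pipeline input files plus the ground-truth manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_ppi(data.ppi, out / "ppi.tsv")
    write_mutations(data.mutations, out / "mutations.tsv")
    for name, df in (("tumor", data.tumor), ("normal", data.normal)):
        d = df.copy()
        d.index.name = "gene"
        d.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.6g")
    write_drug_profiles(data.profiles, out / "zscores.tsv", out / "targets.tsv")
    write_bliss(data.bliss, out / "bliss.tsv")
    manifest = {
        "scenario": asdict(data.scenario),
        "truth": {
            **{k: v for k, v in asdict(data.truth).items()},
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
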