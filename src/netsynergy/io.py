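"""Readers, writers and shared identifier conventions.

All on-disk formats are tab-separated text with a header row. Gene symbols
are normalized to uppercase, whitespace-stripped strings everywhere, and
protein-interaction edges are stored canonically (lexicographically ordered
endpoint pair) so the same undirected edge can never appear twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netsynergy")

__all__ = [
    "FormatError",
    "PPINetwork",
    "ExpressionSignature",
    "MutationTable",
    "DrugProfileSet",
    "BlissMatrix",
    "canonical_pair",
    "normalize_symbol",
    "read_ppi",
    "write_ppi",
    "read_signature",
    "write_signature",
    "read_mutations",
    "write_mutations",
    "read_drug_profiles",
    "write_drug_profiles",
    "read_bliss",
    "write_bliss",
]


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


def normalize_symbol(symbol: object) -> str:
    return str(symbol).strip().upper()


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) ordering for an unordered identifier pair."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Protein–protein interaction network
# ---------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """Undirected weighted PPI graph.

    Each edge carries an experimental-evidence score in [0, 1] and the
    derived cost ``c_e = 1 − evidence`` consumed by the subnetwork
    objective: well-supported interactions are cheap to include, poorly
    supported ones expensive.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        return sorted(canonical_pair(u, v) for u, v in self.graph.edges)

    def evidence(self, u: str, v: str) -> float:
        return float(self.graph[u][v]["evidence"])

    def cost(self, u: str, v: str) -> float:
        return float(self.graph[u][v]["cost"])

    @classmethod
    def from_edges(cls, records: Iterable[tuple[str, str, float]]) -> "PPINetwork":
        """Build a canonical network from (symbolA, symbolB, evidence) triples.

        Self-loops are dropped (logged), duplicate edges collapsed keeping the
        maximum evidence, and evidence rescaled to [0, 1] by the file's maximum
        when scores exceed 1 (e.g. BioGRID/STITCH-style integer confidences).
        """
        best: dict[tuple[str, str], float] = {}
        n_self = 0
        for a, b, ev in records:
            ev = float(ev)
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in best or ev > best[key]:
                best[key] = ev
        if n_self:
            logger.warning("dropped %d self-loop edge(s)", n_self)
        if best:
            top = max(best.values())
            if top > 1.0:
                best = {k: v / top for k, v in best.items()}
        g = nx.Graph()
        for (a, b), ev in best.items():
            ev = min(max(ev, 0.0), 1.0)
            g.add_edge(a, b, evidence=ev, cost=1.0 - ev)
        return cls(g)


def read_ppi(path, evidence_column: str | None = None) -> PPINetwork:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: PPI file needs two symbol columns and one evidence column")
    cols = list(df.columns)
    if evidence_column is None:
        evidence_column = cols[2]
    elif evidence_column not in cols:
        raise FormatError(f"{path}: missing evidence column {evidence_column!r}")
    ev = pd.to_numeric(df[evidence_column], errors="coerce")
    if ev.isna().any():
        raise FormatError(f"{path}: non-numeric evidence values in column {evidence_column!r}")
    return PPINetwork.from_edges(zip(df[cols[0]], df[cols[1]], ev))


def write_ppi(net: PPINetwork, path) -> None:
    rows = [(u, v, net.evidence(u, v)) for u, v in net.edges()]
    pd.DataFrame(rows, columns=["symbolA", "symbolB", "evidence"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# Expression signature
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSignature:
    """Per-gene log2 fold change and BH-adjusted p-value.

    Supplies node prizes for the subnetwork objective: a significant
    up-regulated gene is worth its fold change, everything else zero, so
    down-regulated genes can only enter a subnetwork as free connectors.
    """

    table: pd.DataFrame  # index: gene; columns: log2fc, padj

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["log2fc", "padj"]:
            t = t.rename(columns=dict(zip(t.columns[:2], ["log2fc", "padj"])))
        t = t.copy()
        t.index = [normalize_symbol(g) for g in t.index]
        if t.index.has_duplicates:
            raise FormatError("duplicate gene symbols in expression signature")
        bad = (t["padj"] < 0) | (t["padj"] > 1)
        if bool(bad.any()):
            raise FormatError("adjusted p-values outside [0, 1]")
        self.table = t[["log2fc", "padj"]]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def up_genes(self, fdr: float = 0.05) -> set[str]:
        t = self.table
        return set(t.index[(t["padj"] < fdr) & (t["log2fc"] > 0)])

    def prizes(self, fdr: float = 0.05) -> dict[str, float]:
        """Node prizes b_i = max(log2fc, 0) for significant genes, else 0."""
        t = self.table
        sig = (t["padj"] < fdr) & (t["log2fc"] > 0)
        return {g: float(fc) for g, fc in t.loc[sig, "log2fc"].items()}


def read_signature(path) -> ExpressionSignature:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: signature file needs gene, log2fc, padj columns")
    df = df.set_index(df.columns[0])
    return ExpressionSignature(df)


def write_signature(sig: ExpressionSignature, path) -> None:
    out = sig.table.sort_index()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Mutation table
# ---------------------------------------------------------------------------

MUTATION_CLASSES = ("missense", "truncating", "other")


@dataclass
class MutationTable:
    """Long-form somatic mutation records: (sample, gene, class, lof)."""

    records: pd.DataFrame  # columns: sample, gene, mclass, lof

    def __post_init__(self) -> None:
        df = self.records.copy()
        df.columns = ["sample", "gene", "mclass", "lof"][: df.shape[1]]
        if "lof" not in df.columns:
            df["lof"] = False
        df["gene"] = df["gene"].map(normalize_symbol)
        df["sample"] = df["sample"].astype(str).str.strip()
        df["mclass"] = df["mclass"].astype(str).str.strip().str.lower()
        bad = ~df["mclass"].isin(MUTATION_CLASSES)
        if bool(bad.any()):
            raise FormatError(f"unknown mutation class(es): {sorted(df.loc[bad, 'mclass'].unique())}")
        df["lof"] = df["lof"].astype(bool)
        # truncating mutations are loss-of-function by definition
        df.loc[df["mclass"] == "truncating", "lof"] = True
        df = df.drop_duplicates(subset=["sample", "gene", "mclass"]).reset_index(drop=True)
        self.records = df

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    def mutated_samples(self, gene: str) -> set[str]:
        df = self.records
        return set(df.loc[df["gene"] == normalize_symbol(gene), "sample"])

    def lof_fraction(self, gene: str) -> float:
        """Fraction of this gene's mutation records flagged loss-of-function."""
        df = self.records
        sub = df[df["gene"] == normalize_symbol(gene)]
        if sub.empty:
            return 0.0
        return float(sub["lof"].mean())


def read_mutations(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: mutation file needs sample, gene, class columns")
    return MutationTable(df)


def write_mutations(mut: MutationTable, path) -> None:
    mut.records.sort_values(["sample", "gene", "mclass"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Drug profiles and targets
# ---------------------------------------------------------------------------


@dataclass
class DrugProfileSet:
    """Drug-induced expression Z-scores (genes × drugs) plus drug→target map."""

    z: pd.DataFrame  # index: gene universe; columns: drugs
    targets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = self.z.copy()
        z.index = [normalize_symbol(g) for g in z.index]
        z.columns = [str(c).strip() for c in z.columns]
        if z.index.has_duplicates:
            raise FormatError("duplicate genes in drug profile universe")
        if len(set(z.columns)) != z.shape[1]:
            raise FormatError("duplicate drug names in profile matrix")
        if bool(z.isna().any().any()):
            raise FormatError("missing Z-score entries in drug profile matrix")
        self.z = z
        self.targets = {
            str(d).strip(): {normalize_symbol(g) for g in gs} for d, gs in self.targets.items()
        }
        for d in self.drugs:
            self.targets.setdefault(d, set())

    @property
    def drugs(self) -> list[str]:
        return list(self.z.columns)

    @property
    def universe(self) -> list[str]:
        return list(self.z.index)

    def profile(self, drug: str) -> pd.Series:
        return self.z[drug]


def read_drug_profiles(
    path,
    targets_path=None,
    keep_unmatched_targets: bool = True,
    min_target_score: float | None = None,
) -> DrugProfileSet:
    """Read a genes×drugs Z-score matrix and an optional drug→target table.

    ``min_target_score`` reproduces STITCH-style confidence filtering (keep
    pairs with score above the threshold) when the targets file carries a
    third numeric column. Targets whose drug is absent from the matrix are
    kept under that drug name only when ``keep_unmatched_targets`` is set.
    """
    z = pd.read_csv(path, sep="\t", index_col=0)
    if z.shape[1] < 1:
        raise FormatError(f"{path}: drug matrix needs a gene column plus one column per drug")
    targets: dict[str, set[str]] = {}
    if targets_path is not None:
        tdf = pd.read_csv(targets_path, sep="\t")
        if tdf.shape[1] < 2:
            raise FormatError(f"{targets_path}: targets file needs drug and gene columns")
        if min_target_score is not None and tdf.shape[1] >= 3:
            score = pd.to_numeric(tdf[tdf.columns[2]], errors="coerce")
            tdf = tdf[score > min_target_score]
        matrix_drugs = {str(c).strip() for c in z.columns}
        for drug, gene in zip(tdf[tdf.columns[0]], tdf[tdf.columns[1]]):
            drug = str(drug).strip()
            if drug not in matrix_drugs:
                if not keep_unmatched_targets:
                    logger.warning("target entry for unknown drug %s dropped", drug)
                    continue
                logger.warning("target entry for drug %s absent from matrix kept", drug)
            targets.setdefault(drug, set()).add(normalize_symbol(gene))
    return DrugProfileSet(z, targets)


def write_drug_profiles(profiles: DrugProfileSet, path, targets_path=None) -> None:
    out = profiles.z.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if targets_path is not None:
        rows = [
            (d, g)
            for d in sorted(profiles.targets)
            for g in sorted(profiles.targets[d])
        ]
        pd.DataFrame(rows, columns=["drug", "gene"]).to_csv(targets_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bliss synergy matrix
# ---------------------------------------------------------------------------


@dataclass
class BlissMatrix:
    """Experimental Bliss-independence excess scores for unordered drug pairs."""

    scores: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for (a, b), s in self.scores.items():
            a, b = str(a).strip(), str(b).strip()
            if a == b:
                raise FormatError(f"self-pair {a!r} in Bliss matrix")
            key = (a, b) if a <= b else (b, a)
            if key in canon and canon[key] != float(s):
                raise FormatError(f"conflicting Bliss scores for pair {key}")
            canon[key] = float(s)
        self.scores = canon

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.scores

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return self.scores[(a, b) if a <= b else (b, a)]

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.scores)

    @property
    def drugs(self) -> set[str]:
        return {d for pair in self.scores for d in pair}


def read_bliss(path) -> BlissMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: Bliss file needs drugA, drugB, bliss columns")
    score = pd.to_numeric(df[df.columns[2]], errors="coerce")
    if bool(score.isna().any()):
        raise FormatError(f"{path}: non-numeric Bliss scores")
    return BlissMatrix(
        {(a, b): s for a, b, s in zip(df[df.columns[0]], df[df.columns[1]], score)}
    )


def write_bliss(bliss: BlissMatrix, path) -> None:
    rows = [(a, b, s) for (a, b), s in sorted(bliss.scores.items())]
    pd.DataFrame(rows, columns=["drugA", "drugB", "bliss"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
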