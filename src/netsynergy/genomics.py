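"""Cohort genomics: co-mutation root genes and differential-expression signatures.

Root genes seed the subnetwork optimization. For a chosen driver gene, every
other mutated gene in the cohort is tested for co-occurrence with the driver
in a 2×2 Fisher's exact test; genes with log odds ratio > 0 and p ≤ alpha are
retained. Genes whose mutations are majority loss-of-function are recorded
but flagged, because an undirected interaction model presumes a functional
protein product — a truncated protein cannot relay network flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionSignature, MutationTable, normalize_symbol

__all__ = ["RootGene", "RootGeneSet", "comutation_roots", "differential_signature"]


@dataclass(frozen=True)
class RootGene:
    gene: str
    log_or: float
    p_value: float
    lof_excluded: bool
    is_driver: bool = False


@dataclass
class RootGeneSet:
    subtype: str
    driver: str
    members: list[RootGene]

    @property
    def genes(self) -> list[str]:
        return [m.gene for m in self.members]

    @property
    def active(self) -> list[str]:
        """Roots passed to the optimizer: LOF-dominated genes excluded."""
        return [m.gene for m in self.members if not m.lof_excluded]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.gene, m.log_or, m.p_value, m.lof_excluded, m.is_driver)
                for m in self.members
            ],
            columns=["gene", "log_or", "p_value", "lof_excluded", "is_driver"],
        )


def _log_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Log odds ratio; Haldane–Anscombe 0.5 correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log((a * d) / (b * c))


def comutation_roots(
    mut: MutationTable,
    driver: str,
    alpha: float = 0.05,
    lof_majority: float = 0.5,
    alternative: str = "two-sided",
    subtype: str = "",
) -> RootGeneSet:
    """Select genes significantly co-mutated with ``driver``.

    For each non-driver gene a 2×2 table (driver-mutant vs wild-type ×
    gene-mutant vs not) is tested with Fisher's exact test; a gene is
    retained iff its log odds ratio is positive and p ≤ alpha. Genes with
    more than ``lof_majority`` of their mutation records flagged
    loss-of-function are retained in the report but marked ``lof_excluded``
    and never used as optimizer seeds.
    """
    driver = normalize_symbol(driver)
    samples = mut.samples
    driver_mut = mut.mutated_samples(driver)
    if not driver_mut:
        raise ValueError(f"driver gene {driver!r} absent from mutation table")
    n_mut, n_wt = len(driver_mut), len(samples) - len(driver_mut)
    if n_mut < 2 or n_wt < 2:
        raise ValueError(
            f"need ≥2 samples in each driver group (got {n_mut} mutant / {n_wt} wild-type)"
        )

    members = [
        RootGene(
            driver,
            math.inf,
            0.0,
            lof_excluded=mut.lof_fraction(driver) > lof_majority,
            is_driver=True,
        )
    ]
    for gene in mut.genes:
        if gene == driver:
            continue
        gene_mut = mut.mutated_samples(gene)
        if not gene_mut or len(gene_mut) == len(samples):
            continue  # degenerate margin: test is uninformative
        a = len(gene_mut & driver_mut)
        b = n_mut - a
        c = len(gene_mut) - a
        d = n_wt - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        log_or = _log_odds_ratio(a, b, c, d)
        if log_or > 0 and p <= alpha:
            members.append(
                RootGene(gene, log_or, float(p), mut.lof_fraction(gene) > lof_majority)
            )
    members = [members[0]] + sorted(members[1:], key=lambda m: (m.p_value, m.gene))
    return RootGeneSet(subtype=subtype, driver=driver, members=members)


def differential_signature(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    fdr: float = 0.05,
) -> ExpressionSignature:
    """Tumor-vs-normal differential expression on log2-scale matrices.

    Per shared gene: log2 fold change = mean(tumor) − mean(normal), and a
    two-sample Welch t-test with Benjamini–Hochberg adjustment across genes.
    Genes with zero variance and zero difference get p = 1 by convention.
    """
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least 2 replicate columns per group")
    t = tumor.copy()
    n = normal.copy()
    t.index = [normalize_symbol(g) for g in t.index]
    n.index = [normalize_symbol(g) for g in n.index]
    shared = t.index.intersection(n.index)
    if shared.empty:
        raise ValueError("tumor and normal matrices share no genes")
    t, n = t.loc[shared], n.loc[shared]

    log2fc = t.mean(axis=1).to_numpy() - n.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(t.to_numpy(), n.to_numpy(), axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # both groups constant: no difference → p = 1; nonzero difference → p = 0
    degenerate = np.isnan(pvals)
    pvals[degenerate & (np.abs(log2fc) < 1e-12)] = 1.0
    pvals[degenerate & (np.abs(log2fc) >= 1e-12)] = 0.0
    _, padj, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    table = pd.DataFrame({"log2fc": log2fc, "padj": padj}, index=shared)
    return ExpressionSignature(table)
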