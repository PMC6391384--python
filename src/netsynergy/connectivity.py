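"""Connectivity-map scoring of drug profiles against a disease up-signature.

Each drug's genome-wide Z-score profile is ranked by descending Z; the
disease subnetwork's up-regulated genes form the query set. A one-sided
Kolmogorov–Smirnov-style enrichment statistic measures whether the query
concentrates at the top (positive: the drug mimics the disease) or the
bottom (negative: the drug reverses it). Scores are normalized per sign to
[−1, 1], drugs at or below a cutoff (default −0.50) are selected as
signature reversers, and selected drugs are rank-weighted

    w_i = 1 + (1 − r_i / n_d)  ∈  [1, 2)

with rank 1 the strongest reverser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DrugProfileSet, normalize_symbol

logger = logging.getLogger("netsynergy")

__all__ = [
    "DrugRanking",
    "ks_connectivity",
    "score_drugs",
    "normalize_scores",
    "select_and_weight",
]


def ks_connectivity(profile: pd.Series, up_set, variant: str = "cmap") -> float:
    """Raw connectivity of one drug profile against an up-regulated gene set.

    ``variant='cmap'`` (default) is the running-maximum enrichment statistic:
    with the t query genes found at positions V(1) < … < V(t) of the n-gene
    profile ranked by descending Z,

        a = max_j [ j/t − (V(j)−1)/n ]      b = max_j [ V(j)/n − (j−1)/t ]

    and the score is a when a > b, else −b. A query packed at the very top
    scores +(1 − (t−1)/n); packed at the bottom, the mirror value.

    ``variant='ks2samp'`` uses the two-sample KS statistic between query and
    non-query Z-scores, signed by the query's mean Z, for sensitivity
    analysis.

    Raises ``ValueError`` when the query does not intersect the profile.
    """
    z = profile.copy()
    z.index = [normalize_symbol(g) for g in z.index]
    universe = set(z.index)
    query = {normalize_symbol(g) for g in up_set} & universe
    if not query:
        raise ValueError("up-set does not intersect the profile gene universe")
    if len(query) < len(set(normalize_symbol(g) for g in up_set)):
        logger.debug(
            "up-set trimmed to %d/%d genes present in profile", len(query), len(set(up_set))
        )
    order = sorted(z.index, key=lambda g: (-z[g], g))
    n = len(order)
    if variant == "ks2samp":
        in_q = np.array([g in query for g in order])
        vals = z.loc[order].to_numpy()
        d = stats.ks_2samp(vals[in_q], vals[~in_q]).statistic
        sign = 1.0 if vals[in_q].mean() >= vals[~in_q].mean() else -1.0
        return float(sign * d)
    if variant != "cmap":
        raise ValueError(f"unknown KS variant {variant!r}")
    positions = sorted(i + 1 for i, g in enumerate(order) if g in query)
    t = len(positions)
    a = max(j / t - (v - 1) / n for j, v in enumerate(positions, start=1))
    b = max(v / n - (j - 1) / t for j, v in enumerate(positions, start=1))
    return float(a) if a > b else float(-b)


def score_drugs(
    profiles: DrugProfileSet, up_set, variant: str = "cmap"
) -> pd.Series:
    """Raw connectivity per drug; drugs with no query overlap are dropped."""
    raw = {}
    for drug in profiles.drugs:
        try:
            raw[drug] = ks_connectivity(profiles.profile(drug), up_set, variant=variant)
        except ValueError:
            logger.warning("drug %s dropped: no overlap with up-set", drug)
    return pd.Series(raw, dtype=float)


def normalize_scores(raw: pd.Series) -> pd.Series:
    """Map raw scores into [−1, 1]: positives by the max positive, negatives
    by the magnitude of the most negative (connectivity-map convention).
    Rank order within each sign is preserved; zeros stay zero."""
    out = raw.astype(float).copy()
    pos_max = out[out > 0].max()
    neg_min = out[out < 0].min()
    if pd.notna(pos_max) and pos_max > 0:
        out[out > 0] = out[out > 0] / pos_max
    if pd.notna(neg_min) and neg_min < 0:
        out[out < 0] = out[out < 0] / abs(neg_min)
    return out


@dataclass
class DrugRanking:
    """Per-drug connectivity table with reverser selection and Eq.-style weights.

    ``table`` columns: raw, normalized, selected, rank, weight. Ranks run
    1..n_d over selected drugs only (1 = most negative normalized score,
    ties broken by drug name); weights are frozen at selection time.
    """

    table: pd.DataFrame
    cutoff: float

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    @property
    def selected(self) -> list[str]:
        t = self.table[self.table["selected"]]
        return list(t.sort_values("rank").index)

    def weight(self, drug: str) -> float:
        w = self.table.at[drug, "weight"]
        if pd.isna(w):
            raise KeyError(f"drug {drug!r} was not selected")
        return float(w)

    def restrict(self, keep) -> "DrugRanking":
        """Deselect drugs outside ``keep`` without recomputing ranks/weights."""
        t = self.table.copy()
        t["selected"] = t["selected"] & t.index.isin(set(keep))
        return DrugRanking(t, self.cutoff)


def select_and_weight(
    normalized: pd.Series,
    cutoff: float = -0.50,
    raw: pd.Series | None = None,
) -> DrugRanking:
    """Select reversers (normalized ≤ cutoff) and assign rank weights
    w_i = 1 + (1 − r_i/n_d)."""
    if not (-1.0 <= cutoff <= 0.0):
        raise ValueError("cutoff must lie in [-1, 0]")
    normalized = normalized.astype(float)
    table = pd.DataFrame(
        {
            "raw": raw.reindex(normalized.index) if raw is not None else np.nan,
            "normalized": normalized,
            "selected": normalized <= cutoff,
            "rank": np.nan,
            "weight": np.nan,
        }
    )
    sel = sorted(
        table.index[table["selected"]], key=lambda d: (table.at[d, "normalized"], d)
    )
    n_d = len(sel)
    for r, drug in enumerate(sel, start=1):
        table.at[drug, "rank"] = r
        table.at[drug, "weight"] = 1.0 + (1.0 - r / n_d)
    return DrugRanking(table.sort_index(), cutoff)
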