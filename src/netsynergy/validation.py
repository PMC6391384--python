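"""Evaluation of predicted pairs against a Bliss synergy screen.

A predicted pair found in the screen is a true positive when its Bliss
score is positive and a false positive when negative (exact zeros are
excluded and counted). False negatives are screened pairs with positive
Bliss whose two constituent drugs were both in the method's single-drug
pool yet the pair was never predicted. Both the harmonic F1 and the
geometric mean of precision and recall are reported.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import pandas as pd

from .io import BlissMatrix
from .synergy import PairPrediction

logger = logging.getLogger("netsynergy")

__all__ = ["ValidationReport", "evaluate", "baseline_run", "BASELINE_MODES"]

BASELINE_MODES = ("full", "roots_only", "deg_only", "rewired", "random_pairs")


@dataclass
class ValidationReport:
    tp: int
    fp: int
    fn: int
    excluded_zero: int
    precision: float
    recall: float
    f1: float
    f1_geom: float
    pool: set[str]
    adjudication: pd.DataFrame = field(repr=False)
    evaluable_empty: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "excluded_zero": self.excluded_zero,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f1_geom": self.f1_geom,
            "evaluable_empty": self.evaluable_empty,
            "pool_size": len(self.pool),
        }


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def evaluate(
    predictions: list[PairPrediction] | list[tuple[str, str]],
    bliss: BlissMatrix,
    pool,
) -> ValidationReport:
    """Adjudicate predictions against the screen.

    ``pool`` is the method's single-drug universe; positive-Bliss pairs with
    a drug outside the pool are never counted as false negatives. An empty
    evaluable set yields NaN metrics with ``evaluable_empty`` set rather
    than an exception.
    """
    pool = {str(d).strip() for d in pool}
    pred_pairs: list[tuple[str, str]] = []
    seen = set()
    for p in predictions:
        a, b = p.pair if isinstance(p, PairPrediction) else p
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            pred_pairs.append(key)

    rows = []
    tp = fp = zero = 0
    for a, b in pred_pairs:
        if (a, b) not in bliss:
            rows.append((a, b, math.nan, "not_screened"))
            continue
        s = bliss[(a, b)]
        if s > 0:
            tp += 1
            rows.append((a, b, s, "tp"))
        elif s < 0:
            fp += 1
            rows.append((a, b, s, "fp"))
        else:
            zero += 1
            rows.append((a, b, s, "excluded_zero"))
            logger.info("pair %s-%s has Bliss exactly 0; excluded", a, b)

    fn = 0
    for a, b in bliss.pairs():
        if bliss[(a, b)] > 0 and a in pool and b in pool and (a, b) not in seen:
            fn += 1
            rows.append((a, b, bliss[(a, b)], "fn"))

    adjudication = pd.DataFrame(rows, columns=["drugA", "drugB", "bliss", "call"])
    evaluable = tp + fp + zero
    if evaluable == 0:
        nan = float("nan")
        return ValidationReport(
            tp, fp, fn, zero, nan, nan, nan, nan, pool, adjudication, evaluable_empty=True
        )
    precision = _safe_ratio(tp, tp + fp)
    recall = _safe_ratio(tp, tp + fn)
    f1 = _safe_ratio(2 * precision * recall, precision + recall)
    f1_geom = math.sqrt(precision * recall)
    return ValidationReport(
        tp, fp, fn, zero, precision, recall, f1, f1_geom, pool, adjudication
    )


def baseline_run(mode: str, inputs, seed: int = 0, config=None) -> ValidationReport:
    """Run one ablation variant of the pipeline and evaluate it.

    Modes: ``full`` (the method), ``roots_only`` (root-induced subgraph, no
    optimizer), ``deg_only`` (top up-regulated genes size-matched to the full
    subnetwork, no optimizer), ``rewired`` (degree-preserving PPI shuffle
    before inference), ``random_pairs`` (size-matched uniform pairs from the
    drug pool).
    """
    from .pipeline import run_pipeline  # local import: pipeline depends on evaluate

    if mode not in BASELINE_MODES:
        raise ValueError(f"unknown baseline mode {mode!r}; expected one of {BASELINE_MODES}")
    result = run_pipeline(inputs, config=config, mode=mode, seed=seed)
    if result.report is None:
        raise ValueError("baseline evaluation requires a Bliss matrix in the inputs")
    return result.report


def random_pair_report(
    n_pairs: int, pool, bliss: BlissMatrix, seed: int
) -> ValidationReport:
    """Evaluate ``n_pairs`` drug pairs sampled uniformly without replacement."""
    rng = random.Random(seed)
    pool = sorted({str(d).strip() for d in pool})
    all_pairs = [
        (a, b) for i, a in enumerate(pool) for b in pool[i + 1 :]
    ]
    n_pairs = min(n_pairs, len(all_pairs))
    sample = rng.sample(all_pairs, n_pairs) if n_pairs else []
    return evaluate(sample, bliss, pool)
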