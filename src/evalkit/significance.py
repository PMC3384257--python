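"""Approximate randomization test for F-score differences between two systems.

The test statistic is the absolute difference of the two systems' pooled
(micro-averaged) total F1 over the corpus. Under the null hypothesis that the
systems are interchangeable, swapping the two systems' outputs on any subset
of documents leaves the statistic's distribution unchanged; each repetition
therefore swaps the per-document outputs independently with probability 1/2
and recomputes the statistic. The p-value uses the add-one estimator
``(b + 1) / (R + 1)`` where ``b`` counts repetitions whose pseudo-statistic
reaches the observed value, so p is never exactly zero.

For small corpora an exhaustive mode enumerates all ``2^D`` swap patterns and
returns the exact permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .evaluation import PRFScore, evaluate
from .schemas import TaskSchema
from .standoff import AnnotationSet

__all__ = ["SignificanceConfig", "SignificanceResult", "approx_randomization_test"]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class SignificanceConfig:
    """Settings for the randomization test.

    ``repetitions`` defaults to 9,999; ``exhaustive`` enumerates all swap
    patterns instead of sampling (documents are limited to 20 to keep the
    enumeration tractable).
    """

    repetitions: int = 9_999
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class SignificanceResult:
    observed: float
    p_value: float
    repetitions: int
    seed: int | None
    exhaustive: bool = False


def _doc_counts(
    pred: Mapping[str, AnnotationSet],
    gold: Mapping[str, AnnotationSet],
    schema: TaskSchema,
    criterion: str,
    mode: str,
    doc_ids: list[str],
) -> np.ndarray:
    rows = []
    for doc_id in doc_ids:
        report = evaluate({doc_id: pred[doc_id]}, {doc_id: gold[doc_id]}, schema, criterion=criterion, mode=mode)
        t = report.total
        rows.append((t.matched_gold, t.gold_total, t.matched_pred, t.pred_total))
    return np.asarray(rows, dtype=np.int64)


def _f1_from_sums(sums: np.ndarray) -> np.ndarray:
    """F1 (percent) from pooled count vectors [..., (mg, gt, mp, pt)]."""
    mg, gt, mp, pt = (sums[..., i].astype(float) for i in range(4))
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(gt > 0, 100.0 * mg / np.maximum(gt, 1), 0.0)
        precision = np.where(pt > 0, 100.0 * mp / np.maximum(pt, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return f1


def approx_randomization_test(
    pred_a,
    pred_b,
    gold,
    schema: TaskSchema,
    criterion: str = "primary",
    mode: str = "full",
    config: SignificanceConfig | None = None,
) -> SignificanceResult:
    """Test the significance of the total-F1 difference between two systems.

    ``pred_a``, ``pred_b`` and ``gold`` are mappings from document id to
    annotation set covering the same documents. Fully reproducible from
    ``config.seed``.
    """
    cfg = config or SignificanceConfig()
    pred_a, pred_b, gold = dict(pred_a), dict(pred_b), dict(gold)
    if not (set(pred_a) == set(pred_b) == set(gold)):
        raise ValueError("pred_a, pred_b and gold must cover the same documents")
    doc_ids = sorted(gold)
    counts_a = _doc_counts(pred_a, gold, schema, criterion, mode, doc_ids)
    counts_b = _doc_counts(pred_b, gold, schema, criterion, mode, doc_ids)

    total_a, total_b = counts_a.sum(axis=0), counts_b.sum(axis=0)
    observed = abs(float(_f1_from_sums(total_a)) - float(_f1_from_sums(total_b)))
    diff = counts_b - counts_a  # swapping doc d adds diff[d] to A and removes it from B

    if cfg.exhaustive:
        n_docs = len(doc_ids)
        if n_docs > 20:
            raise ValueError("exhaustive mode supports at most 20 documents")
        patterns = np.arange(2**n_docs, dtype=np.uint64)
        masks = ((patterns[:, None] >> np.arange(n_docs, dtype=np.uint64)) & 1).astype(bool)
        stats = _pseudo_stats(masks, total_a, total_b, diff)
        b = int(np.count_nonzero(stats >= observed - _TIE_EPS))
        p = b / len(patterns)
        return SignificanceResult(observed, p, len(patterns), cfg.seed, exhaustive=True)

    rng = np.random.default_rng(cfg.seed)
    masks = rng.random((cfg.repetitions, len(doc_ids))) < 0.5
    stats = _pseudo_stats(masks, total_a, total_b, diff)
    b = int(np.count_nonzero(stats >= observed - _TIE_EPS))
    p = (b + 1) / (cfg.repetitions + 1)
    return SignificanceResult(observed, p, cfg.repetitions, cfg.seed, exhaustive=False)


def _pseudo_stats(masks: np.ndarray, total_a: np.ndarray, total_b: np.ndarray, diff: np.ndarray) -> np.ndarray:
    shift = masks.astype(np.int64) @ diff  # (R, 4)
    swapped_a = total_a[None, :] + shift
    swapped_b = total_b[None, :] - shift
    return np.abs(_f1_from_sums(swapped_a) - _f1_from_sums(swapped_b))
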