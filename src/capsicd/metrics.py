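"""Evaluation suite for multi-label code prediction.

Covers micro/macro F1 over binary decisions, the top-10 recall used in the
medical-coding literature (per note, gold codes recovered within the top
max(10, |M|) scores, |M| the note's gold-code count), macro AUC within
label-frequency groups, and a false-positive / false-negative error
breakdown annotated with similar-code confusions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from .fusion import cosine_matrix

logger = logging.getLogger(__name__)


@dataclass
class FrequencyBins:
    """Ordered, non-overlapping inclusive intervals over training counts.

    The default grouping is [1,10], [11,50], [51,100], [101, inf); the upper
    group is open-ended.
    """

    edges: Sequence[tuple[int, float]] = (
        (1, 10),
        (11, 50),
        (51, 100),
        (101, float("inf")),
    )

    def __post_init__(self) -> None:
        prev_hi = 0
        for lo, hi in self.edges:
            if lo != prev_hi + 1 or hi < lo:
                raise ValueError(f"bins must be ordered, exhaustive, non-overlapping: {self.edges}")
            prev_hi = hi if hi != float("inf") else prev_hi
        if self.edges[-1][1] != float("inf"):
            raise ValueError("last bin must be open-ended")

    def name(self, lo: int, hi: float) -> str:
        return f"[{lo},{'inf' if hi == float('inf') else int(hi)}]"

    def assign(self, count: int) -> str:
        for lo, hi in self.edges:
            if lo <= count <= hi:
                return self.name(lo, hi)
        raise ValueError(f"count {count} not covered by bins (counts must be >= 1)")


@dataclass
class MetricsReport:
    """All evaluation quantities for one model/test-set pair."""

    micro_f1: float
    macro_f1: float
    top10_recall: float
    test_loss: float | None
    per_group_macro_auc: dict[str, float]
    decision_policy: dict
    n_notes: int = 0
    error_summary: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        payload = {
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "top10_recall": self.top10_recall,
            "test_loss": self.test_loss,
            "per_group_macro_auc": self.per_group_macro_auc,
            "decision_policy": self.decision_policy,
            "n_notes": self.n_notes,
            "error_summary": self.error_summary,
        }
        return json.dumps(payload, sort_keys=True, **kwargs)

    def table(self) -> str:
        lines = [
            f"micro F1      {self.micro_f1:8.4f}",
            f"macro F1      {self.macro_f1:8.4f}",
            f"top-10 recall {self.top10_recall:8.4f}",
        ]
        if self.test_loss is not None:
            lines.append(f"test loss     {self.test_loss:8.4f}")
        for group, auc in self.per_group_macro_auc.items():
            lines.append(f"macro AUC {group:>10} {auc:8.4f}")
        return "\n".join(lines)


def _check_binary(gold: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gold = np.asarray(gold, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if gold.shape != pred.shape:
        raise ValueError(f"shape mismatch: gold {gold.shape}, pred {pred.shape}")
    return gold, pred


def micro_f1(gold: np.ndarray, pred: np.ndarray) -> float:
    """F1 pooled over every (note, label) decision: 2TP / (2TP + FP + FN)."""
    gold, pred = _check_binary(gold, pred)
    return float(f1_score(gold.ravel(), pred.ravel(), zero_division=0))


def macro_f1(gold: np.ndarray, pred: np.ndarray) -> float:
    """Unweighted mean of per-label F1 (0 when a label has no TP, FP or FN
    support in either precision or recall)."""
    gold, pred = _check_binary(gold, pred)
    return float(np.mean(f1_score(gold, pred, average=None, zero_division=0)))


def top10_recall(scores: np.ndarray, gold: np.ndarray, k: int = 10) -> float:
    """Per note, the fraction of gold codes ranked within the top
    max(k, |M|) scores (ties broken by label order), averaged over notes;
    notes with no gold code are excluded with a warning."""
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if scores.shape != gold.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape}, gold {gold.shape}")
    vals = []
    n_skip = 0
    for srow, grow in zip(scores, gold):
        m = int(grow.sum())
        if m == 0:
            n_skip += 1
            continue
        kk = min(max(k, m), len(srow))
        top = np.argsort(-srow, kind="stable")[:kk]
        vals.append(grow[top].sum() / m)
    if n_skip:
        logger.warning("top-%d recall: skipped %d notes with no gold code", k, n_skip)
    if not vals:
        raise ValueError("no notes with at least one gold code")
    return float(np.mean(vals))


def label_auc(scores: np.ndarray, gold: np.ndarray) -> np.ndarray:
    """Per-label ranking AUC; NaN for labels whose gold column is constant."""
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold, dtype=float)
    out = np.full(scores.shape[1], np.nan)
    for j in range(scores.shape[1]):
        col = gold[:, j]
        if col.min() == col.max():
            continue
        out[j] = roc_auc_score(col, scores[:, j])
    return out


def macro_auc_by_group(
    scores: np.ndarray,
    gold: np.ndarray,
    train_label_counts: Sequence[int] | Mapping[int, int],
    bins: FrequencyBins | None = None,
) -> dict[str, float]:
    """Unweighted mean per-label AUC within label-frequency groups.

    Labels are grouped by their training-split frequency; labels with a
    constant gold column (all positive or all negative in the test set) are
    skipped with a warning. Empty groups are absent from the result.
    """
    bins = bins or FrequencyBins()
    if isinstance(train_label_counts, Mapping):
        counts = [train_label_counts.get(j, 0) for j in range(np.asarray(gold).shape[1])]
    else:
        counts = list(train_label_counts)
    aucs = label_auc(scores, gold)
    n_skipped = int(np.isnan(aucs).sum())
    if n_skipped:
        logger.warning("macro AUC: skipped %d labels with constant gold column", n_skipped)
    groups: dict[str, list[float]] = {}
    for j, auc in enumerate(aucs):
        if np.isnan(auc) or counts[j] < 1:
            continue
        groups.setdefault(bins.assign(counts[j]), []).append(auc)
    return {bins.name(lo, hi): float(np.mean(groups[bins.name(lo, hi)]))
            for lo, hi in bins.edges if bins.name(lo, hi) in groups}


def error_breakdown(
    gold: np.ndarray,
    pred: np.ndarray,
    train_label_counts: Sequence[int],
    labels: Sequence[str] | None = None,
    label_vectors: np.ndarray | None = None,
    bins: FrequencyBins | None = None,
    top_pairs: int = 10,
) -> dict:
    """Per-label false-positive / false-negative tallies with frequency-bin
    annotation, plus the most frequent confused similar-code pairs.

    A confusion pair (predicted A, gold-only B) counts the notes where A was
    predicted but not gold while the similar code B was gold but missed;
    similarity means a shared 2-character root prefix or, when
    ``label_vectors`` is given, description cosine >= 0.7.
    """
    gold, pred = _check_binary(gold, pred)
    bins = bins or FrequencyBins()
    L = gold.shape[1]
    names = list(labels) if labels is not None else [str(j) for j in range(L)]
    fp = ((pred == 1) & (gold == 0)).sum(axis=0).astype(int)
    fn = ((pred == 0) & (gold == 1)).sum(axis=0).astype(int)
    per_label = {
        names[j]: {
            "fp": int(fp[j]),
            "fn": int(fn[j]),
            "train_count": int(train_label_counts[j]),
            "group": bins.assign(max(int(train_label_counts[j]), 1)),
        }
        for j in range(L)
    }
    sim = np.zeros((L, L), dtype=bool)
    for a in range(L):
        for b in range(L):
            if a != b and names[a][:2] == names[b][:2]:
                sim[a, b] = True
    if label_vectors is not None:
        sim |= (cosine_matrix(label_vectors, label_vectors) >= 0.7) & ~np.eye(L, dtype=bool)
    pairs: dict[tuple[str, str], int] = {}
    fp_cells = (pred == 1) & (gold == 0)
    fn_cells = (pred == 0) & (gold == 1)
    for a in range(L):
        for b in range(L):
            if not sim[a, b]:
                continue
            n = int((fp_cells[:, a] & fn_cells[:, b]).sum())
            if n:
                pairs[(names[a], names[b])] = n
    confused = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))[:top_pairs]
    return {
        "per_label": per_label,
        "confused_pairs": [
            {"predicted": a, "gold": b, "count": n} for (a, b), n in confused
        ],
    }


def compute_report(
    scores: np.ndarray,
    gold: np.ndarray,
    train_label_counts: Sequence[int],
    threshold: float | None = 0.5,
    top_k: int | None = None,
    test_loss: float | None = None,
    labels: Sequence[str] | None = None,
    bins: FrequencyBins | None = None,
) -> MetricsReport:
    """Assemble the full metric report from a score matrix and gold matrix."""
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if top_k is not None:
        pred = np.zeros_like(scores)
        for i, row in enumerate(scores):
            pred[i, np.argsort(-row, kind="stable")[:top_k]] = 1.0
        policy = {"policy": "top-k", "k": top_k}
    else:
        pred = (scores >= threshold).astype(float)
        policy = {"policy": "threshold", "tau": threshold}
    return MetricsReport(
        micro_f1=micro_f1(gold, pred),
        macro_f1=macro_f1(gold, pred),
        top10_recall=top10_recall(scores, gold),
        test_loss=test_loss,
        per_group_macro_auc=macro_auc_by_group(scores, gold, train_label_counts, bins),
        decision_policy=policy,
        n_notes=int(gold.shape[0]),
        error_summary=error_breakdown(gold, pred, train_label_counts, labels=labels, bins=bins),
    )
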