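"""Binary-classifier evaluation: contingency tables, threshold selection and
the full metric suite (sensitivity, specificity, BAC, Acc, precision, recall,
F, MCC, Youden J, ROC_AUC, PR_AUC).

Conventions
-----------
* A sample is predicted positive iff its probability is >= the cutoff.
* Any 0/0 rate is reported as 0.0 and flagged in ``degenerate_flags``.
* ROC_AUC on a single-class set is reported as 0.5 with a flag; PR_AUC with
  no positives is reported as the prevalence (0.0) with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ContingencyTable",
    "MetricReport",
    "contingency",
    "basic_metrics",
    "youden_cutoff",
    "roc_auc",
    "pr_auc",
    "roc_curve_points",
    "pr_curve_points",
    "full_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/TN/FN counts for one cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """All metrics for one evaluation split.

    ``degenerate_flags`` lists every quantity whose defining ratio was 0/0
    (or whose curve was undefined) and therefore carries a convention value.
    """

    sensitivity: float = 0.0
    specificity: float = 0.0
    bac: float = 0.0
    acc: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    f_measure: float = 0.0
    mcc: float = 0.0
    youden_j: float = 0.0
    cutoff: float = 0.5
    roc_auc: float = 0.5
    pr_auc: float = 0.0
    loss_train: float = float("nan")
    loss_valid: float = float("nan")
    loss_test: float = float("nan")
    n: int = 0
    degenerate_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    NUMERIC_FIELDS = (
        "sensitivity", "specificity", "bac", "acc", "precision", "recall",
        "f_measure", "mcc", "youden_j", "cutoff", "roc_auc", "pr_auc",
        "loss_train", "loss_valid", "loss_test",
    )


def _as_arrays(probs: Sequence[float], labels: Sequence[int]):
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probs and labels must be 1-D and of equal length")
    if p.size == 0:
        raise ValueError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0/1")
    return p, y


def contingency(probs: Sequence[float], labels: Sequence[int],
                cutoff: float) -> ContingencyTable:
    """Count TP/FP/TN/FN with predicted-positive defined as prob >= cutoff."""
    p, y = _as_arrays(probs, labels)
    pred = p >= cutoff
    pos = y == 1
    return ContingencyTable(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return 0.0
    return num / den


def basic_metrics(table: ContingencyTable) -> MetricReport:
    """Rates derived from a single contingency table.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    BAC = (sensitivity+specificity)/2, Acc = (TP+TN)/n,
    precision = TP/(TP+FP), F = 2*recall*precision/(recall+precision),
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if table.total == 0:
        raise ValueError("empty contingency table")
    tp, fp, tn, fn = table.tp, table.fp, table.tn, table.fn
    flags: list[str] = []
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    prec = _safe_div(tp, tp + fp, "precision", flags)
    acc = (tp + tn) / table.total
    f = _safe_div(2 * sens * prec, sens + prec, "f_measure", flags)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom2))
    return MetricReport(
        sensitivity=sens, specificity=spec, bac=(sens + spec) / 2.0,
        acc=acc, precision=prec, recall=sens, f_measure=f, mcc=float(mcc),
        youden_j=sens + spec - 1.0, n=table.total, degenerate_flags=flags,
    )


def _candidate_cutoffs(p: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique probabilities, plus
    sentinels below the minimum and above the maximum."""
    u = np.unique(p)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    lo = u[0] - 0.5
    hi = u[-1] + 0.5
    return np.concatenate(([lo], mids, [hi]))


def youden_cutoff(probs: Sequence[float],
                  labels: Sequence[int]) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive sorted unique
    probabilities plus below-min/above-max sentinels; ties are broken toward
    the smallest cutoff.
    """
    p, y = _as_arrays(probs, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("youden_cutoff requires both classes present")
    best_c, best_j = None, -np.inf
    for c in _candidate_cutoffs(p):
        pred = p >= c
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-15:  # strict improvement -> smallest cutoff wins ties
            best_c, best_j = float(c), float(j)
    return best_c, best_j


def roc_auc(probs: Sequence[float], labels: Sequence[int],
            flags: list[str] | None = None) -> float:
    """Mann-Whitney ROC AUC: P(score_pos > score_neg), ties counted 1/2.

    Single-class input returns 0.5 (flagged if ``flags`` is provided).
    """
    p, y = _as_arrays(probs, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        if flags is not None:
            flags.append("roc_auc")
        return 0.5
    # average ranks (midrank for ties)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(p.size, dtype=float)
    sorted_p = p[order]
    i = 0
    while i < p.size:
        j = i
        while j + 1 < p.size and sorted_p[j + 1] == sorted_p[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def pr_auc(probs: Sequence[float], labels: Sequence[int],
           flags: list[str] | None = None) -> float:
    """Area under the precision-recall curve (average-precision convention):

        AP = sum_k (R_k - R_{k-1}) * P_k

    stepping through thresholds at the observed scores in decreasing order.
    With no positive labels, returns 0.0 and flags the result.
    """
    p, y = _as_arrays(probs, labels)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        if flags is not None:
            flags.append("pr_auc")
        return 0.0
    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    tp = np.cumsum(ys)
    n_pred = np.arange(1, ys.size + 1)
    # threshold steps only where the score changes
    distinct = np.append(ps[1:] != ps[:-1], True)
    tp_d = tp[distinct]
    n_d = n_pred[distinct]
    precision = tp_d / n_d
    recall = tp_d / n_pos
    prev_recall = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - prev_recall) * precision))


def roc_curve_points(probs, labels) -> list[tuple[float, float, float]]:
    """(cutoff, FPR, TPR) triples over all candidate cutoffs, for plotting."""
    p, y = _as_arrays(probs, labels)
    n_pos = max(int(np.sum(y == 1)), 1)
    n_neg = max(int(np.sum(y == 0)), 1)
    pts = []
    for c in _candidate_cutoffs(p)[::-1]:
        pred = p >= c
        pts.append((float(c),
                    float(np.sum(pred & (y == 0)) / n_neg),
                    float(np.sum(pred & (y == 1)) / n_pos)))
    return pts


def pr_curve_points(probs, labels) -> list[tuple[float, float, float]]:
    """(cutoff, recall, precision) triples over all candidate cutoffs."""
    p, y = _as_arrays(probs, labels)
    n_pos = max(int(np.sum(y == 1)), 1)
    pts = []
    for c in _candidate_cutoffs(p)[::-1]:
        pred = p >= c
        n_pred = int(np.sum(pred))
        prec = float(np.sum(pred & (y == 1)) / n_pred) if n_pred else 1.0
        pts.append((float(c), float(np.sum(pred & (y == 1)) / n_pos), prec))
    return pts


def full_report(probs: Sequence[float], labels: Sequence[int],
                cutoff: float | None = None) -> MetricReport:
    """Complete report: Youden cutoff (unless given), contingency at that
    cutoff, basic rates, ROC_AUC and PR_AUC."""
    p, y = _as_arrays(probs, labels)
    flags: list[str] = []
    single_class = len(np.unique(y)) < 2
    if cutoff is None:
        if single_class:
            flags.append("youden_cutoff")
            cutoff, j = 0.5, 0.0
        else:
            cutoff, j = youden_cutoff(p, y)
    else:
        tab = basic_metrics(contingency(p, y, cutoff))
        j = tab.youden_j
    report = basic_metrics(contingency(p, y, cutoff))
    report.cutoff = float(cutoff)
    report.youden_j = float(j)
    report.roc_auc = roc_auc(p, y, flags)
    report.pr_auc = pr_auc(p, y, flags)
    report.degenerate_flags = sorted(set(report.degenerate_flags + flags))
    return report
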