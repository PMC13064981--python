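"""Loss and ranking metrics for imbalanced link prediction.

AUROC uses the Mann–Whitney convention (ties get half credit); AUPRC is
average precision with tied scores grouped at a single threshold. Both are
implemented directly from their definitions so that tie handling is explicit
and exactly reproducible; scikit-learn's implementations serve as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import ContractError, MetricError

__all__ = ["bce_loss", "auroc", "auprc", "MetricsReport"]

PROB_EPS = 1e-7


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=int).reshape(-1)
    if len(s) != len(y):
        raise ContractError(f"scores ({len(s)}) and labels ({len(y)}) differ in length")
    return s, y


def bce_loss(scores, labels) -> float:
    """Mean binary cross-entropy with probabilities clamped to [eps, 1-eps]."""
    p, y = _as_arrays(scores, labels)
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def auroc(scores, labels) -> float:
    """Area under the ROC curve as the Mann–Whitney pair statistic.

    Equals (wins + 0.5 * ties) / (n_pos * n_neg) over all positive–negative
    score pairs; computed via average ranks.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUROC needs both classes present")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision over the descending-score sweep, ties grouped.

    ``sum_k (R_k - R_{k-1}) * P_k`` where k runs over distinct thresholds.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise MetricError("AUPRC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # keep only the last index of each tied-score group
    last_of_group = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last_of_group], fp[last_of_group]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class MetricsReport:
    """Evaluation result of one trained model on one test split."""

    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    neg_ratio: int | None = None
    split_mode: str = "random"
    seed: int = 0
    variant: str = "full"
    architecture: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc <= 1.0 and 0.0 <= self.auprc <= 1.0):
            raise MetricError("metrics must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "neg_ratio": self.neg_ratio,
            "split_mode": self.split_mode,
            "seed": self.seed,
            "variant": self.variant,
            "architecture": self.architecture,
            **self.extras,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)
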