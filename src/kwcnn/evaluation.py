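"""Micro/macro F1 and accuracy binned by training support.

Micro F1 pools true/false positives and negatives over all classes and, for
single-label multiclass prediction, equals plain accuracy.  Macro F1 is the
unweighted mean of per-class F1 over the *full* label inventory — classes that
are never predicted and never true contribute F1 = 0, which is what makes the
macro score sensitive to rare-class performance.  Support bins stratify test
accuracy by how many training documents the true class had, the standard way
to visualize rare-class behavior under long-tailed label distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

__all__ = ["EvalReport", "evaluate", "accuracy_by_support", "DEFAULT_BIN_EDGES"]

DEFAULT_BIN_EDGES = (0, 50, 500, 5000)


@dataclass
class SupportBin:
    lower: float
    upper: float
    accuracy: float  # NaN when the bin is empty
    n_test_samples: int


@dataclass
class EvalReport:
    micro_f1: float
    macro_f1: float
    per_class_f1: dict[str, float]
    support_bins: list[SupportBin] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "per_class_f1": self.per_class_f1,
            "support_bins": [
                {
                    "lower": b.lower,
                    "upper": b.upper,
                    "accuracy": b.accuracy,
                    "n_test_samples": b.n_test_samples,
                }
                for b in self.support_bins
            ],
        }


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str],
) -> EvalReport:
    """Micro, macro and per-class F1 over the full label inventory *labels*.

    Macro F1 averages per-class F1 over every class in the inventory, with
    zero-division per-class F1 defined as 0 (never-predicted, never-true
    classes count as 0, not excluded).
    """
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    missing = set(y_true) - set(labels)
    if missing:
        raise ValueError(f"true labels outside inventory: {sorted(missing)}")
    labels = list(labels)
    micro = float(
        f1_score(y_true, y_pred, labels=labels, average="micro", zero_division=0)
    )
    per_class = f1_score(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )
    macro = float(per_class.mean())
    return EvalReport(
        micro_f1=micro,
        macro_f1=macro,
        per_class_f1={l: float(f) for l, f in zip(labels, per_class)},
    )


def accuracy_by_support(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    train_counts: dict[str, int],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> list[SupportBin]:
    """Test accuracy per training-support bin of the TRUE class.

    Bins are half-open ``[lower, upper)`` over the true class's training-
    document count; the last bin is unbounded above.  Default edges give the
    bins 0-50, 50-500, 500-5000 and >=5000.  Empty bins report accuracy NaN
    with n = 0.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between y_true and y_pred")
    edges = list(bin_edges) + [np.inf]
    counts = np.array([train_counts[t] for t in y_true], dtype=float)
    correct = np.array([t == p for t, p in zip(y_true, y_pred)])
    bins: list[SupportBin] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (counts >= lo) & (counts < hi)
        n = int(mask.sum())
        acc = float(correct[mask].mean()) if n else float("nan")
        bins.append(SupportBin(lower=lo, upper=hi, accuracy=acc, n_test_samples=n))
    return bins
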