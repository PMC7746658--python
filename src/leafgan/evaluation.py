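"""Confusion-matrix construction and multiclass classification metrics.

For a K×K count matrix M with rows = true class and columns = predicted
class:

    overall accuracy = trace(M) / total
    recall_i    = M_ii / sum_j M_ij
    precision_i = M_ii / sum_j M_ji
    F1_i        = 2 R_i P_i / (R_i + P_i)

Degenerate denominators (a class with no true items, or never predicted)
yield metric 0 with an explicit flag rather than an error; flagged classes
are included in macro averages as 0 by default (configurable).

``rounding="table"`` reproduces printed report tables: each per-class F1 is
rounded half-up to two decimals before averaging, matching how published
per-class tables are summarized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "ClassMetrics", "confusion_matrix",
           "overall_accuracy", "per_class_metrics", "f1_score",
           "macro_average_f1", "metrics_report", "round_half_up",
           "MetricsReport"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 → 0.01), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K×K integer counts; ``matrix[i, j]`` = true class i predicted as j."""

    matrix: np.ndarray
    class_names: List[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("confusion-matrix entries must be non-negative")
        if len(self.class_names) != self.matrix.shape[0]:
            raise ValueError("class_names length must match matrix size")
        self.matrix = self.matrix.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def supports(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def prediction_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.class_names,
                            columns=self.class_names)


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class recall / precision / F1 with degeneracy flags."""

    name: str
    recall: float
    precision: float
    f1: float
    support: int
    recall_defined: bool = True
    precision_defined: bool = True


def confusion_matrix(true_labels: Sequence[int], predicted_labels: Sequence[int],
                     n_classes: int, class_names: List[str] | None = None
                     ) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if bad.size:
            raise ValueError(
                f"{name} label out of range at index {bad[0]}: {arr[bad[0]]}")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    names = class_names or [f"class_{i:02d}" for i in range(n_classes)]
    return ConfusionMatrix(m, list(names))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of items on the diagonal (multiclass overall accuracy)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.matrix)) / cm.total


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both are 0."""
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def per_class_metrics(cm: ConfusionMatrix) -> List[ClassMetrics]:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    out = []
    diag = np.diag(cm.matrix)
    row = cm.supports()
    col = cm.prediction_counts()
    for i, name in enumerate(cm.class_names):
        r_def, p_def = row[i] > 0, col[i] > 0
        r = diag[i] / row[i] if r_def else 0.0
        p = diag[i] / col[i] if p_def else 0.0
        out.append(ClassMetrics(name=name, recall=float(r), precision=float(p),
                                f1=f1_score(float(r), float(p)),
                                support=int(row[i]),
                                recall_defined=bool(r_def),
                                precision_defined=bool(p_def)))
    return out


def macro_average_f1(metrics: Sequence[Union[ClassMetrics, float]],
                     rounding: str = "full",
                     include_degenerate: bool = True) -> float:
    """Unweighted mean of per-class F1 scores.

    ``rounding="table"`` rounds each F1 half-up to 2 decimals first, which
    is the mode that reproduces printed table averages; ``"full"`` keeps
    full precision.
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics list")
    if rounding not in ("full", "table"):
        raise ValueError("rounding must be 'full' or 'table'")
    vals = []
    for m in metrics:
        if isinstance(m, ClassMetrics):
            if not include_degenerate and not (m.recall_defined
                                               and m.precision_defined):
                continue
            v = m.f1
        else:
            v = float(m)
        vals.append(round_half_up(v, 2) if rounding == "table" else v)
    if not vals:
        raise ValueError("no classes left after excluding degenerate ones")
    return float(np.mean(vals))


@dataclass
class MetricsReport:
    """Per-group metric tables plus overall summary (CSV/JSON writable)."""

    overall_accuracy: float
    groups: Dict[str, pd.DataFrame]
    group_macro_f1: Dict[str, float]
    macro_f1: float

    def to_json(self) -> str:
        return json.dumps({
            "overall_accuracy": self.overall_accuracy,
            "macro_f1": self.macro_f1,
            "group_macro_f1": self.group_macro_f1,
            "groups": {g: df.to_dict(orient="records")
                       for g, df in self.groups.items()},
        }, indent=1)

    def save(self, directory) -> None:
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for g, df in self.groups.items():
            df.to_csv(directory / f"metrics_{g}.csv", index=False)
        (directory / "summary.json").write_text(json.dumps({
            "overall_accuracy": self.overall_accuracy,
            "macro_f1": self.macro_f1,
            "group_macro_f1": self.group_macro_f1}, indent=1))


def metrics_report(cm: ConfusionMatrix,
                   split_map: Dict[str, Sequence[str]] | None = None,
                   rounding: str = "full") -> MetricsReport:
    """Metric tables per class group (e.g. diseased vs healthy).

    ``split_map`` maps group name → class names and must partition the
    classes; ``None`` puts everything in one group ``"all"``.
    """
    metrics = per_class_metrics(cm)
    by_name = {m.name: m for m in metrics}
    if split_map is None:
        split_map = {"all": list(cm.class_names)}
    claimed = [c for g in split_map.values() for c in g]
    if sorted(claimed) != sorted(cm.class_names):
        raise ValueError("split_map is not a partition of the classes")
    groups, group_f1 = {}, {}
    for gname, members in split_map.items():
        ms = [by_name[c] for c in members]
        groups[gname] = pd.DataFrame(
            [{"class": m.name, "recall": m.recall, "precision": m.precision,
              "f1": m.f1, "support": m.support,
              "degenerate": not (m.recall_defined and m.precision_defined)}
             for m in ms])
        group_f1[gname] = macro_average_f1(ms, rounding=rounding)
    return MetricsReport(
        overall_accuracy=overall_accuracy(cm),
        groups=groups,
        group_macro_f1=group_f1,
        macro_f1=macro_average_f1(metrics, rounding=rounding),
    )
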