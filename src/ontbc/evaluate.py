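"""Score barcode whitelists against a ground truth.

Precision and recall are computed over the set of barcodes whose counts
strictly exceed each threshold; sweeping the threshold over every distinct
count value traces the precision-recall curve, summarised by the trapezoid
area under the curve (over recall, with an anchored (0, first-precision)
endpoint).  A contamination diagnostic reports how many query barcodes sit
within a small edit distance of a reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .whitelist import BarcodeCountTable, min_edit_distance_le


@dataclass(frozen=True)
class PRCurve:
    """Ordered (threshold, precision, recall) points and the AUC."""

    points: tuple[tuple[float, float, float], ...]
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["threshold", "precision", "recall"])


def precision_recall_at(
    predicted: set[str], truth: set[str]
) -> tuple[float, float]:
    """Precision/recall of one prediction set (empty prediction: precision 1)."""
    if not truth:
        raise ValueError("ground-truth barcode set is empty")
    if not predicted:
        return 1.0, 0.0
    tp = len(predicted & truth)
    return tp / len(predicted), tp / len(truth)


def precision_recall_curve(
    table: BarcodeCountTable,
    truth: set[str],
    thresholds: Union[str, Sequence[float]] = "all",
) -> PRCurve:
    """PR curve of the count table across count thresholds.

    ``thresholds="all"`` sweeps every distinct count value plus 0.  At each
    threshold ``t`` the prediction is ``{barcode : count > t}``.
    """
    if not truth:
        raise ValueError("ground-truth barcode set is empty")
    if isinstance(thresholds, str):
        if thresholds != "all":
            raise ValueError(f"unknown threshold spec {thresholds!r}")
        grid = sorted(set(table.entries.values()) | {0})
    else:
        grid = sorted(set(float(t) for t in thresholds))

    points = []
    for t in grid:
        predicted = {bc for bc, count in table.entries.items() if count > t}
        precision, recall = precision_recall_at(predicted, truth)
        points.append((float(t), precision, recall))

    # best achievable precision at each recall level (several thresholds can
    # share a recall); trapezoid over recall with an anchored left endpoint
    best: dict[float, float] = {}
    for _, precision, recall in points:
        best[recall] = max(best.get(recall, 0.0), precision)
    recalls = sorted(best)
    precisions = [best[r] for r in recalls]
    recalls = [0.0] + recalls
    precisions = [precisions[0]] + precisions
    auc = float(np.trapezoid(precisions, recalls))
    return PRCurve(points=tuple(points), auc=auc)


def ed_contamination_fraction(
    query: Iterable[str], reference: set[str], cutoff: int = 2
) -> float:
    """Fraction of query barcodes within edit distance ``cutoff`` of the reference."""
    query = list(query)
    if not query or not reference:
        raise ValueError("query and reference barcode sets must be non-empty")
    hits = sum(1 for q in query if min_edit_distance_le(q, reference, cutoff))
    return hits / len(query)
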