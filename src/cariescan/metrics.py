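"""Diagnostic-performance metrics and rank correlation.

Positive class is operative treatment: sensitivity is the fraction of
operative teeth called operative, specificity the fraction of preventive
teeth called preventive, accuracy the overall fraction of agreement with
the clinical treatment plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discriminant import OPERATIVE, PREVENTIVE

__all__ = ["ClassificationReport", "evaluate", "spearman_rho", "class_summary", "DIAGNOSIS_RANK"]

#: ordinal coding of the clinical severity scale for rank correlation
DIAGNOSIS_RANK = {"C0": 0, "C1": 1, "C2": 2}


@dataclass(frozen=True)
class ClassificationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def evaluate(predicted: Sequence[str], truth: Sequence[str]) -> ClassificationReport:
    """Confusion counts and sensitivity/specificity/accuracy.

    A truth sequence lacking one class leaves the corresponding metric
    undefined (NaN, with a warning); accuracy is always defined.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    if pred.size == 0:
        raise ValueError("empty label sequences")
    for arr, name in ((pred, "predicted"), (true, "truth")):
        bad = set(arr) - {PREVENTIVE, OPERATIVE}
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    tp = int(((pred == OPERATIVE) & (true == OPERATIVE)).sum())
    fn = int(((pred == PREVENTIVE) & (true == OPERATIVE)).sum())
    tn = int(((pred == PREVENTIVE) & (true == PREVENTIVE)).sum())
    fp = int(((pred == OPERATIVE) & (true == PREVENTIVE)).sum())
    if tp + fn == 0:
        warnings.warn("truth has no operative teeth; sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("truth has no preventive teeth; specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + fn + tn + fp)
    return ClassificationReport(tp, fn, tn, fp, sens, spec, acc)


def spearman_rho(x: Sequence, y: Sequence) -> float:
    """Tie-aware Spearman rank correlation (Pearson on midranks).

    Clinical severity labels C0/C1/C2 are accepted and coded 0/1/2.  A
    constant sequence leaves the correlation undefined (NaN, warned).
    """
    x = _as_ordinal(x)
    y = _as_ordinal(y)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant sequence; Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _as_ordinal(seq) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.dtype.kind in "UO":
        try:
            arr = np.array([DIAGNOSIS_RANK[str(v)] for v in arr], dtype=float)
        except KeyError as exc:
            raise ValueError(f"non-numeric value without ordinal coding: {exc}") from exc
    return arr.astype(float)


def class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-diagnosis n and mean (SD) of fd, pa, dd — the study-table layout."""
    if "diagnosis" not in table:
        raise ValueError("table lacks a diagnosis column")
    cols = [c for c in ("fd", "pa", "dd") if c in table]
    rows = []
    for diag, grp in table.groupby("diagnosis", sort=True):
        row: dict = {"diagnosis": diag, "n": len(grp)}
        for c in cols:
            row[f"{c}_mean"] = float(grp[c].mean())
            row[f"{c}_sd"] = float(grp[c].std(ddof=1)) if len(grp) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
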