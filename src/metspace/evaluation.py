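"""Benchmarking: confusion-matrix rates, from-scratch ROC/AUC, the
descriptor x classifier benchmark grid with row/column averages, and
score-distribution histograms.

AUC is computed as the Mann-Whitney statistic (ties counted 1/2), which
equals the trapezoidal area under the threshold-swept ROC curve; a
brute-force pair-counting oracle verifies this in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report-time only; internal math is full precision)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_rates(truth, predicted) -> dict:
    """tp/fn/tn/fp and percent sensitivity/specificity (1 = metabolite).

    Undefined ratios (empty class) are reported as None, not 0.
    """
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth/predicted length mismatch")
    tp = int(((t == 1) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    sens = 100.0 * tp / (tp + fn) if tp + fn else None
    spec = 100.0 * tn / (tn + fp) if tn + fp else None
    return {"tp": tp, "fn": fn, "tn": tn, "fp": fp, "sensitivity": sens, "specificity": spec}


def roc_auc(truth, scores) -> dict:
    """Mann-Whitney AUC (ties 1/2) plus the swept ROC curve points.

    Returns ``{"auc", "fpr", "tpr", "thresholds"}``; the trapezoidal area
    under (fpr, tpr) equals ``auc`` exactly.
    """
    y = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("truth/scores length mismatch")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    # midranks without scipy: average rank within tie groups
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # threshold sweep over unique scores, descending
    desc = np.argsort(-s, kind="mergesort")
    ys, ss = y[desc], s[desc]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    last_of_group = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tps[last_of_group] / n1]
    fpr = np.r_[0.0, fps[last_of_group] / n0]
    thresholds = np.r_[np.inf, ss[last_of_group]]
    return {"auc": float(auc), "fpr": fpr, "tpr": tpr, "thresholds": thresholds}


@dataclass
class BenchmarkTable:
    """Sensitivity/specificity/AUC percent per (descriptor, classifier) cell."""

    cells: dict = field(default_factory=dict)  # (descriptor, classifier) -> metric dict
    descriptors: list[str] = field(default_factory=list)
    classifiers: list[str] = field(default_factory=list)
    metrics = ("sensitivity", "specificity", "auc")

    def row_averages(self, from_rounded: bool = False) -> dict:
        """Per-descriptor averages over classifiers (unrounded cells by default)."""
        out = {}
        for d in self.descriptors:
            out[d] = {
                m: float(np.mean([self._val(d, c, m, from_rounded) for c in self.classifiers]))
                for m in self.metrics
            }
        return out

    def col_averages(self, from_rounded: bool = False) -> dict:
        out = {}
        for c in self.classifiers:
            out[c] = {
                m: float(np.mean([self._val(d, c, m, from_rounded) for d in self.descriptors]))
                for m in self.metrics
            }
        return out

    def _val(self, d, c, m, from_rounded):
        v = self.cells[(d, c)][m]
        return round_half_away(v, 2) if from_rounded else v

    def to_dataframe(self, ndigits: int | None = 2) -> pd.DataFrame:
        rows = []
        for d in self.descriptors:
            row = {"descriptor": d}
            for c in self.classifiers:
                for m in self.metrics:
                    v = self.cells[(d, c)][m]
                    row[f"{c}_{m}"] = round_half_away(v, ndigits) if ndigits is not None else v
            avg = self.row_averages()[d]
            for m in self.metrics:
                v = avg[m]
                row[f"avg_{m}"] = round_half_away(v, ndigits) if ndigits is not None else v
            rows.append(row)
        avg_row = {"descriptor": "Average"}
        col = self.col_averages()
        for c in self.classifiers:
            for m in self.metrics:
                v = col[c][m]
                avg_row[f"{c}_{m}"] = round_half_away(v, ndigits) if ndigits is not None else v
        grand = {
            m: float(np.mean([self.cells[(d, c)][m] for d in self.descriptors for c in self.classifiers]))
            for m in self.metrics
        }
        for m in self.metrics:
            v = grand[m]
            avg_row[f"avg_{m}"] = round_half_away(v, ndigits) if ndigits is not None else v
        rows.append(avg_row)
        return pd.DataFrame(rows)


def benchmark_grid(
    train_data: dict,
    test_data: dict,
    descriptors: list[str],
    classifiers: list[str],
    seed: int = 0,
    cv_k: int = 5,
    small_grids: bool = False,
    cutoff: float = 0.5,
) -> tuple[BenchmarkTable, dict]:
    """Tune, train and evaluate one model per (descriptor, classifier) cell.

    ``train_data`` / ``test_data`` map descriptor name -> (X, y) with
    y in {0, 1}; the same molecules underlie every descriptor view.
    Returns the benchmark table and the trained models per cell.
    """
    from . import models as M  # local import avoids a cycle

    table = BenchmarkTable(descriptors=list(descriptors), classifiers=list(classifiers))
    trained: dict = {}
    for d in descriptors:
        Xtr, ytr = train_data[d]
        Xte, yte = test_data[d]
        for c in classifiers:
            try:
                grid = M.default_grid(c, Xtr.shape[1], small=small_grids)
                spec = M.ModelSpec(classifier=c, descriptor=d)
                cv = M.cross_validate(Xtr, ytr, spec, grid, k=cv_k, seed=seed)
                spec = M.ModelSpec(classifier=c, descriptor=d, hyperparams=dict(cv.best_params))
                model = M.train(Xtr, ytr, spec, seed=seed)
                scores = M.metabolite_likeness(model, Xte)
            except Exception as exc:  # pragma: no cover - abort contract
                raise RuntimeError(f"benchmark cell ({d}, {c}) failed: {exc}") from exc
            pred = (scores >= cutoff).astype(int)
            rates = confusion_rates(yte, pred)
            table.cells[(d, c)] = {
                "sensitivity": rates["sensitivity"],
                "specificity": rates["specificity"],
                "auc": 100.0 * roc_auc(yte, scores)["auc"],
            }
            trained[(d, c)] = model
    return table, trained


@dataclass
class ScoreHistogram:
    set_name: str
    counts: np.ndarray
    edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def score_histogram(scores, set_name: str) -> ScoreHistogram:
    """Counts over ten width-0.1 bins on [0, 1]; the last bin is closed."""
    s = np.asarray(scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(s, bins=edges)
    return ScoreHistogram(set_name=set_name, counts=counts.astype(int), edges=edges)
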