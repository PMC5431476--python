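"""NPDR-vs-PDR severity classification with an RBF SVM.

Eyes with NPDR are the positive class and PDR the negative class.  A
leave-one-out protocol trains on all other eyes, with the regularization
parameter C and kernel width gamma chosen per fold by an inner
cross-validated grid search (ties break toward the smallest C, then the
smallest gamma, so runs are deterministic).  Performance is summarised
by sensitivity, specificity, accuracy and the Matthews correlation
coefficient computed from the pooled confusion counts:

    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The eight evaluated feature combinations all contain average area (1)
and average amount (2), optionally augmented with average distance (3),
altitude (4) and reflectivity (5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

POSITIVE = "NPDR"
NEGATIVE = "PDR"

COMBOS = [
    (1, 2),
    (1, 2, 3),
    (1, 2, 4),
    (1, 2, 5),
    (1, 2, 3, 4),
    (1, 2, 3, 5),
    (1, 2, 4, 5),
    (1, 2, 3, 4, 5),
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class MetricSet:
    """Sen/Spe/Acc as fractions in [0, 1]; MCC in [-1, 1]."""

    sen: float
    spe: float
    acc: float
    mcc: float
    mcc_degenerate: bool = False

    def as_percent(self) -> dict:
        return {
            "sen": 100.0 * self.sen,
            "spe": 100.0 * self.spe,
            "acc": 100.0 * self.acc,
            "mcc": 100.0 * self.mcc,
        }


@dataclass
class SvmConfig:
    c_grid: tuple = tuple(2.0 ** e for e in range(-8, 9, 2))
    g_grid: tuple = tuple(2.0 ** e for e in range(-8, 9, 2))
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if not self.c_grid or not self.g_grid:
            raise ValueError("grids must be nonempty")
        if min(self.c_grid) <= 0 or min(self.g_grid) <= 0:
            raise ValueError("grid values must be positive")


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    A zero factor in the MCC denominator makes MCC undefined; it is
    reported as 0 with ``mcc_degenerate=True``.
    """
    total = c.tp + c.fp + c.tn + c.fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / total
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        warnings.warn("MCC denominator has a zero factor; reporting MCC = 0")
        return MetricSet(sen, spe, acc, 0.0, mcc_degenerate=True)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(sen, spe, acc, mcc)


def enumerate_combos():
    """The eight feature index sets, each containing area (1) and amount (2)."""
    return [tuple(c) for c in COMBOS]


def _grid_search(X: np.ndarray, y: np.ndarray, cfg: SvmConfig):
    """Best (C, gamma) by inner stratified-CV accuracy; first (smallest) wins ties."""
    if len(cfg.c_grid) == 1 and len(cfg.g_grid) == 1:
        return cfg.c_grid[0], cfg.g_grid[0]
    classes, counts = np.unique(y, return_counts=True)
    k = int(min(cfg.inner_folds, counts.min()))
    if k >= 2:
        skf = StratifiedKFold(n_splits=k, shuffle=False)
        splits = list(skf.split(X, y))
    else:
        splits = None
    best = (-1.0, None, None)
    for c in sorted(cfg.c_grid):
        for g in sorted(cfg.g_grid):
            if splits is None:
                acc = 0.0  # no usable inner split: any (c, g) ties, first wins
            else:
                correct = 0
                for tr, te in splits:
                    clf = SVC(C=c, gamma=g, kernel="rbf")
                    clf.fit(X[tr], y[tr])
                    correct += int((clf.predict(X[te]) == y[te]).sum())
                acc = correct / len(y)
            if acc > best[0]:
                best = (acc, c, g)
    return best[1], best[2]


def loo_evaluate(X, y, combo, cfg: SvmConfig | None = None):
    """Leave-one-out evaluation of one feature combination.

    ``X`` is the normalized (n_eyes x 5) feature matrix, ``y`` labels in
    {"NPDR", "PDR"}; ``combo`` holds 1-based feature indices.  Returns
    ``(ConfusionCounts, MetricSet)`` with NPDR counted positive.
    """
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("feature matrix and labels are inconsistent")
    for cls in (POSITIVE, NEGATIVE):
        if (y == cls).sum() < 2:
            raise ValueError(f"need >= 2 eyes per class; class {cls} too small")
    cols = [i - 1 for i in combo]
    Xc = X[:, cols]
    tp = fp = tn = fn = 0
    for i in range(len(y)):
        tr = np.arange(len(y)) != i
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training fold")
        c, g = _grid_search(Xc[tr], y[tr], cfg)
        clf = SVC(C=c, gamma=g, kernel="rbf")
        clf.fit(Xc[tr], y[tr])
        pred = clf.predict(Xc[i : i + 1])[0]
        if y[i] == POSITIVE:
            tp += int(pred == POSITIVE)
            fn += int(pred != POSITIVE)
        else:
            tn += int(pred == NEGATIVE)
            fp += int(pred != NEGATIVE)
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts, compute_metrics(counts)


def severity_report(feature_tables: dict, cfg: SvmConfig | None = None):
    """Metrics for all 8 combinations over each lesion group.

    ``feature_tables`` maps a group name (e.g. "HEs", "HRF_excl_HE",
    "HRF_incl_HE") to ``(X_normalized, labels)``.  Returns a pandas
    DataFrame with one row per (combo, group), metrics as percentages.
    """
    import pandas as pd

    rows = []
    for combo in enumerate_combos():
        for group, (X, y) in feature_tables.items():
            _, metrics = loo_evaluate(X, y, combo, cfg)
            pct = metrics.as_percent()
            rows.append(
                {
                    "combo": ", ".join(str(i) for i in combo),
                    "group": group,
                    "sen_pct": round(pct["sen"], 2),
                    "spe_pct": round(pct["spe"], 2),
                    "acc_pct": round(pct["acc"], 2),
                    "mcc_pct": round(pct["mcc"], 2),
                }
            )
    return pd.DataFrame(rows)


def format_report(df) -> str:
    """Fixed-width text rendering of a severity report."""
    lines = [f"{'combo':<14}{'group':<14}{'Sen':>8}{'Spe':>8}{'Acc':>8}{'MCC':>8}"]
    for _, r in df.iterrows():
        lines.append(
            f"{r['combo']:<14}{r['group']:<14}"
            f"{r['sen_pct']:>8.2f}{r['spe_pct']:>8.2f}{r['acc_pct']:>8.2f}{r['mcc_pct']:>8.2f}"
        )
    return "\n".join(lines)
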