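"""Confusion-matrix metrics, ROC/AUC, threshold selection, the SAD baseline,
and the stratified repeated-CV harness.

AUC is computed two independent ways — trapezoidal integration of the ROC
polygon and the tie-corrected Mann–Whitney pair statistic — and the two are
required to agree to 1e-12, which holds exactly for the standard ROC
construction over all distinct score thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, specificity, sensitivity, precision, F1.

    A metric whose denominator is zero is ``None`` (flagged undefined rather
    than silently 0).
    """

    accuracy: float | None
    specificity: float | None
    sensitivity: float | None
    precision: float | None
    f1: float | None


def metrics_from_cm(cm: ConfusionMatrix) -> MetricSet:
    """The five standard diagnostic metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den):
        return num / den if den > 0 else None

    acc = _ratio(cm.tp + cm.tn, cm.total)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if prec is not None and sens is not None and (prec + sens) > 0
        else None
    )
    return MetricSet(acc, spec, sens, prec, f1)


def confusion_from_predictions(predicted, actual) -> ConfusionMatrix:
    p = np.asarray(predicted, bool)
    a = np.asarray(actual, bool)
    return ConfusionMatrix(
        tp=int((p & a).sum()),
        tn=int((~p & ~a).sum()),
        fp=int((p & ~a).sum()),
        fn=int((~p & a).sum()),
    )


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the tie-corrected Mann–Whitney statistic.

    (#concordant pairs + 0.5 #tied pairs) / (n_pos * n_neg), computed from
    midranks; the independent cross-check route for the trapezoidal AUC.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_and_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points over all distinct thresholds and the trapezoidal AUC.

    Returns an (m, 2) array of (fpr, tpr) from (0,0) to (1,1) and the AUC.
    The trapezoid value is asserted against the Mann–Whitney pair statistic
    to 1e-12 before being returned.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    if y.all() or (~y).all():
        raise ValueError("both classes required for ROC")
    fpr, tpr, _ = roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    mw = auc_mann_whitney(s, y)
    if abs(auc - mw) > 1e-12:  # pragma: no cover - structural identity
        raise AssertionError(f"trapezoid AUC {auc} != Mann-Whitney AUC {mw}")
    return np.column_stack([fpr, tpr]), auc


def grouped_roc_auc(neg_counts, pos_counts) -> float:
    """AUC of an ordinal grouped score (counts per ordered category).

    Used for the radiologist's LN-RADS level itself as a malignancy score:
    expand the per-level benign/malignant counts into scores 0..5 and apply
    :func:`roc_and_auc`.
    """
    neg = np.asarray(neg_counts, int)
    pos = np.asarray(pos_counts, int)
    scores = np.concatenate(
        [np.full(c, i, float) for i, c in enumerate(neg)]
        + [np.full(c, i, float) for i, c in enumerate(pos)]
    )
    labels = np.concatenate([np.zeros(neg.sum(), bool), np.ones(pos.sum(), bool)])
    return roc_and_auc(scores, labels)[1]


def select_threshold(scores, labels) -> float:
    """Threshold maximising Youden J = TPR - FPR on the given split.

    Candidates are midpoints between consecutive distinct sorted scores plus
    sentinels below and above every score; ties in J are broken toward the
    smallest threshold (the higher-sensitivity operating point).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    if y.all() or (~y).all():
        raise ValueError("both classes required for threshold selection")
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    n_pos, n_neg = y.sum(), (~y).sum()
    # predicted positive iff score > threshold
    tpr = (s[y][:, None] > candidates).sum(axis=0) / n_pos
    fpr = (s[~y][:, None] > candidates).sum(axis=0) / n_neg
    j = tpr - fpr
    return float(candidates[np.argmax(j)])  # argmax takes the first (smallest)


def sad_classify(sad_mm, threshold_mm: float = 10.0):
    """The classical size rule: malignant iff SAD strictly exceeds the cut-off.

    A node at exactly the cut-off is benign ("greater than 10 mm" read as a
    strict inequality).
    """
    sad = np.asarray(sad_mm, float)
    if (sad <= 0).any():
        raise ValueError("SAD must be positive")
    out = sad > threshold_mm
    return bool(out) if np.isscalar(sad_mm) else out


@dataclass(frozen=True)
class CVPlan:
    """Stratified k-fold x repeats assignments: fold index per record."""

    k: int
    repeats: int
    assignments: np.ndarray  # (repeats, n) fold indices
    seed: int

    def split(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        mask = self.assignments[repeat] == fold
        idx = np.arange(self.assignments.shape[1])
        return idx[~mask], idx[mask]

    def iter_splits(self):
        for r in range(self.repeats):
            for f in range(self.k):
                yield r, f, *self.split(r, f)


def make_cv_plan(labels, k: int = 5, repeats: int = 10, seed: int = 0) -> CVPlan:
    """Class-stratified k-fold partition, repeated with fresh shuffles.

    Per-fold positive counts differ by at most 1 from perfect stratification
    (the stratified splitter's guarantee).  Reproducible from ``seed``.
    """
    y = np.asarray(labels, bool).astype(int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(np.bincount(y, minlength=2)) < k:
        raise ValueError(f"need at least k={k} members of each class")
    n = len(y)
    assignments = np.empty((repeats, n), dtype=int)
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seeds[r]))
        for f, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y)):
            assignments[r, test_idx] = f
    return CVPlan(k=k, repeats=repeats, assignments=assignments, seed=seed)


def aggregate_runs(per_run: list[dict]) -> tuple[dict, dict]:
    """Mean and standard deviation of per-run scalar metrics.

    ``per_run`` is a list of dicts of scalars or equal-length sequences
    (curves); sequences are averaged elementwise.
    """
    if not per_run:
        raise ValueError("no runs to aggregate")
    keys = per_run[0].keys()
    means, stds = {}, {}
    for key in keys:
        vals = [np.asarray(run[key], float) for run in per_run]
        if len({v.shape for v in vals}) != 1:
            raise ValueError(f"mismatched curve lengths for {key!r}")
        stacked = np.stack(vals)
        m, s = stacked.mean(axis=0), stacked.std(axis=0)
        means[key] = float(m) if m.ndim == 0 else m
        stds[key] = float(s) if s.ndim == 0 else s
    return means, stds


def report_table(rows: list[dict]) -> pd.DataFrame:
    """Report mirroring the published comparison-table columns, plus AUC."""
    cols = ["Model", "Accuracy", "Specificity", "Sensitivity", "Precision", "F1", "AUC"]
    return pd.DataFrame(rows, columns=cols)
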