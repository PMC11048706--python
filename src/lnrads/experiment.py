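"""End-to-end experiment: the four head variants vs the SAD baseline.

Runs the full comparison on a synthetic cohort: stratified k-fold CV
repeated R times; per split, each variant's head is trained under the SGD
protocol, the decision threshold is selected on the training folds, and the
test-fold confusion metrics and AUC are recorded; per-variant results are
averaged over all k x R runs and reported next to the 10 mm / 8 mm SAD
baseline rows.

The default "fast" path draws 10-d feature vectors directly from the
generator (no images, no backbone), which exercises the complete
head/training/evaluation stack in seconds; image mode renders speckle
phantoms and extracts features with the frozen CNN backbone first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from .cohort import GeneratorConfig, features_from_records, sample_cohort
from .metrics import (
    confusion_from_predictions,
    grouped_roc_auc,
    make_cv_plan,
    metrics_from_cm,
    report_table,
    roc_and_auc,
    sad_classify,
    ConfusionMatrix,
    aggregate_runs,
)
from .model import HeadSpec
from .train import TrainConfig, train

logger = logging.getLogger(__name__)

#: The four variants, named as in the published comparison table.
VARIANT_LABELS = {
    "1a_hist_narrow": ("binary_narrow", "1a Histopathology Narrow"),
    "1b_hist_wide": ("binary_wide", "1b Histopathology Wide"),
    "2_lnrads_multinomial_false": ("lnrads_fc", "2 LNRADS Cut (Multinomial = False)"),
    "2_lnrads_multinomial_true": ("lnrads_mlr", "2 LNRADS Cut (Multinomial = True)"),
}

#: Published baseline confusion counts of the 10 mm SAD rule (real cohort).
BASELINE_CM = ConfusionMatrix(tp=138, tn=147, fp=25, fn=88)


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(n=2000))
    variants: tuple = tuple(VARIANT_LABELS)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv_k: int = 5
    cv_repeats: int = 10
    baseline_thresholds_mm: tuple = (10.0, 8.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        if "train" in raw:
            kwargs["train"] = TrainConfig(**raw["train"])
        for key in ("variants", "cv_k", "cv_repeats", "baseline_thresholds_mm", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def run_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full comparison; returns the report table and per-variant curves.

    The report has one row per trained variant (metrics averaged over the
    k x repeats runs) plus one row per SAD baseline threshold.  Curves are
    the per-epoch test ACC/AUC trajectories averaged over runs.
    """
    gen = replace(config.generator, seed=config.seed)
    records = sample_cohort(gen)
    X = features_from_records(records, seed=config.seed)
    y = np.array([r.malignant for r in records])
    levels = [r.lnrads for r in records]
    sad = np.array([r.sad_mm for r in records])

    plan = make_cv_plan(y, k=config.cv_k, repeats=config.cv_repeats, seed=config.seed)
    rows, all_curves = [], {}
    for name in config.variants:
        variant, label = VARIANT_LABELS[name]
        spec = HeadSpec(variant)
        runs = []
        for r, f, tr_idx, te_idx in plan.iter_splits():
            run_seed = (config.train.seed + 7919 * (r * config.cv_k + f)) % (2**31)
            cfg = replace(config.train, seed=run_seed)
            head, curves, _ = train(
                spec, X[tr_idx], y[tr_idx], cfg,
                levels_train=[levels[i] for i in tr_idx],
                X_eval=X[te_idx], malignant_eval=y[te_idx],
            )
            cm = confusion_from_predictions(head.predict(X[te_idx]), y[te_idx])
            ms = metrics_from_cm(cm)
            _, auc = roc_and_auc(head.scores(X[te_idx]), y[te_idx])
            runs.append(
                {
                    "Accuracy": ms.accuracy, "Specificity": ms.specificity,
                    "Sensitivity": ms.sensitivity, "Precision": ms.precision,
                    "F1": ms.f1, "AUC": auc,
                    "acc_curve": curves.acc, "auc_curve": curves.auc,
                }
            )
            logger.info("%s repeat=%d fold=%d acc=%.3f auc=%.3f",
                        name, r, f, ms.accuracy, auc)
        means, _ = aggregate_runs(runs)
        all_curves[name] = {"acc": means.pop("acc_curve"), "auc": means.pop("auc_curve")}
        rows.append({"Model": label, **{k: means[k] for k in
                     ("Accuracy", "Specificity", "Sensitivity", "Precision", "F1", "AUC")}})

    _, sad_auc = roc_and_auc(sad, y)
    for thr in config.baseline_thresholds_mm:
        cm = confusion_from_predictions(sad_classify(sad, thr), y)
        ms = metrics_from_cm(cm)
        rows.append(
            {
                "Model": f"{thr:g} mm SAD threshold",
                "Accuracy": ms.accuracy, "Specificity": ms.specificity,
                "Sensitivity": ms.sensitivity, "Precision": ms.precision,
                "F1": ms.f1, "AUC": sad_auc,
            }
        )
    return report_table(rows), all_curves


def reproduce_baseline() -> dict:
    """Recompute the published 10 mm SAD baseline row from its confusion counts.

    Inputs are the printed counts themselves (TN=147, TP=138, FN=88, FP=25)
    plus the published per-level benign/malignant counts for the grouped
    ordinal AUC of the radiologist's LN-RADS score.
    """
    ms = metrics_from_cm(BASELINE_CM)
    neg = (_cohort.LEVEL_COUNTS - _cohort.MALIGNANT_COUNTS).astype(int)
    pos = _cohort.MALIGNANT_COUNTS.astype(int)
    return {
        "total": BASELINE_CM.total,
        "accuracy": ms.accuracy,
        "specificity": ms.specificity,
        "sensitivity": ms.sensitivity,
        "precision": ms.precision,
        "f1": ms.f1,
        "lnrads_grouped_auc": grouped_roc_auc(neg, pos),
    }


def sad_baseline_on_cohort(records, threshold_mm: float = 10.0) -> dict:
    """Operating point of the SAD rule on a (synthetic) cohort."""
    sad = np.array([r.sad_mm for r in records])
    y = np.array([r.malignant for r in records])
    cm = confusion_from_predictions(sad_classify(sad, threshold_mm), y)
    ms = metrics_from_cm(cm)
    _, auc = roc_and_auc(sad, y)
    return {"tpr": ms.sensitivity, "fpr": 1 - ms.specificity,
            "accuracy": ms.accuracy, "auc": auc}
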