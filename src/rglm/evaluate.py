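"""Evaluation protocol: repeated k-fold cross-validation and binary metrics.

The headline protocol is 3-fold cross-validation averaged over many random
partitions of the data.  Binary outcomes are stratified so every fold holds
both classes whenever possible; accuracy is 1 minus the misclassification
rate, with class 1 treated as positive for sensitivity/specificity.
Continuous outcomes report the Pearson correlation between predictions and
observed values per held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .ensemble import EnsembleConfig, predict, train_rglm
from .glm import Family

__all__ = ["EvalReport", "binary_metrics", "repeated_kfold"]


@dataclass
class EvalReport:
    fold_accuracies: "list[float]"        # one entry per (repeat, fold)
    mean_accuracy: float
    median_accuracy: float
    sensitivity: float                    # NaN for continuous outcomes
    specificity: float
    n_repeats: int
    k: int


def binary_metrics(pred_class: np.ndarray, truth: np.ndarray):
    """(accuracy, sensitivity, specificity) with class 1 positive.

    When the truth contains a single class the undefined rate is NaN.
    """
    pred = np.asarray(pred_class)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth lengths differ")
    acc = float(np.mean(pred == truth))
    pos = truth == 1
    neg = truth == 0
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    spec = float(np.mean(pred[neg] == 0)) if neg.any() else float("nan")
    return acc, sens, spec


def repeated_kfold(
    X: np.ndarray,
    y: np.ndarray,
    config: "EnsembleConfig | None" = None,
    k: int = 3,
    n_repeats: int = 100,
    rng: "np.random.Generator | int | None" = None,
) -> EvalReport:
    """Mean/median k-fold CV accuracy over ``n_repeats`` random partitions.

    Every repeat draws a fresh partition; the ensemble is retrained on each
    training split with a seed derived from ``rng`` so the whole evaluation
    is reproducible.  Repeats whose training split loses a class entirely are
    skipped.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or EnsembleConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    binary = config.family is Family.BINOMIAL

    accs: list[float] = []
    tp = fn = tn = fp = 0
    for _rep in range(n_repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        splitter = (StratifiedKFold if binary else KFold)(
            n_splits=k, shuffle=True, random_state=split_seed
        )
        for train_idx, test_idx in splitter.split(X, y if binary else None):
            y_tr = y[train_idx]
            if binary and np.unique(y_tr).size < 2:
                continue
            cfg = EnsembleConfig(
                n_bags=config.n_bags,
                n_features_in_bag=config.n_features_in_bag,
                n_candidate_covariates=config.n_candidate_covariates,
                max_interaction_order=config.max_interaction_order,
                family=config.family,
                classify_threshold=config.classify_threshold,
                seed=int(rng.integers(0, 2**31 - 1)),
                interaction_self_products=config.interaction_self_products,
            )
            model = train_rglm(X[train_idx], y_tr, cfg)
            if binary:
                cls = predict(model, X[test_idx], output="class")
                accs.append(float(np.mean(cls == y[test_idx])))
                yt = y[test_idx]
                tp += int(np.sum((cls == 1) & (yt == 1)))
                fn += int(np.sum((cls == 0) & (yt == 1)))
                tn += int(np.sum((cls == 0) & (yt == 0)))
                fp += int(np.sum((cls == 1) & (yt == 0)))
            else:
                pred = predict(model, X[test_idx], output="response")
                yt = y[test_idx]
                if pred.std() == 0 or yt.std() == 0:
                    accs.append(float("nan"))
                else:
                    accs.append(float(np.corrcoef(pred, yt)[0, 1]))
    accs_arr = np.asarray(accs, dtype=float)
    sens = tp / (tp + fn) if binary and (tp + fn) else float("nan")
    spec = tn / (tn + fp) if binary and (tn + fp) else float("nan")
    return EvalReport(
        fold_accuracies=accs,
        mean_accuracy=float(np.nanmean(accs_arr)) if accs else float("nan"),
        median_accuracy=float(np.nanmedian(accs_arr)) if accs else float("nan"),
        sensitivity=float(sens),
        specificity=float(spec),
        n_repeats=n_repeats,
        k=k,
    )
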