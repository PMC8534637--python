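"""Confusion-matrix metrics and the grouped nested cross-validation harness.

Metrics follow the usual binary definitions with *fresh* as the positive
class: Acc = (TP+TN)/(TP+FN+FP+TN), Pre = TP/(TP+FP), Sen = TP/(TP+FN),
Spe = TN/(TN+FP). A metric whose denominator is zero is reported as
``None`` (undefined) and excluded from cross-fold averages with a warning.

The cross-validation plan is grouped by acquisition batch (purchase day):
with G groups there are G outer folds, each holding one group out as the
test set; within each outer fold the remaining G-1 groups rotate as the
validation set of G-1 inner folds. Hyperparameters are chosen by mean inner
validation accuracy (ties broken by grid order), the winning configuration
is refit on the whole outer training set, and the headline result is the
arithmetic mean of the per-fold test metrics; pooled metrics over all test
predictions are reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataio import POSITIVE_LABEL, SpectraDataset
from .errors import FoldError

logger = logging.getLogger(__name__)

#: large prime stride separating per-fold seeds derived from the base seed
_SEED_STRIDE = 9973
_SEED_MOD = 2**31


def fold_seed(base_seed: int, outer_idx: int, inner_idx: int = -1) -> int:
    """Deterministic per-fold seed: the global seed offset by fold indices."""
    return (base_seed + _SEED_STRIDE * (outer_idx + 1) + 131 * (inner_idx + 1)) % _SEED_MOD


# ---------------------------------------------------------------------------
# confusion counts and derived metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )

    def to_dict(self) -> dict:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


@dataclass
class MetricSet:
    """Accuracy, precision, sensitivity, specificity as fractions in [0, 1];
    ``None`` marks a metric whose denominator was zero."""

    acc: float | None
    pre: float | None
    sen: float | None
    spe: float | None

    def to_dict(self, percent: bool = False) -> dict:
        f = (lambda v: None if v is None else 100.0 * v) if percent else (lambda v: v)
        return {"acc": f(self.acc), "pre": f(self.pre), "sen": f(self.sen), "spe": f(self.spe)}


def confusion(
    y_true: Sequence, y_pred: Sequence, positive_label=POSITIVE_LABEL
) -> ConfusionCounts:
    """Count TP/TN/FP/FN with the given positive class.

    True/predicted labels must come from the same binary label set; an
    unseen value raises ``ValueError``.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    values = set(np.unique(yt)) | set(np.unique(yp))
    if positive_label not in values and len(values) > 1:
        raise ValueError(f"positive label {positive_label!r} absent from labels {values}")
    if len(values - {positive_label}) > 1:
        raise ValueError(f"labels are not binary: {sorted(map(str, values))}")
    pos_t = yt == positive_label
    pos_p = yp == positive_label
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """Derive Acc/Pre/Sen/Spe from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return MetricSet(
        acc=_ratio(c.TP + c.TN, c.total),
        pre=_ratio(c.TP, c.TP + c.FP),
        sen=_ratio(c.TP, c.TP + c.FN),
        spe=_ratio(c.TN, c.TN + c.FP),
    )


def mean_metrics(sets: Sequence[MetricSet]) -> MetricSet:
    """Arithmetic mean of per-fold metrics; undefined entries are dropped
    from their metric's average with a warning."""
    out = {}
    for name in ("acc", "pre", "sen", "spe"):
        vals = [getattr(s, name) for s in sets]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            warnings.warn(
                f"{len(vals) - len(defined)} fold(s) had undefined {name}; "
                "excluded from the average",
                stacklevel=2,
            )
        out[name] = float(np.mean(defined)) if defined else None
    return MetricSet(**out)


# ---------------------------------------------------------------------------
# nested cross-validation plan
# ---------------------------------------------------------------------------


@dataclass
class InnerFold:
    val_group: str
    fit_groups: tuple


@dataclass
class OuterFold:
    test_group: str
    train_groups: tuple
    inner: list  # list[InnerFold]


@dataclass
class NestedCVPlan:
    groups: tuple
    outer: list  # list[OuterFold]


def make_plan(groups: Sequence) -> NestedCVPlan:
    """Build the grouped nested-CV plan from per-sample group labels.

    For G distinct groups: G outer folds (each group is the test set exactly
    once); inside each outer fold the G-1 training groups rotate as the
    validation group of G-1 inner folds. Fit, validation and test groups are
    pairwise disjoint by construction.
    """
    uniq = tuple(sorted(set(map(str, groups))))
    if len(uniq) < 3:
        raise ValueError(f"nested CV needs >= 3 distinct groups, got {len(uniq)}")
    outer = []
    for test in uniq:
        train = tuple(g for g in uniq if g != test)
        inner = [
            InnerFold(val_group=v, fit_groups=tuple(g for g in train if g != v))
            for v in train
        ]
        outer.append(OuterFold(test_group=test, train_groups=train, inner=inner))
    return NestedCVPlan(groups=uniq, outer=outer)


# ---------------------------------------------------------------------------
# nested cross-validation driver
# ---------------------------------------------------------------------------


@dataclass
class OuterFoldResult:
    test_group: str
    chosen_params: dict
    counts: ConfusionCounts
    metrics: MetricSet
    n_test: int
    inner_mean_accuracy: dict | None = None  # repr(params) -> mean val acc

    def to_dict(self) -> dict:
        return {
            "test_group": self.test_group,
            "chosen_params": self.chosen_params,
            "counts": self.counts.to_dict(),
            "metrics": self.metrics.to_dict(percent=True),
            "n_test": self.n_test,
        }


@dataclass
class NestedCVResult:
    folds: list  # list[OuterFoldResult]
    mean: MetricSet
    pooled: MetricSet
    pooled_counts: ConfusionCounts
    seed: int = 0

    @property
    def accuracy(self) -> float:
        return self.mean.acc

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "folds": [f.to_dict() for f in self.folds],
            "mean_metrics_percent": self.mean.to_dict(percent=True),
            "pooled_metrics_percent": self.pooled.to_dict(percent=True),
            "pooled_counts": self.pooled_counts.to_dict(),
        }


def _check_two_classes(y: np.ndarray, context: str) -> None:
    if len(np.unique(y)) < 2:
        raise FoldError(
            f"{context} contains a single class; the fold is unusable "
            f"(labels seen: {sorted(map(str, np.unique(y)))})"
        )


def nested_cv(
    dataset: SpectraDataset,
    model_factory: Callable[[dict, int], object],
    hyperparameter_grid: Sequence[dict],
    train_fn: Callable[[object, np.ndarray, np.ndarray], object] | None = None,
    predict_fn: Callable[[object, np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> NestedCVResult:
    """Run grouped nested cross-validation of one model family.

    ``model_factory(params, seed)`` must return a fresh estimator;
    ``train_fn`` defaults to ``est.fit(X, y)`` and ``predict_fn`` to
    ``est.predict(X)``; labels are the integer coding (fresh = 1). Inner
    selection maximizes mean validation accuracy; ties are broken by grid
    order. A grid with a single configuration short-circuits the inner
    evaluation (the selection is forced and the result is identical to
    plain grouped CV of that configuration). Per-fold model fits use the
    global seed offset deterministically by the fold indices.
    """
    grid = list(hyperparameter_grid)
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    train_fn = train_fn or (lambda est, X, y: est.fit(X, y) or est)
    predict_fn = predict_fn or (lambda est, X: est.predict(X))

    groups = np.asarray(dataset.day, dtype=object)
    X, y = dataset.X, dataset.y()
    plan = make_plan(groups)

    fold_results: list[OuterFoldResult] = []
    for o_idx, fold in enumerate(plan.outer):
        test_mask = groups == fold.test_group
        train_mask = ~test_mask
        _check_two_classes(y[train_mask], f"outer training set (test={fold.test_group})")

        if len(grid) == 1:
            best_params, inner_acc = grid[0], None
        else:
            mean_accs = []
            for params in grid:
                accs = []
                for i_idx, ifold in enumerate(fold.inner):
                    val_mask = groups == ifold.val_group
                    fit_mask = train_mask & ~val_mask
                    _check_two_classes(
                        y[fit_mask],
                        f"inner fit set (test={fold.test_group}, val={ifold.val_group})",
                    )
                    est = model_factory(params, fold_seed(seed, o_idx, i_idx))
                    est = train_fn(est, X[fit_mask], y[fit_mask])
                    pred = np.asarray(predict_fn(est, X[val_mask]))
                    accs.append(float(np.mean(pred == y[val_mask])))
                mean_accs.append(float(np.mean(accs)))
            best_idx = int(np.argmax(mean_accs))  # first-in-grid wins ties
            best_params = grid[best_idx]
            inner_acc = {repr(p): a for p, a in zip(grid, mean_accs)}
            logger.info(
                "outer fold %s: chose %s (inner val acc %.4f)",
                fold.test_group,
                best_params,
                mean_accs[best_idx],
            )

        est = model_factory(best_params, fold_seed(seed, o_idx))
        est = train_fn(est, X[train_mask], y[train_mask])
        pred = np.asarray(predict_fn(est, X[test_mask]))
        counts = confusion(y[test_mask], pred, positive_label=1)
        fold_results.append(
            OuterFoldResult(
                test_group=fold.test_group,
                chosen_params=dict(best_params),
                counts=counts,
                metrics=metrics(counts),
                n_test=int(test_mask.sum()),
                inner_mean_accuracy=inner_acc,
            )
        )

    pooled_counts = fold_results[0].counts
    for r in fold_results[1:]:
        pooled_counts = pooled_counts + r.counts
    return NestedCVResult(
        folds=fold_results,
        mean=mean_metrics([r.metrics for r in fold_results]),
        pooled=metrics(pooled_counts),
        pooled_counts=pooled_counts,
        seed=seed,
    )
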