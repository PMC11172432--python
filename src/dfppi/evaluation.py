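"""Evaluation protocols for pair-interaction classifiers.

Threshold metrics (accuracy, sensitivity, specificity, precision, NPV, F1,
MCC) are computed from exact confusion counts; ranking metrics (AUROC,
AUPRC) via scikit-learn (midrank tie handling for AUROC, step integration
for the precision-recall curve).  Higher-level protocols: stratified k-fold
cross-validation with per-fold mean±SD, the positive-only
threshold-accuracy AUC used for cross-species transfer tests, F1-based
threshold selection on a holdout split, and network edge reconstruction
counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .embedding import EmbeddingMatrix
from .io import PairExample, ProteinRecord, mean_sequence_length
from .model import DFPPI, DFPPIResults, FeatureStore
from .network import ModelConfig, TrainConfig


@dataclass(frozen=True)
class ConfusionCounts:
    """Exact binary confusion counts; P = TP+FN positives, N = TN+FP negatives."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """The standard binary-classification panel; AUCs are None for
    threshold-only evaluation."""

    acc: float
    sen: float
    spe: float
    pre: float
    npv: float
    f1: float
    mcc: float
    auroc: float | None = None
    auprc: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }


@dataclass(frozen=True)
class CVResult:
    """Per-fold metric reports plus their mean and sample standard deviation."""

    folds: tuple[MetricsReport, ...]
    mean: dict[str, float]
    sd: dict[str, float]


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Count TP/FN/TN/FP from 0/1 labels and 0/1 predictions."""
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {yhat.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(yhat, (0, 1)).all()):
        raise ValueError("labels and predictions must be 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from confusion counts; zero denominators give 0
    with a warning so fold aggregation stays total."""
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    mcc_den = np.sqrt(
        float(counts.p) * counts.n * (tp + fp) * (tn + fn)
    )
    return MetricsReport(
        acc=_ratio(tp + tn, counts.p + counts.n, "accuracy"),
        sen=_ratio(tp, counts.p, "sensitivity"),
        spe=_ratio(tn, counts.n, "specificity"),
        pre=_ratio(tp, tp + fp, "precision"),
        npv=_ratio(tn, tn + fn, "NPV"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        mcc=_ratio(tp * tn - fp * fn, mcc_den, "MCC"),
    )


def ranking_aucs(labels: Sequence[int], probabilities: Sequence[float]) -> tuple[float, float]:
    """(AUROC, AUPRC) of interaction probabilities against 0/1 labels."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ranking metrics require both classes present")
    return float(roc_auc_score(y, p)), float(average_precision_score(y, p))


def full_report(labels, predictions, probabilities) -> MetricsReport:
    """Threshold metrics plus AUCs in one report."""
    base = metrics(confusion(labels, predictions))
    auroc, auprc = ranking_aucs(labels, probabilities)
    return MetricsReport(**{**base.as_dict(), "auroc": auroc, "auprc": auprc})


def cross_validate(
    pairs: Sequence[PairExample],
    records: Sequence[ProteinRecord],
    k: int = 5,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    embeddings: "EmbeddingMatrix | None" = None,
    embedding_factory: Callable[[Sequence[ProteinRecord]], object] | None = None,
    threshold: float = 0.5,
    feature_store: "FeatureStore | None" = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the fusion model.

    Folds are class-balanced and reproducible from ``seed``.  For each fold
    a fresh model is built on the training pairs (feature scaling fitted on
    training proteins only) and evaluated on the held-out pairs.  A fixed
    ``embeddings`` matrix (pre-trained on a corpus disjoint from the pair
    data) may be supplied, or ``embedding_factory`` may be given to train
    embeddings inside each fold from the training-fold records.  A shared
    ``feature_store`` avoids recomputing descriptor vectors per fold; when
    absent one is built over all records with the token length N taken as
    the floor of the mean sequence length (sequence length carries no label
    information).
    """
    labels = np.array([p.label for p in pairs])
    if any(l is None for l in labels):
        raise ValueError("cross-validation requires labeled pairs")
    counts = np.bincount(labels, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count {counts.min()}")

    if feature_store is None:
        cfg = model_config or ModelConfig()
        n = cfg.fixed_length or mean_sequence_length(list(records))
        feature_store = FeatureStore(records, n)

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    pairs = list(pairs)
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(pairs)), labels)):
        train_pairs = [pairs[i] for i in tr]
        test_pairs = [pairs[i] for i in te]
        model = DFPPI(
            train_pairs, records, config=model_config, embeddings=embeddings,
            feature_store=feature_store,
        )
        if embedding_factory is not None:
            model = DFPPI(
                train_pairs, records, config=model_config,
                embeddings=embedding_factory(model.train_records),
                feature_store=feature_store,
            )
        results = model.fit(train_config)
        yhat, probs = results.predict(test_pairs, threshold)
        reports.append(full_report(labels[te], yhat, probs))

    keys = reports[0].as_dict().keys()
    mean = {m: float(np.mean([getattr(r, m) for r in reports])) for m in keys}
    sd = {m: float(np.std([getattr(r, m) for r in reports], ddof=1)) for m in keys}
    return CVResult(tuple(reports), mean, sd)


def threshold_accuracy_auc(
    probabilities: Sequence[float], grid_points: int = 1001
) -> float:
    """Area under the accuracy-versus-threshold curve for a positive-only set.

    Accuracy at threshold t is the fraction of probabilities >= t; the curve
    is integrated by the trapezoid rule on a uniform grid over [0, 1].  A
    confident model (all probabilities near 1) scores near 1; uniformly
    spread probabilities score near 0.5.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("threshold-accuracy AUC requires a non-empty probability set")
    grid = np.linspace(0.0, 1.0, grid_points)
    acc = (p[None, :] >= grid[:, None]).mean(axis=1)
    return float(np.trapezoid(acc, grid))


def select_threshold(
    labels: Sequence[int],
    probabilities: Sequence[float],
    lo: float = 0.5,
    hi: float = 1.0,
    step: float = 0.001,
) -> float:
    """Smallest grid threshold in [lo, hi] maximizing F1 on the holdout."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection requires both classes in the holdout")
    if hi < lo:
        raise ValueError(f"empty threshold range [{lo}, {hi}]")
    grid = np.arange(lo, hi + step / 2, step)
    best_t, best_f1 = grid[0], -1.0
    for t in grid:
        yhat = (p >= t).astype(int)
        tp = int(np.sum((y == 1) & (yhat == 1)))
        fp = int(np.sum((y == 0) & (yhat == 1)))
        fn = int(np.sum((y == 1) & (yhat == 0)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        if f1 > best_f1:  # strict: ties keep the smallest threshold
            best_t, best_f1 = t, f1
    return float(best_t)


def reconstruct_network(
    results,
    edges: Sequence[PairExample],
    threshold: float,
    records: Sequence[ProteinRecord] | None = None,
) -> tuple[int, int]:
    """(recovered, total) edge counts of a known PPI network.

    Every edge of the network is scored by the fitted model (any object
    with the ``predict(pairs, threshold, records)`` surface, e.g.
    :class:`~dfppi.model.DFPPIResults` or a synthetic oracle); an edge is
    recovered when its interaction probability reaches the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    yhat, _ = results.predict(list(edges), threshold, records)
    return int(yhat.sum()), len(edges)
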