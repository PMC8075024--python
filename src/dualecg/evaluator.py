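"""Confusion matrix, one-vs-rest metric suite, and evaluation protocols.

Metrics follow the standard one-vs-rest reduction of the 4x4 confusion
matrix (rows = actual N, VEB, SVEB, F; columns = predicted):

* sensitivity ``TP/(TP+FN)``, specificity ``TN/(TN+FP)``, precision
  ``TP/(TP+FP)``, accuracy ``(TP+TN)/total``, F1 ``2TP/(2TP+FP+FN)``,
  G-score ``sqrt(Se*Sp)``.

``specificity_denominator="fn"`` switches to the variant ``TN/(TN+FN)``
for auditability; the default follows the table-consistent definition.

Two protocols are provided: **inter-patient** (train/validate with
stratified CV on one patient set, test on disjoint patients) and
**intra-patient** (beats pooled across patients, stratified holdout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classes import AAMI_CLASSES, N_CLASSES, class_index

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")


@dataclass
class ConfusionMatrix:
    """4x4 count matrix, rows = actual class, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 4x4 matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Count matrix from label sequences (class names or indices)."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")

    def to_idx(v) -> int:
        return class_index(v) if isinstance(v, str) else class_index(AAMI_CLASSES[int(v)])

    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for a, p in zip(y_true, y_pred):
        counts[to_idx(a), to_idx(p)] += 1
    return ConfusionMatrix(counts)


def one_vs_rest(cm: ConfusionMatrix, cls) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for one class of the matrix."""
    i = class_index(cls) if isinstance(cls, str) else int(cls)
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = cm.total - tp - fp - fn
    return tp, fp, tn, fn


@dataclass
class ClassMetrics:
    """One-vs-rest metric bundle, each a fraction in [0, 1] (NaN = undefined)."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    g: float

    def as_percent(self, ndigits: int = 2) -> dict[str, float]:
        """Percentages rounded to ``ndigits`` (round-half-even)."""
        return {k: round(100 * v, ndigits) for k, v in vars(self).items()}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined: zero denominator", name)
        return UNDEFINED
    return num / den


def class_metrics(cm: ConfusionMatrix, cls,
                  specificity_denominator: str = "fp") -> ClassMetrics:
    """The full one-vs-rest metric bundle for one class."""
    tp, fp, tn, fn = one_vs_rest(cm, cls)
    if specificity_denominator == "fp":
        sp = _ratio(tn, tn + fp, "specificity")
    elif specificity_denominator == "fn":
        sp = _ratio(tn, tn + fn, "specificity")
    else:
        raise ValueError("specificity_denominator must be 'fp' or 'fn'")
    se = _ratio(tp, tp + fn, "sensitivity")
    return ClassMetrics(
        accuracy=_ratio(tp + tn, cm.total, "accuracy"),
        sensitivity=se,
        specificity=sp,
        precision=_ratio(tp, tp + fp, "precision"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        g=float(np.sqrt(se * sp)),
    )


def aggregate(cm: ConfusionMatrix) -> tuple[float, float, dict[str, ClassMetrics]]:
    """(macro_accuracy, micro_f1, per-class metrics).

    Macro accuracy is the mean of the four one-vs-rest accuracies; micro-F1
    is the micro-averaged F1 over classes, which for single-label
    classification equals trace/total (overall accuracy).
    """
    per_class = {c: class_metrics(cm, c) for c in AAMI_CLASSES}
    macro_acc = float(np.mean([m.accuracy for m in per_class.values()]))
    tp = sum(one_vs_rest(cm, c)[0] for c in AAMI_CLASSES)
    fp = sum(one_vs_rest(cm, c)[1] for c in AAMI_CLASSES)
    fn = sum(one_vs_rest(cm, c)[3] for c in AAMI_CLASSES)
    micro_f1 = _ratio(2 * tp, 2 * tp + fp + fn, "micro_f1")
    return macro_acc, micro_f1, per_class


def macro_f1(cm: ConfusionMatrix) -> float:
    """Mean per-class F1 (undefined classes excluded)."""
    f1s = [class_metrics(cm, c).f1 for c in AAMI_CLASSES]
    f1s = [f for f in f1s if np.isfinite(f)]
    return float(np.mean(f1s))


# ---------------------------------------------------------------------------
# Protocols


@dataclass
class FoldResult:
    confusion: ConfusionMatrix
    macro_accuracy: float
    micro_f1: float
    macro_f1: float
    per_class: dict[str, ClassMetrics]
    history: object = None


@dataclass
class ProtocolReport:
    protocol: str
    folds: list[FoldResult]
    pooled_confusion: ConfusionMatrix

    @property
    def mean_macro_accuracy(self) -> float:
        return float(np.mean([f.macro_accuracy for f in self.folds]))

    @property
    def mean_micro_f1(self) -> float:
        return float(np.mean([f.micro_f1 for f in self.folds]))

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean([f.macro_f1 for f in self.folds]))

    def to_dict(self) -> dict:
        _, _, pooled = aggregate(self.pooled_confusion)
        return {
            "protocol": self.protocol,
            "n_folds": len(self.folds),
            "mean_macro_accuracy": self.mean_macro_accuracy,
            "mean_micro_f1": self.mean_micro_f1,
            "mean_macro_f1": self.mean_macro_f1,
            "pooled_confusion": self.pooled_confusion.counts.tolist(),
            "pooled_per_class": {c: m.as_percent() for c, m in pooled.items()},
        }


def write_report_csv(cm: ConfusionMatrix, path) -> None:
    """Per-class metric table (counts + percentages) mirroring the standard
    confusion-matrix report layout."""
    lines = ["class," + ",".join(AAMI_CLASSES)
             + ",accuracy,sensitivity,specificity,precision,f1,g"]
    for i, cls in enumerate(AAMI_CLASSES):
        m = class_metrics(cm, cls).as_percent()
        row = [cls] + [str(int(c)) for c in cm.counts[i]] + [
            f"{m[k]:.2f}" for k in ("accuracy", "sensitivity", "specificity",
                                    "precision", "f1", "g")]
        lines.append(",".join(row))
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def _fold_result(cm: ConfusionMatrix, history=None) -> FoldResult:
    macro_acc, micro, per_class = aggregate(cm)
    return FoldResult(cm, macro_acc, micro, macro_f1(cm), per_class, history)


def run_protocol(protocol: str, records, pipeline_config=None, seed: int = 0,
                 n_folds: int = 10, train_ids=None, test_ids=None) -> ProtocolReport:
    """Run the full train/evaluate protocol on a set of annotated records.

    ``inter_patient``: records are split into disjoint patient sets
    (``train_ids``/``test_ids`` if given, the canonical MIT-BIH split if the
    ids match it, else a seeded 70/30 record split); each CV fold trains on
    the training-set beats and is tested on the held-out patients.

    ``intra_patient``: beats pooled over all records, 20% stratified test
    holdout, ``n_folds``-fold CV on the remaining 80%.
    """
    from .pipeline import PipelineConfig, prepare_dataset, train_fold

    cfg = pipeline_config or PipelineConfig()
    if protocol == "inter_patient":
        ids = [r.record_id for r in records]
        if train_ids is None or test_ids is None:
            from .record_io import standard_splits

            ds1, ds2 = standard_splits()
            if set(ids) <= set(ds1.record_ids) | set(ds2.record_ids):
                train_ids = [i for i in ids if i in ds1.record_ids]
                test_ids = [i for i in ids if i in ds2.record_ids]
            else:
                rng = np.random.default_rng(seed)
                shuffled = list(ids)
                rng.shuffle(shuffled)
                cut = max(1, int(round(0.7 * len(shuffled))))
                train_ids, test_ids = shuffled[:cut], shuffled[cut:]
        overlap = set(train_ids) & set(test_ids)
        assert not overlap, f"patient leakage between train and test: {overlap}"
        train_recs = [r for r in records if r.record_id in set(train_ids)]
        test_recs = [r for r in records if r.record_id in set(test_ids)]
        train_ds = prepare_dataset(train_recs, cfg)
        test_ds = prepare_dataset(test_recs, cfg)
        assert not set(train_ds.groups) & set(test_ds.groups)

        from .trainer import stratified_folds

        fold_idx = stratified_folds(train_ds.y, k=n_folds, seed=seed)
        results = []
        all_idx = np.arange(len(train_ds))
        for f, val_idx in enumerate(fold_idx):
            tr_idx = np.setdiff1d(all_idx, val_idx)
            cm, hist = train_fold(
                train_ds.subset(tr_idx), train_ds.subset(val_idx), test_ds,
                cfg, seed=seed + f,
            )
            results.append(_fold_result(cm, hist))
            logger.info("fold %d/%d: macro-F1 %.3f on held-out patients",
                        f + 1, n_folds, results[-1].macro_f1)
        pooled = ConfusionMatrix(sum(r.confusion.counts for r in results))
        return ProtocolReport("inter_patient", results, pooled)

    if protocol == "intra_patient":
        from sklearn.model_selection import train_test_split

        from .trainer import stratified_folds

        ds = prepare_dataset(list(records), cfg)
        idx = np.arange(len(ds))
        trval_idx, test_idx = train_test_split(
            idx, test_size=0.2, stratify=ds.y, random_state=seed)
        trval, test_ds = ds.subset(trval_idx), ds.subset(test_idx)
        fold_idx = stratified_folds(trval.y, k=n_folds, seed=seed)
        results = []
        all_idx = np.arange(len(trval))
        for f, val_idx in enumerate(fold_idx):
            tr_idx = np.setdiff1d(all_idx, val_idx)
            cm, hist = train_fold(
                trval.subset(tr_idx), trval.subset(val_idx), test_ds,
                cfg, seed=seed + f,
            )
            results.append(_fold_result(cm, hist))
        pooled = ConfusionMatrix(sum(r.confusion.counts for r in results))
        return ProtocolReport("intra_patient", results, pooled)

    raise ValueError(f"unknown protocol {protocol!r}")
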