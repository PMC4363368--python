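"""RBF-SVM classifier for quorum-sensing peptides.

The modelling surface follows the Model/Results convention: a
:class:`QspClassifier` is constructed from labelled peptides plus an
:class:`~qsppred.features.EncodingSpec`; ``fit()`` runs the (C, gamma) grid
search under seeded stratified 10-fold cross-validation and returns a
:class:`QspClassifierResults` carrying the selected hyper-parameters, the
pooled cross-validation metrics (sensitivity, specificity, accuracy, MCC,
ROC-AUC, per-fold breakdown) and a final model refitted on all data, from
which new peptides can be scored.

Evaluation details that matter for reproducibility:

* folds are stratified and seeded, so the whole pipeline is deterministic;
* min-max feature scaling to [0, 1] is learned on the training folds only
  (no leakage into held-out folds);
* the model-selection metric is pooled CV accuracy, ties broken by higher
  MCC then smaller C;
* threshold-dependent metrics are computed at decision threshold 0 by
  default; AUC is threshold-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .aaindex import AAIndexTable
from .features import EncodingError, EncodingSpec, encode, encode_peptide
from .seqio import NEGATIVE, POSITIVE, Peptide, PeptideSet

#: Default log2 hyper-parameter grids for the RBF kernel.
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_G_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and grid-search configuration."""

    n_folds: int = 10
    seed: int = 0
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    g_grid: tuple[float, ...] = DEFAULT_G_GRID
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.c_grid or not self.g_grid:
            raise ValueError("hyper-parameter grids must be non-empty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.g_grid):
            raise ValueError("C and gamma values must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN at a fixed decision threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Threshold-dependent and threshold-independent performance measures.

    Sensitivity, specificity and accuracy are percentages on [0, 100]; MCC
    is on [-1, 1]; AUC on [0, 1]. ``mcc_undefined`` flags a zero marginal in
    the confusion table (MCC then reported as 0 by convention).
    """

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None
    confusion: ConfusionCounts | None = None
    mcc_undefined: bool = False
    fold_accuracies: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
        }
        if self.confusion is not None:
            d.update(tp=self.confusion.tp, tn=self.confusion.tn,
                     fp=self.confusion.fp, fn=self.confusion.fn)
        return d


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Acc (percent) and MCC from a confusion table.

    MCC uses the standard [-1, 1] definition
    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; if any
    marginal is zero the denominator vanishes and MCC is reported as 0 with
    ``mcc_undefined`` set.
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("sensitivity/specificity require both classes present")
    sn = 100.0 * c.tp / (c.tp + c.fn)
    sp = 100.0 * c.tn / (c.tn + c.fp)
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc, undefined = 0.0, True
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
        undefined = False
    return MetricsReport(sensitivity=sn, specificity=sp, accuracy=acc,
                         mcc=mcc, confusion=c, mcc_undefined=undefined)


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.0
) -> ConfusionCounts:
    """Confusion table from decision values; predicted positive iff score >= t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area under the curve.

    Equals the Mann-Whitney pair statistic: the fraction of
    (positive, negative) pairs in which the positive scores higher, ties
    counting one half.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points (false positive rate, true positive rate)."""
    fpr, tpr, thr = roc_curve(np.asarray(labels, int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _labels_array(s: PeptideSet) -> np.ndarray:
    y = np.empty(len(s), dtype=int)
    for i, p in enumerate(s):
        if p.label == POSITIVE:
            y[i] = 1
        elif p.label == NEGATIVE:
            y[i] = 0
        else:
            raise ValueError(f"peptide {p.id!r} has no class label")
    return y


def _cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    cfg: CVConfig,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Pooled out-of-fold decision values and per-fold accuracies."""
    if groups is None:
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        )
    else:
        splitter = StratifiedGroupKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        )
    pooled = np.empty(len(y))
    fold_acc: list[float] = []
    for train_idx, test_idx in splitter.split(X, y, groups):
        scaler = MinMaxScaler().fit(X[train_idx])
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(scaler.transform(X[train_idx]), y[train_idx])
        d = clf.decision_function(scaler.transform(X[test_idx]))
        pooled[test_idx] = d
        fold_acc.append(float(np.mean((d >= 0.0) == (y[test_idx] == 1))) * 100.0)
    return pooled, fold_acc


def cross_validate(
    s: PeptideSet,
    spec: EncodingSpec,
    cfg: CVConfig = CVConfig(),
    table: AAIndexTable | None = None,
    threshold: float = 0.0,
    groups: Sequence | None = None,
) -> tuple[MetricsReport, tuple[float, float]]:
    """Grid-searched, seeded, stratified k-fold cross-validation.

    For every (C, gamma) pair the set is split into ``cfg.n_folds``
    stratified folds; each fold is scored by a model trained (with its
    scaler) on the other folds only, and the pooled out-of-fold decision
    values give one confusion table at ``threshold`` and one AUC. The pair
    maximizing pooled accuracy (ties: higher MCC, then smaller C, then
    smaller gamma) is selected and its report returned together with
    ``(C, gamma)``.

    ``groups``, when given, keeps peptides sharing a group key in the same
    fold (stratified group k-fold). This matters for composition-matched
    scrambled negatives: a peptide and its scramble have identical
    composition features with opposite labels, and letting one twin into the
    training folds while the other is tested makes any kernel classifier
    *anti*-predict the held-out twin. Grouping peptide/scramble pairs
    removes that leakage and restores the honest chance-level result.
    """
    y = _labels_array(s)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"each class needs >= {cfg.n_folds} members, got {counts.tolist()}"
        )
    X = encode(spec, s, table).values
    group_arr = None if groups is None else np.asarray(groups)
    best: tuple | None = None
    for C in cfg.c_grid:
        for gamma in cfg.g_grid:
            pooled, fold_acc = _cv_scores(X, y, C, gamma, cfg, group_arr)
            rep = metrics(confusion_at_threshold(pooled, y, threshold))
            rep.auc = auc(pooled, y)
            rep.fold_accuracies = fold_acc
            key = (-rep.accuracy, -rep.mcc, C, gamma)
            if best is None or key < best[0]:
                best = (key, rep, (C, gamma))
    assert best is not None
    return best[1], best[2]


@dataclass
class TrainedModel:
    """A fitted scaler+SVM with its encoding spec, ready to score peptides."""

    spec: EncodingSpec
    C: float
    gamma: float
    scaler: MinMaxScaler
    svc: SVC
    decision_threshold: float = 0.0
    table: AAIndexTable | None = None
    version: str = _pkg_version

    def decision_values(self, s: PeptideSet) -> np.ndarray:
        X = encode(self.spec, s, self.table).values
        return self.svc.decision_function(self.scaler.transform(X))

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        m = joblib.load(path)
        if not isinstance(m, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return m


def train_final(
    s: PeptideSet,
    spec: EncodingSpec,
    C: float,
    gamma: float,
    table: AAIndexTable | None = None,
    threshold: float = 0.0,
) -> TrainedModel:
    """Fit scaler and SVM on all of ``s`` at fixed hyper-parameters."""
    y = _labels_array(s)
    X = encode(spec, s, table).values
    scaler = MinMaxScaler().fit(X)
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit(scaler.transform(X), y)
    return TrainedModel(spec=spec, C=C, gamma=gamma, scaler=scaler, svc=svc,
                        decision_threshold=threshold, table=table)


def predict(m: TrainedModel, s: PeptideSet) -> pd.DataFrame:
    """Score peptides; one row per input peptide, never silently dropped.

    Columns: ``decision_value``, ``label`` (positive/negative), ``scorable``
    and ``reason`` (non-empty when a peptide violates the encoding's length
    precondition and cannot be scored).
    """
    rows = []
    for p in s:
        try:
            x = encode_peptide(p, m.spec, m.table).reshape(1, -1)
            d = float(m.svc.decision_function(m.scaler.transform(x))[0])
            lab = POSITIVE if d >= m.decision_threshold else NEGATIVE
            rows.append((p.id, d, lab, True, ""))
        except EncodingError as e:
            rows.append((p.id, np.nan, "unscorable", False, str(e)))
    return pd.DataFrame(
        rows, columns=["peptide_id", "decision_value", "label", "scorable", "reason"]
    ).set_index("peptide_id")


class QspClassifier:
    """Quorum-sensing peptide classifier model (Model/Results pattern).

    Parameters
    ----------
    data : PeptideSet
        Labelled peptides (labels ``positive``/``negative``).
    encoding : EncodingSpec
        Feature encoding scheme.
    cv : CVConfig
        Fold count, seed and hyper-parameter grids.
    table : AAIndexTable, optional
        Required when the encoding includes a Physico component.

    ``fit()`` grid-searches (C, gamma) by pooled 10-fold CV accuracy and
    returns a :class:`QspClassifierResults`.
    """

    def __init__(
        self,
        data: PeptideSet,
        encoding: EncodingSpec,
        cv: CVConfig = CVConfig(),
        table: AAIndexTable | None = None,
        decision_threshold: float = 0.0,
        groups: Sequence | None = None,
    ) -> None:
        self.data = data
        self.encoding = encoding
        self.cv = cv
        self.table = table
        self.decision_threshold = decision_threshold
        self.groups = groups

    @classmethod
    def from_peptide_sets(
        cls,
        positives: PeptideSet,
        negatives: PeptideSet,
        encoding: EncodingSpec,
        cv: CVConfig = CVConfig(),
        table: AAIndexTable | None = None,
    ) -> "QspClassifier":
        pos = positives.relabelled(POSITIVE)
        neg = negatives.relabelled(NEGATIVE)
        data = PeptideSet(list(pos) + list(neg), name="training")
        return cls(data, encoding, cv=cv, table=table)

    @classmethod
    def from_fasta(
        cls,
        pos_path: str | Path,
        neg_path: str | Path,
        encoding: EncodingSpec,
        cv: CVConfig = CVConfig(),
        table: AAIndexTable | None = None,
    ) -> "QspClassifier":
        from .seqio import read_fasta

        return cls.from_peptide_sets(
            read_fasta(pos_path, POSITIVE), read_fasta(neg_path, NEGATIVE),
            encoding, cv=cv, table=table,
        )

    def fit(self) -> "QspClassifierResults":
        report, (C, gamma) = cross_validate(
            self.data, self.encoding, self.cv, self.table,
            self.decision_threshold, self.groups,
        )
        trained = train_final(
            self.data, self.encoding, C, gamma, self.table, self.decision_threshold
        )
        return QspClassifierResults(self, report, trained)


class QspClassifierResults:
    """Fit results: selected hyper-parameters, CV metrics and final model."""

    def __init__(
        self, model: QspClassifier, cv_report: MetricsReport, trained: TrainedModel
    ) -> None:
        self.model = model
        self.cv_report = cv_report
        self.trained = trained

    @property
    def C(self) -> float:
        return self.trained.C

    @property
    def gamma(self) -> float:
        return self.trained.gamma

    @property
    def accuracy(self) -> float:
        return self.cv_report.accuracy

    @property
    def mcc(self) -> float:
        return self.cv_report.mcc

    @property
    def auc(self) -> float | None:
        return self.cv_report.auc

    def predict(self, s: PeptideSet) -> pd.DataFrame:
        return predict(self.trained, s)

    def validate(self, s: PeptideSet) -> MetricsReport:
        """Evaluate on an independent labelled set (same scoring path as CV)."""
        y = _labels_array(s)
        d = self.trained.decision_values(s)
        rep = metrics(confusion_at_threshold(d, y, self.trained.decision_threshold))
        rep.auc = auc(d, y)
        return rep

    def design(self, parent: Peptide) -> pd.DataFrame:
        from .tools import qspepdesign

        return qspepdesign(self.trained, parent)

    def map_protein(self, protein: Peptide, window: int = 12, step: int = 1):
        from .tools import qspepmap

        return qspepmap(self.trained, protein, window, step)

    def roc(self) -> pd.DataFrame:
        """ROC points of the final model on its own training data."""
        y = _labels_array(self.model.data)
        return roc_points(self.trained.decision_values(self.model.data), y)

    def save(self, path: str | Path) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        r = self.cv_report
        c = r.confusion
        lines = [
            "QSP classifier — RBF-SVM fit summary",
            "=" * 52,
            f"Encoding:            {self.model.encoding.describe()}"
            f" ({self.model.encoding.n_features} features)",
            f"Peptides:            {len(self.model.data)}"
            f" ({int(np.sum(_labels_array(self.model.data)))} positive)",
            f"CV folds / seed:     {self.model.cv.n_folds} / {self.model.cv.seed}",
            f"Selected C, gamma:   {self.C:g}, {self.gamma:g}",
            "-" * 52,
            f"CV sensitivity:      {r.sensitivity:6.2f} %",
            f"CV specificity:      {r.specificity:6.2f} %",
            f"CV accuracy:         {r.accuracy:6.2f} %",
            f"CV MCC:              {r.mcc:6.3f}" + ("  (undefined, reported 0)" if r.mcc_undefined else ""),
            f"CV ROC AUC:          {r.auc:6.3f}" if r.auc is not None else "CV ROC AUC:           n/a",
        ]
        if c is not None:
            lines.append(
                f"Confusion (pooled):  TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}"
            )
        if r.fold_accuracies:
            folds = " ".join(f"{a:.0f}" for a in r.fold_accuracies)
            lines.append(f"Per-fold accuracy:   {folds}")
        lines.append("=" * 52)
        return "\n".join(lines)
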