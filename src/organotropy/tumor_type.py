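"""Multiclass tumor-type classification — the architecture's first stage.

A gradient-boosted tree ensemble assigns each transcriptome a cancer-type
label (and a posterior probability vector); classifying the tumor type first
constrains which organotropic progression models apply downstream. COAD and
READ are merged into a single COADREAD class by default, mirroring their
transcriptomic overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import train_test_split

from .clinical import COADREAD_CODES


@dataclass
class MulticlassReport:
    """Confusion matrix with per-class and macro-averaged metrics."""

    confusion: pd.DataFrame          # true x predicted counts
    per_class: pd.DataFrame          # precision, recall, f1, support
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def summary(self) -> str:
        lines = ["Tumor-type classification", "=" * 42,
                 self.per_class.round(4).to_string(), "-" * 42,
                 f"macro precision {self.macro_precision:.4f}  "
                 f"macro recall {self.macro_recall:.4f}  macro F1 {self.macro_f1:.4f}"]
        return "\n".join(lines)

    def plot_confusion(self, ax=None):
        """Heatmap of the confusion matrix (true labels on rows)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.confusion.to_numpy(), cmap="Reds")
        ax.set_xticks(range(len(self.confusion.columns)), self.confusion.columns,
                      rotation=90)
        ax.set_yticks(range(len(self.confusion.index)), self.confusion.index)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.figure.colorbar(im, ax=ax)
        return ax


def report_from_confusion(confusion: pd.DataFrame) -> MulticlassReport:
    """Metrics from a true x predicted count matrix.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    macro averages are unweighted over classes present in the test set
    (support > 0); a class never predicted gets precision 0. Classes with
    zero support are excluded from the macro with a warning.
    """
    cm = confusion.to_numpy(dtype=float)
    classes = list(confusion.index)
    tp = np.diag(cm)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, np.nan)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    per_class = pd.DataFrame({"precision": precision, "recall": recall, "f1": f1,
                              "support": support.astype(int)},
                             index=pd.Index(classes, name="class"))
    present = support > 0
    if not present.all():
        warnings.warn(f"classes absent from test set excluded from macro: "
                      f"{[c for c, p in zip(classes, present) if not p]}")
    return MulticlassReport(
        confusion=confusion,
        per_class=per_class,
        macro_precision=float(np.mean(precision[present])),
        macro_recall=float(np.mean(recall[present])),
        macro_f1=float(np.mean(f1[present])),
    )


def evaluate_multiclass(model, X_test, y_test, classes=None) -> MulticlassReport:
    """Deterministic report for a fitted classifier on held-out data."""
    y_pred = model.predict(np.asarray(X_test, dtype=float))
    y_test = np.asarray(y_test)
    if classes is None:
        classes = sorted(set(y_test) | set(y_pred))
    cm = pd.DataFrame(0, index=pd.Index(classes, name="true"),
                      columns=pd.Index(classes, name="predicted"))
    for t, p in zip(y_test, y_pred):
        cm.loc[t, p] += 1
    return report_from_confusion(cm)


class TumorTypeModel:
    """Gradient-boosted tree multiclass model of cancer type.

    Parameters
    ----------
    X : DataFrame
        Normalized expression, samples x transcripts.
    labels : Series
        Cancer-type code per sample, aligned with ``X``.
    merge_coadread : bool
        Collapse COAD/READ labels into COADREAD before fitting.
    """

    def __init__(self, X: pd.DataFrame, labels: pd.Series, *,
                 merge_coadread: bool = True, holdout_fraction: float = 0.3,
                 n_estimators: int = 300, max_depth: int = 3,
                 learning_rate: float = 0.1, seed: int = 0):
        labels = labels.loc[X.index].astype(str)
        if merge_coadread:
            labels = labels.replace({c: "COADREAD" for c in COADREAD_CODES})
        if labels.nunique() < 2:
            raise ValueError("need at least two cancer-type classes")
        self.X = X
        self.labels = labels
        self.holdout_fraction = holdout_fraction
        self.seed = seed
        self._params = dict(max_iter=n_estimators, max_depth=max_depth,
                            learning_rate=learning_rate, random_state=seed)

    def fit(self) -> "TumorTypeResults":
        """Stratified 70/30 split, fit the ensemble, evaluate on the holdout."""
        idx = self.X.index.to_numpy()
        train_idx, test_idx = train_test_split(
            idx, test_size=self.holdout_fraction, stratify=self.labels.to_numpy(),
            random_state=self.seed)
        y_train = self.labels.loc[train_idx]
        small = y_train.value_counts()
        for cls, n in small.items():
            if n < 2:
                warnings.warn(f"class {cls} has {n} training sample(s); "
                              "the fitted model for it will be weak")
        est = HistGradientBoostingClassifier(**self._params)
        est.fit(self.X.loc[train_idx].to_numpy(dtype=float), y_train.to_numpy())
        report = evaluate_multiclass(est, self.X.loc[test_idx],
                                     self.labels.loc[test_idx],
                                     classes=sorted(self.labels.unique()))
        return TumorTypeResults(self, est, report, list(train_idx), list(test_idx))


@dataclass
class TumorTypeResults:
    model: TumorTypeModel
    estimator: HistGradientBoostingClassifier
    report: MulticlassReport
    train_ids: list
    test_ids: list

    def predict_proba(self, X) -> pd.DataFrame:
        """Posterior probability per class; rows sum to 1."""
        p = self.estimator.predict_proba(np.asarray(X, dtype=float))
        idx = X.index if isinstance(X, pd.DataFrame) else None
        return pd.DataFrame(p, index=idx, columns=self.estimator.classes_)

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def summary(self) -> str:
        return self.report.summary()
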