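"""Per-(cancer, site) binary progression classifiers with leakage-safe evaluation.

Each retained tumor-site pair gets its own binary model: 30% of the *real*
samples are held out (stratified) before anything else; SMOTE balancing and
feature selection see only the training split, so no held-out sample ever
serves as a SMOTE template or influences the candidate features; the test set
contains real instances only. Models are random forests by default with a
gradient-boosted alternative, predicting the class by rounding the posterior
(ties at exactly 0.5 go to the positive class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split

from .balancing import BalancedDataset, SmoteConfig, balance_dataset
from .clinical import ProgressionLabelSet
from .selection import CandidateFeatureSet, SelectionConfig, select_candidates

MODEL_KINDS = ("rf", "gbt")


@dataclass
class SplitPlan:
    """Stratified train/test partition of real samples."""

    train_ids: list
    test_ids: list
    holdout_fraction: float = 0.3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def split_holdout(labels: pd.Series, holdout_fraction: float = 0.3,
                  seed: int = 0) -> SplitPlan:
    """Stratified holdout over real samples; both classes must be present."""
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 2:
        raise ValueError(f"a class has {counts.min()} sample(s); cannot stratify")
    ids = labels.index.to_numpy()
    train, test = train_test_split(ids, test_size=holdout_fraction,
                                   stratify=labels.to_numpy(), random_state=seed)
    return SplitPlan(list(train), list(test), holdout_fraction, True, seed)


def classify_from_proba(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Round the posterior: class 1 iff p >= threshold (half rounds up)."""
    return (np.asarray(p) >= threshold).astype(int)


def train_site_model(X_train: np.ndarray, y_train: np.ndarray,
                     model_kind: str = "rf", *, n_estimators: int = 300,
                     max_depth: int | None = None, learning_rate: float = 0.1,
                     seed: int = 0):
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training input")
    if model_kind == "rf":
        model = RandomForestClassifier(n_estimators=n_estimators,
                                       max_depth=max_depth, random_state=seed, n_jobs=1)
    elif model_kind == "gbt":
        model = HistGradientBoostingClassifier(max_iter=n_estimators,
                                               max_depth=max_depth or 3,
                                               learning_rate=learning_rate,
                                               random_state=seed)
    else:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    return model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))


@dataclass
class BinaryEvalReport:
    """Confusion counts and derived metrics for one pair's holdout."""

    pair: tuple[str, str]
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float
    per_class: pd.DataFrame = field(repr=False)
    n_test: int = 0

    def to_dict(self) -> dict:
        return {"pair": "|".join(self.pair), "tp": self.tp, "fp": self.fp,
                "fn": self.fn, "tn": self.tn, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "accuracy": self.accuracy,
                "n_test": self.n_test}


def _safe_div(a: float, b: float) -> float | None:
    return a / b if b > 0 else None


def report_from_counts(tp: int, fp: int, fn: int, tn: int,
                       pair: tuple[str, str] = ("NA", "NA")) -> BinaryEvalReport:
    """Metrics from binary confusion counts; undefined metrics are None.

    Positive-class metrics are the headline precision/recall/F1; the
    negative-class row reports the same formulas with the classes swapped.
    """
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty test set")
    prec = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1 = (2 * prec * rec / (prec + rec)
          if prec is not None and rec is not None and prec + rec > 0 else
          (0.0 if prec is not None and rec is not None else None))
    nprec = _safe_div(tn, tn + fn)
    nrec = _safe_div(tn, tn + fp)
    nf1 = (2 * nprec * nrec / (nprec + nrec)
           if nprec is not None and nrec is not None and nprec + nrec > 0 else
           (0.0 if nprec is not None and nrec is not None else None))
    per_class = pd.DataFrame(
        {"precision": [prec, nprec], "recall": [rec, nrec], "f1": [f1, nf1],
         "support": [tp + fn, tn + fp]},
        index=pd.Index(["positive", "negative"], name="class"))
    return BinaryEvalReport(pair, tp, fp, fn, tn, prec, rec, f1,
                            accuracy=(tp + tn) / n, per_class=per_class, n_test=n)


def evaluate_binary(model, split: SplitPlan, X: pd.DataFrame, y: pd.Series,
                    pair: tuple[str, str] = ("NA", "NA"),
                    threshold: float = 0.5) -> BinaryEvalReport:
    """Evaluate on the real held-out samples only."""
    Xt = X.loc[split.test_ids]
    yt = y.loc[split.test_ids].to_numpy()
    proba = model.predict_proba(Xt.to_numpy(dtype=float))[:, list(model.classes_).index(1)]
    pred = classify_from_proba(proba, threshold)
    tp = int(np.sum((pred == 1) & (yt == 1)))
    fp = int(np.sum((pred == 1) & (yt == 0)))
    fn = int(np.sum((pred == 0) & (yt == 1)))
    tn = int(np.sum((pred == 0) & (yt == 0)))
    return report_from_counts(tp, fp, fn, tn, pair)


class SiteProgressionModel:
    """Binary organotropic-progression model for one (cancer, site) pair.

    fit() runs the leakage-safe protocol end to end: stratified 70/30 split
    of real samples, SMOTE balancing of the training split, blockwise
    consensus feature selection on the balanced training data (unless a
    pre-selected feature list is supplied), model training on the selected
    features, and evaluation on the untouched real holdout.
    """

    def __init__(self, X: pd.DataFrame, labels: ProgressionLabelSet | pd.Series, *,
                 features: list[str] | None = None, model_kind: str = "rf",
                 smote_cfg: SmoteConfig | None = None,
                 selection_cfg: SelectionConfig | None = None,
                 holdout_fraction: float = 0.3, n_estimators: int = 300,
                 max_depth: int | None = None, learning_rate: float = 0.1,
                 seed: int = 0):
        if isinstance(labels, ProgressionLabelSet):
            self.pair = labels.pair
            labels = labels.labels
        else:
            self.pair = tuple(str(labels.name).split("|")) if labels.name else ("NA", "NA")
        self.X = X.loc[labels.index]
        self.y = labels.astype(int)
        self.features = features
        self.model_kind = model_kind
        self.smote_cfg = smote_cfg or SmoteConfig(seed=seed)
        self.selection_cfg = selection_cfg
        self.holdout_fraction = holdout_fraction
        self.seed = seed
        self._model_params = dict(n_estimators=n_estimators, max_depth=max_depth,
                                  learning_rate=learning_rate, seed=seed)

    def fit(self) -> "SiteProgressionResults":
        split = split_holdout(self.y, self.holdout_fraction, self.seed)
        X_tr = self.X.loc[split.train_ids]
        y_tr = self.y.loc[split.train_ids]

        balanced = balance_dataset(X_tr.to_numpy(dtype=float), y_tr.to_numpy(),
                                   self.smote_cfg, sample_ids=split.train_ids)
        X_bal = pd.DataFrame(balanced.X, columns=self.X.columns,
                             index=balanced.sample_ids)

        selection: CandidateFeatureSet | None = None
        if self.features is not None:
            feats = list(self.features)
        else:
            cfg = self.selection_cfg or SelectionConfig(
                n_blocks=min(10, self.X.shape[1]), per_block_keep=10, seed=self.seed)
            selection = select_candidates(X_bal, balanced.y, cfg)
            feats = selection.candidates

        model = train_site_model(X_bal[feats].to_numpy(dtype=float), balanced.y,
                                 self.model_kind, **self._model_params)
        report = evaluate_binary(model, split, self.X[feats], self.y, self.pair)
        return SiteProgressionResults(self, model, report, split, balanced,
                                      feats, selection)


@dataclass
class SiteProgressionResults:
    model: SiteProgressionModel
    estimator: object
    report: BinaryEvalReport
    split: SplitPlan
    balanced: BalancedDataset
    features: list[str]
    selection: CandidateFeatureSet | None = None

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.estimator.predict_proba(X[self.features].to_numpy(dtype=float))
        return p[:, list(self.estimator.classes_).index(1)]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return classify_from_proba(self.predict_proba(X))

    def summary(self) -> str:
        r = self.report
        fmt = lambda v: "NA" if v is None else f"{v:.4f}"
        return "\n".join([
            f"Site progression model {r.pair[0]} -> {r.pair[1]} ({self.model.model_kind})",
            "=" * 48,
            f"test n={r.n_test}  TP={r.tp} FP={r.fp} FN={r.fn} TN={r.tn}",
            f"precision {fmt(r.precision)}  recall {fmt(r.recall)}  "
            f"F1 {fmt(r.f1)}  accuracy {r.accuracy:.4f}",
            f"features used: {len(self.features)}  "
            f"synthetic training samples: {self.balanced.n_synthetic}",
        ])


def aggregate_by_cancer(reports: list[BinaryEvalReport]) -> pd.DataFrame:
    """Per-cancer unweighted means of site-level metrics (Table-1-style)."""
    rows = []
    for r in reports:
        rows.append({"cancer_code": r.pair[0], "site": r.pair[1],
                     "precision": r.precision, "recall": r.recall,
                     "f1": r.f1, "accuracy": r.accuracy})
    df = pd.DataFrame(rows)
    return (df.groupby("cancer_code")[["precision", "recall", "f1", "accuracy"]]
              .mean().reset_index())
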