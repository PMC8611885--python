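"""Blockwise consensus feature selection with five-method support voting.

The transcriptome is partitioned into contiguous blocks (100 blocks of ~600
features at full scale); within each block five selectors score every
feature — a chi-square filter, recursive feature elimination wrapped around a
logistic estimator, random-forest classifier importance, random-forest
regressor importance, and L1-penalized logistic regression. A feature's
support vote (0-5) counts how many methods flag it; features are ranked by
(vote, mean normalized score, index), colinear features (|Pearson r| at or
above a threshold against an already-kept feature) are pruned greedily in
rank order, and the top ``per_block_keep`` survivors of each block form the
candidate set (50 x 100 = 5000 at full scale). A global top-1000 list is
exported for the recapture stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

logger = logging.getLogger(__name__)

EMBEDDED_METHODS = ("rf_classifier", "rf_regressor", "l1_logistic")
METHOD_NAMES = ("chi2_filter", "rfe_logistic", "rf_classifier", "rf_regressor", "l1_logistic")


@dataclass
class BlockPartition:
    """Contiguous, order-preserving partition of the feature axis."""

    n_features: int
    n_blocks: int
    ranges: list[tuple[int, int]]  # half-open [start, stop)

    def sizes(self) -> list[int]:
        return [b - a for a, b in self.ranges]


@dataclass
class SelectionConfig:
    n_blocks: int = 100
    per_block_keep: int = 50
    keep_fraction: float | None = None  # the "top 10%" reading, overrides per_block_keep
    colinearity_r: float = 0.95
    export_top: int = 1000
    rfe_step: float = 0.1
    cv_folds: int = 1
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.colinearity_r <= 1.0:
            raise ValueError("colinearity_r must lie in (0, 1]")
        if self.keep_fraction is not None and not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must lie in (0, 1]")


@dataclass
class CandidateFeatureSet:
    """Selected candidates plus the full support table."""

    candidates: list[str]
    top: list[str]
    support_table: pd.DataFrame
    partition: BlockPartition
    shortfalls: dict[int, int] = field(default_factory=dict)

    def support_to_tsv(self, path) -> None:
        self.support_table.to_csv(path, sep="\t")


def partition_blocks(n_features: int, n_blocks: int) -> BlockPartition:
    """Split ``n_features`` into ``n_blocks`` contiguous near-equal blocks.

    The first (n_features mod n_blocks) blocks get the ceiling size, the rest
    the floor; 60,483 features in 100 blocks gives 83 blocks of 605 and 17 of
    604.
    """
    if n_blocks > n_features:
        raise ValueError(f"n_blocks {n_blocks} exceeds n_features {n_features}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    q, r = divmod(n_features, n_blocks)
    ranges, start = [], 0
    for b in range(n_blocks):
        size = q + (1 if b < r else 0)
        ranges.append((start, start + size))
        start += size
    return BlockPartition(n_features, n_blocks, ranges)


def _top_k_support(scores: np.ndarray, k: int) -> np.ndarray:
    """Boolean support for the k largest scores; ties to the lower index."""
    n = len(scores)
    k = min(k, n)
    support = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.lexsort((np.arange(n), -scores))
        support[order[:k]] = True
    return support


def chi2_select(block_X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square filter on min-max scaled features.

    Constant features scale to all-zeros, score 0, and are never supported.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class target: chi-square filter undefined")
    Xs = MinMaxScaler().fit_transform(np.asarray(block_X, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scores, _ = sk_chi2(Xs, y)
    scores = np.nan_to_num(scores, nan=0.0)
    return _top_k_support(scores, k), scores


def _fit_logistic(X, y, C=1.0, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            return LogisticRegression(C=C, max_iter=500, **kw).fit(X, y)
        except ConvergenceWarning:
            pass
    # one retry at stronger regularization, then let any failure propagate
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        return LogisticRegression(C=C / 10.0, max_iter=500, **kw).fit(X, y)


def rfe_select(block_X: np.ndarray, y: np.ndarray, n_keep: int,
               step: float = 0.1) -> tuple[np.ndarray, np.ndarray, int]:
    """Recursive feature elimination with a linear logistic estimator.

    Each round refits on the surviving features and drops the
    ``step``-fraction (at least one) with the smallest |coefficient| until
    ``n_keep`` remain. Returns (support, score, n_rounds) where score is the
    elimination round at which a feature was removed (survivors score
    highest), giving a full ranking.
    """
    X = np.asarray(block_X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("two classes required for RFE")
    n = X.shape[1]
    n_keep = min(n_keep, n)
    alive = np.arange(n)
    score = np.zeros(n)
    rounds = 0
    while len(alive) > n_keep:
        model = _fit_logistic(X[:, alive], y)
        imp = np.abs(model.coef_).ravel()
        n_drop = min(max(1, int(np.floor(step * len(alive)))), len(alive) - n_keep)
        # drop smallest |coef|; ties resolved against the higher feature index
        order = np.lexsort((-alive, imp))
        drop = order[:n_drop]
        rounds += 1
        score[alive[drop]] = rounds
        alive = np.delete(alive, drop)
    score[alive] = rounds + 1
    support = np.zeros(n, dtype=bool)
    support[alive] = True
    return support, score, rounds


def embedded_select(block_X: np.ndarray, y: np.ndarray, method: str, n_keep: int,
                    seed: int = 0, n_trees: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Embedded selection: forest importances or L1-logistic |coefficients|.

    ``rf_regressor`` treats the 0/1 label as a numeric target. All-zero
    importances yield an empty support with a warning.
    """
    X = np.asarray(block_X, dtype=float)
    y = np.asarray(y)
    if method == "rf_classifier":
        if len(np.unique(y)) < 2:
            raise ValueError("two classes required")
        imp = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                     n_jobs=1).fit(X, y).feature_importances_
    elif method == "rf_regressor":
        imp = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1).fit(X, y.astype(float)).feature_importances_
    elif method == "l1_logistic":
        if len(np.unique(y)) < 2:
            raise ValueError("two classes required")
        model = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                   random_state=seed)
        imp = np.abs(model.fit(X, y).coef_).ravel()
    else:
        raise ValueError(f"unknown embedded method {method!r}; one of {EMBEDDED_METHODS}")
    if n_keep == 0:
        return np.zeros(X.shape[1], dtype=bool), imp
    if not np.any(imp):
        warnings.warn(f"{method}: all importances zero; supporting no feature")
        return np.zeros(X.shape[1], dtype=bool), imp
    return _top_k_support(imp, n_keep), imp


def _normalize(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores, dtype=float)
    return (scores - lo) / (hi - lo)


def vote_and_rank(support_table: pd.DataFrame) -> pd.DataFrame:
    """Sort features by (vote desc, mean normalized score desc, index asc).

    ``support_table`` carries one boolean column per method plus matching
    ``score_<method>`` columns; votes are the row sums of the booleans.
    """
    tab = support_table.copy()
    method_cols = [m for m in METHOD_NAMES if m in tab.columns]
    tab["vote"] = tab[method_cols].sum(axis=1).astype(int)
    score_cols = [f"score_{m}" for m in method_cols if f"score_{m}" in tab.columns]
    if score_cols:
        norm = np.column_stack([_normalize(tab[c].to_numpy(float)) for c in score_cols])
        tab["mean_score"] = norm.mean(axis=1)
    else:
        tab["mean_score"] = 0.0
    tab["_pos"] = np.arange(len(tab))
    tab = tab.sort_values(["vote", "mean_score", "_pos"],
                          ascending=[False, False, True], kind="stable")
    return tab.drop(columns="_pos")


def drop_colinear(ranked_features, X: pd.DataFrame, r_threshold: float) -> list[str]:
    """Greedy colinearity pruning in rank order.

    A feature is dropped when its |Pearson r| with any already-kept feature
    reaches the threshold; zero-variance features correlate with nothing
    (r treated as 0) and are kept if ranked.
    """
    kept: list[str] = []
    kept_mat: list[np.ndarray] = []
    for f in ranked_features:
        v = X[f].to_numpy(dtype=float)
        sd = v.std()
        colinear = False
        if sd > 0 and kept_mat:
            vz = (v - v.mean()) / sd
            for kz in kept_mat:
                if kz is not None and abs(float(vz @ kz) / len(v)) >= r_threshold:
                    colinear = True
                    break
        if not colinear:
            kept.append(f)
            kept_mat.append((v - v.mean()) / sd if sd > 0 else None)
    return kept


def _block_supports(Xb: np.ndarray, y: np.ndarray, k: int, cfg: SelectionConfig
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    sup_chi, sc_chi = chi2_select(Xb, y, k)
    sup_rfe, sc_rfe, _ = rfe_select(Xb, y, k, cfg.rfe_step)
    out = {"chi2_filter": (sup_chi, sc_chi), "rfe_logistic": (sup_rfe, sc_rfe)}
    for m in EMBEDDED_METHODS:
        out[m] = embedded_select(Xb, y, m, k, seed=cfg.seed, n_trees=cfg.n_trees)
    return out


def select_candidates(X: pd.DataFrame, y, cfg: SelectionConfig | None = None
                      ) -> CandidateFeatureSet:
    """Run the full blockwise consensus selection over a feature matrix.

    Per block: five-method scoring (optionally repeated over stratified CV
    folds with majority-fold support), support voting, colinearity pruning,
    and truncation to the per-block keep count. Candidates from all blocks
    are pooled; the global ``export_top`` features by (vote, score) are also
    returned. A block exhausted by pruning below the keep count is logged as
    a shortfall.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(y)
    part = partition_blocks(X.shape[1], cfg.n_blocks)
    all_rows = []
    candidates: list[str] = []
    shortfalls: dict[int, int] = {}

    for bi, (lo, hi) in enumerate(part.ranges):
        cols = list(X.columns[lo:hi])
        Xb = X.iloc[:, lo:hi].to_numpy(dtype=float)
        block_size = hi - lo
        k = (max(1, int(round(cfg.keep_fraction * block_size)))
             if cfg.keep_fraction is not None else min(cfg.per_block_keep, block_size))

        if cfg.cv_folds > 1:
            skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
            votes = {m: np.zeros(block_size) for m in METHOD_NAMES}
            scores = {m: np.zeros(block_size) for m in METHOD_NAMES}
            for tr, _ in skf.split(Xb, y):
                sup = _block_supports(Xb[tr], y[tr], k, cfg)
                for m, (s, sc) in sup.items():
                    votes[m] += s
                    scores[m] += sc
            supports = {m: (votes[m] > cfg.cv_folds / 2, scores[m] / cfg.cv_folds)
                        for m in METHOD_NAMES}
        else:
            supports = _block_supports(Xb, y, k, cfg)

        tab = pd.DataFrame(index=pd.Index(cols, name="feature"))
        for m in METHOD_NAMES:
            tab[m] = supports[m][0]
            tab[f"score_{m}"] = supports[m][1]
        ranked = vote_and_rank(tab)
        survivors = drop_colinear(list(ranked.index), X[cols], cfg.colinearity_r)
        keep = survivors[:k]
        if len(keep) < k:
            shortfalls[bi] = k - len(keep)
            logger.warning("block %d: only %d survivors for keep=%d", bi, len(keep), k)
        candidates.extend(keep)
        ranked["block"] = bi
        ranked["kept"] = ranked.index.isin(keep)
        all_rows.append(ranked)

    support_table = pd.concat(all_rows)
    cand_tab = support_table.loc[support_table["kept"]]
    cand_tab = cand_tab.loc[candidates]  # preserve block/rank order
    glob = cand_tab.assign(_pos=np.arange(len(cand_tab))).sort_values(
        ["vote", "mean_score", "_pos"], ascending=[False, False, True], kind="stable")
    top = list(glob.index[: cfg.export_top])
    return CandidateFeatureSet(candidates, top, support_table, part, shortfalls)
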