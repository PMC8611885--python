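"""Minority-class oversampling (SMOTE) with an 80%-of-majority stopping rule.

Each synthetic point is a convex combination x_i + u (x_j - x_i) of a real
minority instance and one of its k minority-class nearest neighbors
(Euclidean), u ~ U[0, 1]. Oversampling stops once the minority count reaches
round(f * majority) with f = 0.8 by default — a guard against overfitting to
a flood of synthetic samples; the rounding is half-away-from-zero ("rounded
to the closest integer"). Every synthetic point records its two parents and
interpolation weight, so leakage audits can verify that no held-out sample
ever served as a SMOTE template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._util import round_half_away


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in (0, 1]")


@dataclass
class BalancedDataset:
    """Real + synthetic instances with full synthetic provenance."""

    X: np.ndarray
    y: np.ndarray
    is_synthetic: np.ndarray
    provenance: pd.DataFrame  # synthetic_id, parent_a, parent_b, u
    sample_ids: list

    @property
    def n_synthetic(self) -> int:
        return int(self.is_synthetic.sum())

    def provenance_to_tsv(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)


def smote_interpolate(x_i: np.ndarray, x_j: np.ndarray, u: float) -> np.ndarray:
    """Convex combination x_i + u (x_j - x_i) for u in [0, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"dimension mismatch: {x_i.shape} vs {x_j.shape}")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    return x_i + u * (x_j - x_i)


def smote_target(n_minority: int, n_majority: int, f: float = 0.8) -> int:
    """Final minority count under the f-of-majority rule (no shrinking)."""
    return max(n_minority, round_half_away(f * n_majority))


def _minority_neighbors(X_min: np.ndarray, k: int) -> np.ndarray:
    """Indices of each minority point's k nearest minority neighbors.

    Euclidean distance; ties broken by lower instance index (stable sort on
    distance, self excluded).
    """
    d = cdist(X_min, X_min)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def balance_dataset(X, y, cfg: SmoteConfig | None = None,
                    sample_ids=None) -> BalancedDataset:
    """Oversample the minority class to round(f * majority) instances.

    Neighbors are searched within the minority class only. If the minority is
    no larger than k, k is reduced to minority - 1 with a warning. When the
    minority already meets the target, no synthetics are generated.
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    minority_class = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(y))]
    sample_ids = list(sample_ids)

    k = cfg.k_neighbors
    if n_min <= k:
        if n_min < 2:
            raise ValueError("minority class needs at least 2 instances for SMOTE")
        warnings.warn(f"minority size {n_min} <= k_neighbors {k}; reducing k to {n_min - 1}")
        k = n_min - 1

    target = smote_target(int(n_min), int(n_maj), cfg.target_fraction)
    n_syn = target - int(n_min)

    min_idx = np.flatnonzero(y == minority_class)
    prov_rows = []
    if n_syn > 0:
        rng = np.random.default_rng(cfg.seed)
        nn = _minority_neighbors(X[min_idx], k)
        syn = np.empty((n_syn, X.shape[1]))
        for s in range(n_syn):
            a = int(rng.integers(len(min_idx)))
            b = int(nn[a, int(rng.integers(k))])
            u = float(rng.random())
            syn[s] = smote_interpolate(X[min_idx[a]], X[min_idx[b]], u)
            prov_rows.append({"synthetic_id": f"syn{s}",
                              "parent_a": sample_ids[min_idx[a]],
                              "parent_b": sample_ids[min_idx[b]], "u": u})
        X_out = np.vstack([X, syn])
        y_out = np.concatenate([y, np.full(n_syn, minority_class, dtype=y.dtype)])
        ids_out = sample_ids + [r["synthetic_id"] for r in prov_rows]
        is_syn = np.concatenate([np.zeros(len(y), bool), np.ones(n_syn, bool)])
    else:
        X_out, y_out, ids_out = X.copy(), y.copy(), sample_ids
        is_syn = np.zeros(len(y), bool)

    prov = pd.DataFrame(prov_rows, columns=["synthetic_id", "parent_a", "parent_b", "u"])
    return BalancedDataset(X_out, y_out, is_syn, prov, ids_out)
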