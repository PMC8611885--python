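"""Block partitioning, the five selectors, voting, colinearity pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import organotropy as ot
from organotropy.selection import SelectionConfig


# ---- partition -------------------------------------------------------------

def test_full_scale_partition_sizes():
    part = ot.partition_blocks(60483, 100)
    sizes = part.sizes()
    assert sizes.count(605) == 83 and sizes.count(604) == 17
    assert sum(sizes) == 60483


def test_even_split_and_singletons():
    assert ot.partition_blocks(10, 2).sizes() == [5, 5]
    assert ot.partition_blocks(7, 7).sizes() == [1] * 7


def test_more_blocks_than_features_rejected():
    with pytest.raises(ValueError):
        ot.partition_blocks(5, 6)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(1, 10_000), st.integers(1, 200))
def test_partition_conservation_property(n, b):
    if b > n:
        n, b = b, n
    part = ot.partition_blocks(n, b)
    sizes = part.sizes()
    assert sum(sizes) == n
    assert max(sizes) - min(sizes) <= 1
    # disjoint and order-preserving
    stops = [r[1] for r in part.ranges]
    starts = [r[0] for r in part.ranges]
    assert starts[0] == 0 and stops[-1] == n
    assert all(stops[i] == starts[i + 1] for i in range(b - 1))


# ---- chi2 ------------------------------------------------------------------

def test_chi2_finds_label_matching_feature():
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 20)
    X = rng.random((40, 5))
    X[:, 2] = y  # perfect match
    support, scores = ot.chi2_select(X, y, k=1)
    assert support[2] and support.sum() == 1
    # brute-force chi-square on the 2x2 table agrees it is the top score
    tab = pd.crosstab(X[:, 2] > 0.5, y)
    assert chi2_contingency(tab, correction=False)[0] > 0


def test_chi2_saturation_and_constant_feature():
    rng = np.random.default_rng(1)
    y = np.array([0, 1] * 10)
    X = rng.random((20, 4))
    X[:, 3] = 2.5  # constant
    support, scores = ot.chi2_select(X, y, k=4)
    assert support.sum() == 4  # k = block size: all supported
    support, scores = ot.chi2_select(X, y, k=3)
    assert not support[3] and scores[3] == 0.0


def test_chi2_single_class_target_rejected():
    with pytest.raises(ValueError, match="single-class"):
        ot.chi2_select(np.random.default_rng(0).random((10, 3)), np.zeros(10), 1)


# ---- RFE -------------------------------------------------------------------

def test_rfe_keeps_perfectly_separating_feature():
    rng = np.random.default_rng(2)
    n = 60
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 8))
    X[:, 5] = y * 4 + rng.normal(0, 0.1, n)
    support, _, _ = ot.rfe_select(X, y, n_keep=1, step=0.25)
    assert support[5] and support.sum() == 1


def test_rfe_no_elimination_when_keep_equals_block():
    rng = np.random.default_rng(3)
    y = np.array([0, 1] * 10)
    X = rng.normal(size=(20, 4))
    support, _, rounds = ot.rfe_select(X, y, n_keep=4)
    assert support.all() and rounds == 0


def test_rfe_one_per_round_counts_rounds():
    rng = np.random.default_rng(4)
    y = np.array([0, 1] * 10)
    X = rng.normal(size=(20, 3))
    support, score, rounds = ot.rfe_select(X, y, n_keep=1, step=1e-9)
    assert rounds == 2 and support.sum() == 1


# ---- embedded --------------------------------------------------------------

def test_l1_supports_planted_linear_signal():
    rng = np.random.default_rng(5)
    n = 80
    X = rng.normal(size=(n, 6))
    y = (X[:, 4] > 0).astype(int)
    for n_keep in (1, 3):
        support, imp = ot.embedded_select(X, y, "l1_logistic", n_keep)
        assert support[4]
    assert np.argmax(np.abs(imp)) == 4


def test_rf_classifier_support_is_seed_reproducible():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 10))
    y = np.array([0, 1] * 15)
    a, _ = ot.embedded_select(X, y, "rf_classifier", 3, seed=11)
    b, _ = ot.embedded_select(X, y, "rf_classifier", 3, seed=11)
    np.testing.assert_array_equal(a, b)


def test_embedded_zero_keep_and_unknown_method():
    X = np.random.default_rng(7).normal(size=(20, 4))
    y = np.array([0, 1] * 10)
    support, _ = ot.embedded_select(X, y, "rf_regressor", 0)
    assert not support.any()
    with pytest.raises(ValueError, match="unknown"):
        ot.embedded_select(X, y, "boosting", 2)


# ---- voting and pruning ----------------------------------------------------

def _support_table(bools, scores=None):
    methods = ["chi2_filter", "rfe_logistic", "rf_classifier", "rf_regressor", "l1_logistic"]
    n = len(bools)
    tab = pd.DataFrame(index=[f"f{i}" for i in range(n)])
    for j, m in enumerate(methods):
        tab[m] = [row[j] for row in bools]
        tab[f"score_{m}"] = [row[j] for row in (scores or bools)]
    return tab


def test_vote_counts_true_booleans():
    tab = _support_table([[1, 1, 0, 1, 0], [1, 1, 1, 1, 1], [0, 0, 0, 0, 0]])
    ranked = ot.vote_and_rank(tab)
    assert ranked.loc["f0", "vote"] == 3
    assert list(ranked.index[:2]) == ["f1", "f0"]  # vote 5 above vote 3


def test_equal_vote_equal_score_breaks_by_index():
    tab = _support_table([[1, 1, 1, 0, 0], [1, 1, 1, 0, 0]])
    ranked = ot.vote_and_rank(tab)
    assert list(ranked.index) == ["f0", "f1"]


def test_vote_monotonicity_extra_support_never_demotes():
    base = [[1, 1, 0, 0, 0], [1, 1, 0, 0, 0], [1, 0, 0, 0, 0]]
    r1 = ot.vote_and_rank(_support_table(base))
    boosted = [[1, 1, 1, 0, 0], [1, 1, 0, 0, 0], [1, 0, 0, 0, 0]]
    r2 = ot.vote_and_rank(_support_table(boosted))
    assert list(r2.index).index("f0") <= list(r1.index).index("f0")


def test_duplicate_column_dropped_any_threshold():
    rng = np.random.default_rng(8)
    X = pd.DataFrame({"a": rng.normal(size=50)})
    X["b"] = X["a"]
    X["c"] = rng.normal(size=50)
    kept = ot.drop_colinear(["a", "b", "c"], X, r_threshold=1.0)
    assert kept == ["a", "c"]


def test_negated_column_dropped_via_absolute_r():
    rng = np.random.default_rng(9)
    X = pd.DataFrame({"a": rng.normal(size=50)})
    X["neg"] = -X["a"]
    assert ot.drop_colinear(["a", "neg"], X, 0.95) == ["a"]


def test_orthogonal_features_survive_and_zero_variance_kept():
    rng = np.random.default_rng(10)
    X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
    X["const"] = 1.0
    kept = ot.drop_colinear(["a", "b", "c", "const"], X, 0.95)
    assert kept == ["a", "b", "c", "const"]


# ---- end-to-end selection --------------------------------------------------

def _signal_frame(n=80, p=10, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, p))
    X[:, 0] += 2.0 * y
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(p)]), y


def test_candidate_count_contract():
    X, y = _signal_frame()
    res = ot.select_candidates(X, y, SelectionConfig(n_blocks=2, per_block_keep=3,
                                                     export_top=4, seed=0))
    assert len(res.candidates) == 6
    assert len(res.top) == 4
    assert not res.shortfalls


def test_keep_fraction_overrides_fixed_count():
    X, y = _signal_frame()
    res = ot.select_candidates(X, y, SelectionConfig(n_blocks=2, keep_fraction=0.4, seed=0))
    assert len(res.candidates) == 4  # 2 blocks x round(0.4*5)


def test_block_independence_under_within_block_permutation():
    """Permuting features inside a block does not change the selected IDs."""
    X, y = _signal_frame(n=60, p=8, seed=3)
    cfg = SelectionConfig(n_blocks=2, per_block_keep=2, seed=0)
    base = ot.select_candidates(X, y, cfg)
    perm = X[["g3", "g1", "g2", "g0", "g4", "g5", "g6", "g7"]]  # shuffle block 0 only
    permuted = ot.select_candidates(perm, y, cfg)
    assert set(base.candidates) == set(permuted.candidates)


def test_planted_signature_recovered_in_candidates(small_cohort_normalized):
    cfg, X, clinical, truth = small_cohort_normalized
    table = ot.harmonize_sites(clinical)
    ls = ot.build_progression_labels(table, "BRCA", "Liver")
    Xp = X.loc[ls.labels.index]
    res = ot.select_candidates(Xp, ls.labels.to_numpy(),
                               SelectionConfig(n_blocks=6, per_block_keep=10, seed=0))
    sig = set(truth.signatures[("BRCA", "Liver")])
    assert len(sig & set(res.candidates)) / len(sig) >= 0.8


def test_null_recovery_at_chance_rate():
    """On pure noise, 'recovery' of arbitrary planted IDs is at chance level."""
    rng = np.random.default_rng(12)
    p, keep_per, blocks = 200, 5, 4
    X = pd.DataFrame(rng.normal(size=(60, p)), columns=[f"g{i}" for i in range(p)])
    y = np.array([0, 1] * 30)
    res = ot.select_candidates(X, y, SelectionConfig(n_blocks=blocks, per_block_keep=keep_per, seed=0))
    planted = {f"g{i}" for i in rng.choice(p, 20, replace=False)}
    hits = len(planted & set(res.candidates))
    # chance: 20 draws at rate (keep_per*blocks)/p = 0.1 -> binomial 95% bounds
    assert hits <= 7  # P(X >= 8 | B(20, 0.1)) < 0.0005
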