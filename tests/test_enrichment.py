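"""Overrepresentation, the weighted overlap null, and semantic clustering."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

import organotropy as ot
from organotropy.enrichment import (
    GmtAnnotation,
    NullSimConfig,
    observed_significant_overlap,
    sampling_weights,
)


def _annotation(term_sets):
    return GmtAnnotation({t: frozenset(v) for t, v in term_sets.items()})


def test_hand_enumerated_hypergeometric_example():
    """N=20, K=5, n=4, k=3 -> p = (C(5,3)C(15,1)+C(5,4)C(15,0))/C(20,4)."""
    bg = [f"g{i}" for i in range(20)]
    ann = _annotation({"GO:A": bg[:5], "GO:B": bg})  # second term fills the universe
    gene_list = bg[:3] + [bg[10]]
    res = ot.go_overrepresentation(gene_list, ann)
    expected = (comb(5, 3) * comb(15, 1) + comb(5, 4)) / comb(20, 4)
    assert res.loc["GO:A", "p"] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(155 / 4845)


def test_zero_hits_gives_p_one():
    bg = [f"g{i}" for i in range(30)]
    ann = _annotation({"GO:A": bg[:5], "GO:B": bg})
    res = ot.go_overrepresentation(bg[10:14], ann)
    assert res.loc["GO:A", "k"] == 0
    assert res.loc["GO:A", "p"] == pytest.approx(1.0)


def test_full_term_membership_is_extremal():
    bg = [f"g{i}" for i in range(40)]
    ann = _annotation({"GO:A": bg[:4], "GO:B": bg})
    res = ot.go_overrepresentation(bg[:4], ann)
    assert res.loc["GO:A", "k"] == 4
    assert res.loc["GO:A", "p"] == pytest.approx(1 / comb(40, 4), rel=1e-9)


def test_exact_enumeration_oracle_small_universes():
    """Hypergeometric p equals brute-force enumeration for all N <= 50."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        N = int(rng.integers(5, 51))
        bg = [f"g{i}" for i in range(N)]
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        ann = _annotation({"GO:A": bg[:K], "GO:B": bg})
        gene_list = list(rng.choice(bg, n, replace=False))
        k = len(set(gene_list) & set(bg[:K]))
        expected = sum(comb(K, i) * comb(N - K, n - i)
                       for i in range(k, min(K, n) + 1)) / comb(N, n)
        res = ot.go_overrepresentation(gene_list, ann)
        assert res.loc["GO:A", "p"] == pytest.approx(expected, abs=1e-12)


def test_bonferroni_and_kept_flag():
    bg = [f"g{i}" for i in range(100)]
    ann = _annotation({f"GO:{i}": bg[i * 5:(i + 1) * 5] for i in range(20)})
    res = ot.go_overrepresentation(bg[:5], ann)
    assert (res["p_adj"] == np.minimum(1.0, len(ann) * res["p"])).all()
    assert res.loc["GO:0", "kept"]
    assert res["kept"].equals(res["p_adj"] < 0.05)


def test_mapping_multiplicity_and_unannotated_drop():
    bg = [f"g{i}" for i in range(10)]
    ann = _annotation({"GO:A": bg[:4], "GO:B": bg[2:6], "GO:C": bg[3:8]})
    per_tx, agg = ot.map_transcripts_to_go(["g3", "zzz"], ann)
    assert per_tx["g3"] == {"GO:A", "GO:B", "GO:C"}  # 3 memberships
    assert "zzz" not in per_tx
    assert agg == ["GO:A", "GO:B", "GO:C"]


def test_empty_annotated_list_warns_empty_result():
    ann = _annotation({"GO:A": ["g1", "g2"]})
    with pytest.warns(UserWarning, match="no annotated"):
        res = ot.go_overrepresentation(["absent"], ann)
    assert res.empty


# ---- weighted null ---------------------------------------------------------

def test_schedule_arithmetic_matches_full_design():
    cfg = NullSimConfig(reps_per_combination=50_000)
    assert len(cfg.size_pairs) == 15
    assert cfg.total_replicates == 750_000


def test_inverse_multiplicity_weights_ratio(small_annotation):
    """Transcripts mapping to 1 term are drawn twice as often as those with 2."""
    ann, _, _ = small_annotation
    w = sampling_weights(ann)
    m = ann.multiplicity.to_numpy()
    rng = np.random.default_rng(3)
    draws = np.zeros(len(m))
    for _ in range(10_000):
        draws[rng.choice(len(m), 20, replace=False, p=w)] += 1
    ratio = draws[m == 1].mean() / draws[m == 2].mean()
    assert ratio == pytest.approx(2.0, rel=0.1)


def test_uniform_multiplicity_degenerates_to_uniform_sampling():
    bg = [f"g{i}" for i in range(200)]
    ann = _annotation({f"GO:{i}": bg[i * 10:(i + 1) * 10] for i in range(20)})
    assert (ann.multiplicity == 1).all()
    w = sampling_weights(ann)
    rng = np.random.default_rng(4)
    weighted = np.concatenate([rng.choice(200, 10, replace=False, p=w)
                               for _ in range(1000)])
    uniform = np.concatenate([rng.choice(200, 10, replace=False)
                              for _ in range(1000)])
    assert ks_2samp(weighted, uniform).pvalue > 0.01


def test_null_reproducible_and_bounded(small_annotation):
    ann, _, _ = small_annotation
    cfg = NullSimConfig(list_sizes=(50, 100), reps_per_combination=50, seed=9)
    a = ot.weighted_overlap_null(ann, cfg)
    b = ot.weighted_overlap_null(ann, cfg)
    for key in a.overlaps:
        np.testing.assert_array_equal(a.overlaps[key], b.overlaps[key])
        assert (a.overlaps[key] >= 0).all()
    assert set(a.overlaps) == {(50, 50), (50, 100), (100, 100)}


def test_oversized_list_rejected(small_annotation):
    ann, _, _ = small_annotation
    with pytest.raises(ValueError, match="exceeds"):
        ot.weighted_overlap_null(ann, NullSimConfig(list_sizes=(10_000,),
                                                    reps_per_combination=1))


def test_planted_shared_signal_beats_null_random_does_not():
    """Shared-site signatures exceed the null's 95th percentile; random lists do not."""
    cfg = ot.CohortConfig(n_cancer_types=2, samples_per_type=50, n_transcripts=1000,
                          sites=["Liver"], tropism_signature_size=20, effect_size=2.0,
                          positive_fraction=0.25, seed=5)
    _, _, truth = ot.generate_cohort(cfg)
    tx = [f"ENST{i:011d}" for i in range(1, 1001)]
    from organotropy.simulate import GoConfig, generate_go_annotation
    ann, _ = generate_go_annotation(
        GoConfig(n_terms=150, term_size_range=(5, 30), multiplicity_skew=1.0, seed=5),
        tx, seed_sets={f"{c}|{s}": v for (c, s), v in truth.signatures.items()})
    rng = np.random.default_rng(0)
    def padded(pair):
        sig = truth.signatures[pair]
        filler = [t for t in tx if t not in set(sig)]
        return sig + list(rng.choice(filler, 100 - len(sig), replace=False))
    obs = observed_significant_overlap(padded(("BRCA", "Liver")),
                                       padded(("LUAD", "Liver")), ann)
    null = ot.weighted_overlap_null(ann, NullSimConfig(list_sizes=(100,),
                                                       reps_per_combination=200, seed=1))
    q95 = null.q95(100, 100)
    assert obs > q95
    rand = observed_significant_overlap(list(rng.choice(tx, 100, replace=False)),
                                        list(rng.choice(tx, 100, replace=False)), ann)
    assert rand <= q95


# ---- semantic clustering ---------------------------------------------------

TOY_EDGES = [("GO:B", "GO:A"), ("GO:C", "GO:A"),
             ("GO:D", "GO:B"), ("GO:E", "GO:C")]


def test_similarity_unit_diagonal_and_symmetry():
    sim, _ = ot.go_semantic_clusters(["GO:B", "GO:C", "GO:D"], TOY_EDGES)
    np.testing.assert_allclose(np.diag(sim), 1.0)
    np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)


def test_root_only_shared_ancestor_hand_value():
    """D and E share only the root A: |{A}| / |{D,B,A,E,C}| = 1/5."""
    sim, _ = ot.go_semantic_clusters(["GO:D", "GO:E"], TOY_EDGES)
    assert sim.loc["GO:D", "GO:E"] == pytest.approx(1 / 5)


def test_two_planted_term_families_recovered():
    edges = [("GO:root", "GO:top")]
    fam = {}
    for f, hub in (("L", "GO:hubL"), ("R", "GO:hubR")):
        edges.append((hub, "GO:root"))
        for i in range(4):
            t = f"GO:{f}{i}"
            edges.append((t, hub))
            fam[t] = f
    terms = sorted(fam)
    _, labels = ot.go_semantic_clusters(terms, edges, threshold=0.6)
    assert labels.nunique() == 2
    by_family = {f: set(labels[[t for t in terms if fam[t] == f]]) for f in "LR"}
    assert by_family["L"] != by_family["R"]
    assert all(len(v) == 1 for v in by_family.values())


def test_terms_absent_from_dag_excluded():
    sim, labels = ot.go_semantic_clusters(["GO:B", "GO:zzz"], TOY_EDGES)
    assert list(sim.index) == ["GO:B"]


def test_gmt_round_trip(tmp_path, small_annotation):
    ann, _, _ = small_annotation
    path = tmp_path / "ann.gmt"
    ann.to_gmt(path)
    back = GmtAnnotation.from_gmt(path)
    assert back.terms == ann.terms
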