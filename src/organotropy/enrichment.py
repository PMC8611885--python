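"""GO biological-process overrepresentation and the weighted overlap null.

Three pieces live here:

* per-list overrepresentation — a hypergeometric upper-tail test per term
  against the annotated transcript universe, Bonferroni-corrected at 0.05;
* a multiplicity-weighted simulation null for the overlap of two
  significant-term lists: transcript lists are drawn without replacement with
  weight proportional to 1/m_i (m_i = number of terms a transcript maps to),
  so promiscuously annotated transcripts do not inflate chance overlap;
* a simplified semantic-similarity clustering of enriched terms — Jaccard
  index of inclusive ancestor sets in the is_a DAG, clustered by recursive
  bipartition.

The full schedule mirrors 50,000 replicates for each of the 15 unordered
pairs of list sizes {100..500} (750,000 runs); the default is a desk-scale
500 replicates per pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class GmtAnnotation:
    """Term -> transcript-set annotation with a cached membership matrix.

    ``multiplicity[i]`` is the number of terms transcript i belongs to; it
    drives the weighted null sampling.
    """

    def __init__(self, terms: dict[str, frozenset[str]]):
        if not terms:
            raise ValueError("annotation is empty")
        for t, members in terms.items():
            if not members:
                raise ValueError(f"term {t} has no members")
        self.terms = {t: frozenset(v) for t, v in terms.items()}
        self.term_ids = sorted(self.terms)
        self.transcripts = sorted(set().union(*self.terms.values()))
        self._tx_index = {g: i for i, g in enumerate(self.transcripts)}
        M = np.zeros((len(self.term_ids), len(self.transcripts)), dtype=bool)
        for ti, t in enumerate(self.term_ids):
            for g in self.terms[t]:
                M[ti, self._tx_index[g]] = True
        self._M = M
        self.multiplicity = pd.Series(M.sum(axis=0), index=self.transcripts, name="m")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def term_sizes(self) -> np.ndarray:
        return self._M.sum(axis=1)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GmtAnnotation":
        from gseapy.parser import read_gmt
        raw = read_gmt(str(path))
        return cls({t: frozenset(v) for t, v in raw.items()})

    def to_gmt(self, path: str | Path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for t in self.term_ids:
                fh.write("\t".join([t, description, *sorted(self.terms[t])]) + "\n")

    def indicator(self, transcripts) -> np.ndarray:
        """Boolean vector over the annotated universe; unannotated IDs ignored."""
        v = np.zeros(len(self.transcripts), dtype=bool)
        for g in transcripts:
            i = self._tx_index.get(g)
            if i is not None:
                v[i] = True
        return v


def map_transcripts_to_go(transcripts, annotation: GmtAnnotation):
    """Per-transcript term sets plus the aggregate (union) term list.

    Unannotated transcripts are dropped and their count logged.
    """
    per_tx: dict[str, set[str]] = {}
    dropped = 0
    universe = set(annotation.transcripts)
    for g in transcripts:
        if g not in universe:
            dropped += 1
            continue
        per_tx[g] = {t for t, members in annotation.terms.items() if g in members}
    if dropped:
        logger.info("map_transcripts_to_go: dropped %d unannotated transcripts", dropped)
    aggregate = sorted(set().union(*per_tx.values())) if per_tx else []
    return per_tx, aggregate


def go_overrepresentation(gene_list, annotation: GmtAnnotation,
                          alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each term in ``gene_list``.

    For a term of size K in an annotated universe of size N, with n annotated
    list members of which k hit the term, p = P(X >= k) for
    X ~ Hypergeom(N, K, n). Bonferroni over all tested terms; ``kept`` flags
    p_adj < alpha.

    Returns a DataFrame indexed by term id with columns
    k, K, n, N, p, p_adj, kept.
    """
    ind = annotation.indicator(gene_list)
    n = int(ind.sum())
    N = len(annotation.transcripts)
    if n == 0:
        warnings.warn("no annotated transcripts in gene_list; empty enrichment result")
        return pd.DataFrame(columns=["k", "K", "n", "N", "p", "p_adj", "kept"])
    K = annotation.term_sizes
    k = annotation._M.astype(np.int64) @ ind.astype(np.int64)
    p = hypergeom.sf(k - 1, N, K, n)
    m = len(annotation.term_ids)
    p_adj = np.minimum(1.0, m * p)
    return pd.DataFrame(
        {"k": k, "K": K, "n": n, "N": N, "p": p, "p_adj": p_adj, "kept": p_adj < alpha},
        index=pd.Index(annotation.term_ids, name="term_id"),
    )


@dataclass
class NullSimConfig:
    """Schedule of the weighted overlap simulation.

    At the full schedule (reps_per_combination=50,000, five sizes) the total
    is 750,000 replicates; the default desk scale is 500 per combination.
    """

    list_sizes: tuple[int, ...] = (100, 200, 300, 400, 500)
    reps_per_combination: int = 500
    weighting: str = "inverse-multiplicity"
    alpha: float = DEFAULT_ALPHA
    seed: int = 0

    @property
    def size_pairs(self) -> list[tuple[int, int]]:
        return list(combinations_with_replacement(sorted(self.list_sizes), 2))

    @property
    def total_replicates(self) -> int:
        return self.reps_per_combination * len(self.size_pairs)


@dataclass
class OverlapNull:
    """Empirical null of significant-term-list overlaps per size pair."""

    overlaps: dict[tuple[int, int], np.ndarray]
    quantiles: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for (a, b), v in sorted(self.overlaps.items()):
            rows.append({"size_a": a, "size_b": b,
                         "q50": float(np.quantile(v, 0.50)),
                         "q95": float(np.quantile(v, 0.95)),
                         "q99": float(np.quantile(v, 0.99))})
        self.quantiles = pd.DataFrame(rows)

    def q95(self, size_a: int, size_b: int) -> float:
        a, b = min(size_a, size_b), max(size_a, size_b)
        return float(np.quantile(self.overlaps[(a, b)], 0.95))

    def to_tsv(self, path: str | Path) -> None:
        self.quantiles.to_csv(path, sep="\t", index=False)


def sampling_weights(annotation: GmtAnnotation, weighting: str = "inverse-multiplicity") -> np.ndarray:
    m = annotation.multiplicity.to_numpy(dtype=float)
    if weighting == "inverse-multiplicity":
        w = 1.0 / m
    elif weighting == "uniform":
        w = np.ones_like(m)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return w / w.sum()


def _min_hits_for_significance(annotation: GmtAnnotation, n: int, alpha: float) -> np.ndarray:
    """Smallest k per term with Bonferroni-adjusted p < alpha at list size n.

    Precomputing this turns each replicate's two enrichment tests into a
    single vectorized comparison.
    """
    N = len(annotation.transcripts)
    K = annotation.term_sizes
    m = len(annotation.term_ids)
    thr = alpha / m
    kmax = np.minimum(K, n)
    kmin = np.full(len(K), np.iinfo(np.int64).max, dtype=np.int64)
    for ti in range(len(K)):
        ks = np.arange(0, kmax[ti] + 1)
        p = hypergeom.sf(ks - 1, N, K[ti], n)
        ok = np.flatnonzero(p < thr)
        if ok.size:
            kmin[ti] = ks[ok[0]]
    return kmin


def weighted_overlap_null(annotation: GmtAnnotation, cfg: NullSimConfig) -> OverlapNull:
    """Simulate the null distribution of significant-GO-list overlaps.

    Each replicate draws two transcript lists without replacement with weight
    w_i proportional to 1/m_i, runs the overrepresentation test on each, and
    records the number of terms significant in both. A replicate with no
    significant term in either list contributes overlap 0.
    """
    N = len(annotation.transcripts)
    for s in cfg.list_sizes:
        if s > N:
            raise ValueError(f"list size {s} exceeds {N} annotated transcripts")
    rng = np.random.default_rng(cfg.seed)
    w = sampling_weights(annotation, cfg.weighting)
    M = annotation._M
    kmin_cache: dict[int, np.ndarray] = {}
    overlaps: dict[tuple[int, int], np.ndarray] = {}
    for (sa, sb) in cfg.size_pairs:
        for s in (sa, sb):
            if s not in kmin_cache:
                kmin_cache[s] = _min_hits_for_significance(annotation, s, cfg.alpha)
        out = np.empty(cfg.reps_per_combination, dtype=np.int64)
        for r in range(cfg.reps_per_combination):
            ia = rng.choice(N, size=sa, replace=False, p=w)
            ib = rng.choice(N, size=sb, replace=False, p=w)
            sig_a = M[:, ia].sum(axis=1) >= kmin_cache[sa]
            sig_b = M[:, ib].sum(axis=1) >= kmin_cache[sb]
            out[r] = int(np.sum(sig_a & sig_b))
        overlaps[(sa, sb)] = out
    return OverlapNull(overlaps)


def observed_significant_overlap(list_a, list_b, annotation: GmtAnnotation,
                                 alpha: float = DEFAULT_ALPHA) -> int:
    """Number of terms significantly overrepresented in both transcript lists."""
    ra = go_overrepresentation(list_a, annotation, alpha)
    rb = go_overrepresentation(list_b, annotation, alpha)
    sa = set(ra.index[ra["kept"]]) if len(ra) else set()
    sb = set(rb.index[rb["kept"]]) if len(rb) else set()
    return len(sa & sb)


# ---------------------------------------------------------------------------
# semantic-similarity clustering (simplified: ancestor-set Jaccard + binary cut)
# ---------------------------------------------------------------------------

def _ancestor_sets(term_ids, dag_edges) -> dict[str, frozenset[str]]:
    G = nx.DiGraph()
    G.add_edges_from(dag_edges)  # edges child -> parent
    if not nx.is_directed_acyclic_graph(G):
        raise ValueError("term DAG contains a cycle")
    out = {}
    for t in term_ids:
        out[t] = frozenset({t} | nx.descendants(G, t))  # inclusive ancestors
    return out


def go_semantic_clusters(term_ids, dag_edges, threshold: float = 0.6,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise ancestor-Jaccard similarity and recursive-bipartition clusters.

    Similarity of two terms is the Jaccard index of their inclusive is_a
    ancestor sets. Clustering recursively 2-means-splits the similarity rows
    and stops once a cluster's mean off-diagonal similarity reaches
    ``threshold``. Terms absent from the DAG are excluded (logged).
    """
    from sklearn.cluster import KMeans

    G_nodes = set()
    for c, p in dag_edges:
        G_nodes.add(c)
        G_nodes.add(p)
    kept = [t for t in term_ids if t in G_nodes]
    missing = sorted(set(term_ids) - set(kept))
    if missing:
        logger.info("go_semantic_clusters: %d terms absent from DAG excluded", len(missing))
    if not kept:
        raise ValueError("no query term present in the DAG")

    anc = _ancestor_sets(kept, dag_edges)
    n = len(kept)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(anc[kept[i]] & anc[kept[j]])
            union = len(anc[kept[i]] | anc[kept[j]])
            S[i, j] = S[j, i] = inter / union
    sim = pd.DataFrame(S, index=kept, columns=kept)

    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def mean_offdiag(idx: np.ndarray) -> float:
        if idx.size < 2:
            return 1.0
        sub = S[np.ix_(idx, idx)]
        return float((sub.sum() - idx.size) / (idx.size * (idx.size - 1)))

    def split(idx: np.ndarray, depth: int) -> None:
        if mean_offdiag(idx) >= threshold or idx.size < 2 or depth > 32:
            return
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        part = km.fit_predict(S[np.ix_(idx, idx)])
        left, right = idx[part == 0], idx[part == 1]
        if left.size == 0 or right.size == 0:
            return
        labels[right] = next_label[0]
        next_label[0] += 1
        split(left, depth + 1)
        split(right, depth + 1)

    split(np.arange(n), 0)
    # relabel to consecutive ints in first-appearance order
    remap: dict[int, int] = {}
    final = np.array([remap.setdefault(l, len(remap)) for l in labels])
    return sim, pd.Series(final, index=kept, name="cluster")
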