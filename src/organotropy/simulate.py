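"""Synthetic cohort and annotation generator.

Builds desk-scale cohorts with the statistical structure the organotropism
pipeline assumes: negative-binomial transcript counts with cancer-type
signatures (making tumor types separable), per-(cancer, site) tropism
signatures with a standardized log-scale mean shift in metastatic samples,
TCGA-style clinical free-text site columns (messy case/whitespace, multi-site
cells, "synchronous" progression rows), and a GO-like term annotation with a
long-tailed transcript->term multiplicity plus a rooted acyclic term DAG.

Ground truth (which transcripts carry planted signal, which samples are
positive) is emitted as a separate artifact and is never read by the pipeline
itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GmtAnnotation

# Biological (log-scale) noise s.d.; effect sizes are standardized against this.
LOG_NOISE_SD = 0.5

# Canonical site vocabulary with raw free-text variants, to exercise the
# clinical harmonization stage.
SITE_VARIANTS: dict[str, list[str]] = {
    "Bone": ["Bone", "bone", " Bone ", "BONE"],
    "Liver": ["Liver", "liver", "LIVER", " liver"],
    "Lung": ["Lung", "lung", " Lung ", "LUNG"],
    "Lymph Node": ["Lymph Node", "lymph node", "Lymph node", "LYMPH NODE"],
    "Brain": ["Brain", "brain", " Brain "],
}

_CANCER_CODES = [
    "BRCA", "LUAD", "PRAD", "SKCM", "STAD", "BLCA", "HNSC", "KIRC",
    "LIHC", "PAAD", "SARC", "THCA", "ESCA", "KIRP", "LUSC", "CESC",
]


@dataclass
class CohortConfig:
    """Configuration of a synthetic multi-cancer cohort.

    ``effect_size`` is the standardized mean shift (in units of the log-scale
    biological noise s.d.) applied to a pair's signature transcripts in
    samples positive for that pair. ``site_shared_fraction`` of each signature
    is a site-core subset shared by every cancer metastasizing to that site —
    the organotropic structure the downstream recapture and enrichment stages
    look for.
    """

    n_cancer_types: int = 3
    samples_per_type: int = 100
    n_transcripts: int = 2000
    sites: list[str] = field(default_factory=lambda: ["Bone", "Liver", "Lung"])
    tropism_signature_size: int = 20
    effect_size: float = 1.5
    positive_fraction: float = 0.25
    synchronous_fraction: float = 0.1
    noise_dispersion: float = 0.3
    type_signature_size: int = 50
    type_effect_size: float = 2.0
    site_shared_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer_types", "samples_per_type", "n_transcripts",
                     "tropism_signature_size", "type_signature_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0.0 <= self.synchronous_fraction < 1.0:
            raise ValueError("synchronous_fraction must lie in [0, 1)")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be > 0")
        unknown = set(self.sites) - set(SITE_VARIANTS)
        if unknown:
            raise ValueError(f"unknown sites (no raw variants defined): {sorted(unknown)}")


@dataclass
class GoConfig:
    """Configuration of the synthetic GO-BP-like annotation."""

    n_terms: int = 100
    term_size_range: tuple[int, int] = (5, 40)
    multiplicity_skew: float = 1.0
    dag_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not (0 < lo <= hi):
            raise ValueError("term_size_range must satisfy 0 < min <= max")
        if self.n_terms <= 0 or self.dag_depth <= 0:
            raise ValueError("n_terms and dag_depth must be > 0")
        if self.multiplicity_skew < 0:
            raise ValueError("multiplicity_skew must be >= 0")


@dataclass
class GroundTruth:
    """Planted-signal record — written beside the cohort, never consumed by it."""

    signatures: dict[tuple[str, str], list[str]]
    site_cores: dict[str, list[str]]
    type_signatures: dict[str, list[str]]
    positives: dict[tuple[str, str], list[str]]
    synchronous_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "signatures": {f"{c}|{s}": v for (c, s), v in self.signatures.items()},
            "site_cores": self.site_cores,
            "type_signatures": self.type_signatures,
            "positives": {f"{c}|{s}": v for (c, s), v in self.positives.items()},
            "synchronous_ids": self.synchronous_ids,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _transcript_ids(n: int) -> list[str]:
    return [f"ENST{i:011d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression, clinical, ground_truth) for a synthetic cohort.

    Expression is a samples x transcripts count matrix (gamma-Poisson, i.e.
    negative-binomial, with log-scale type/tropism mean shifts). The clinical
    table carries a free-text "metastatic tissue" column and a
    "progression timing" column with "synchronous" rows at the configured
    fraction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tx = _transcript_ids(cfg.n_transcripts)
    cancers = _CANCER_CODES[: cfg.n_cancer_types]
    if cfg.n_cancer_types > len(_CANCER_CODES):
        cancers = cancers + [f"CN{i:02d}" for i in range(cfg.n_cancer_types - len(_CANCER_CODES))]

    n_pairs = len(cancers) * len(cfg.sites)
    core = int(round(cfg.site_shared_fraction * cfg.tropism_signature_size))
    private = cfg.tropism_signature_size - core
    needed = (cfg.n_cancer_types * cfg.type_signature_size
              + len(cfg.sites) * core + n_pairs * private)
    if needed > cfg.n_transcripts:
        raise ValueError(
            f"signatures need {needed} transcripts but only {cfg.n_transcripts} exist; "
            "shrink tropism_signature_size/type_signature_size or add transcripts")

    pool = rng.permutation(cfg.n_transcripts)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor:cursor + k]
        cursor += k
        return out

    type_sig = {c: take(cfg.type_signature_size) for c in cancers}
    site_core = {s: take(core) for s in cfg.sites}
    signatures: dict[tuple[str, str], np.ndarray] = {}
    for c in cancers:
        for s in cfg.sites:
            signatures[(c, s)] = np.concatenate([site_core[s], take(private)])

    # per-transcript baseline log mean (long-tailed count means)
    log_mu0 = rng.normal(3.0, 1.0, size=cfg.n_transcripts)
    # total log-scale s.d. per transcript: biological lognormal noise plus the
    # delta-method approximation of the NB sampling noise, so that effect_size
    # is a standardized (Cohen's d) shift on the observed log-expression scale
    sigma_total = np.sqrt(LOG_NOISE_SD ** 2 + cfg.noise_dispersion + np.exp(-log_mu0))

    sample_ids, rows_cancer = [], []
    for c in cancers:
        for i in range(cfg.samples_per_type):
            sample_ids.append(f"{c}-{i:04d}")
            rows_cancer.append(c)
    n_samples = len(sample_ids)

    # positives drawn independently per (cancer, site)
    n_pos = int(round(cfg.positive_fraction * cfg.samples_per_type))
    positives: dict[tuple[str, str], list[str]] = {}
    pos_mask = {}
    for ci, c in enumerate(cancers):
        base = ci * cfg.samples_per_type
        for s in cfg.sites:
            idx = rng.choice(cfg.samples_per_type, size=n_pos, replace=False)
            mask = np.zeros(n_samples, dtype=bool)
            mask[base + np.sort(idx)] = True
            pos_mask[(c, s)] = mask
            positives[(c, s)] = [sample_ids[j] for j in np.flatnonzero(mask)]

    # log-scale mean per sample
    shift = np.zeros((n_samples, cfg.n_transcripts))
    for ci, c in enumerate(cancers):
        base = ci * cfg.samples_per_type
        shift[base:base + cfg.samples_per_type][:, type_sig[c]] += (
            cfg.type_effect_size * sigma_total[type_sig[c]])
    for (c, s), mask in pos_mask.items():
        sig_idx = signatures[(c, s)]
        shift[np.ix_(mask, sig_idx)] += cfg.effect_size * sigma_total[sig_idx]

    log_mu = (log_mu0[None, :] + shift
              + rng.normal(0.0, LOG_NOISE_SD, size=(n_samples, cfg.n_transcripts)))
    mu = np.exp(log_mu)
    # gamma-Poisson mixture == negative binomial with dispersion phi (var = mu + phi mu^2)
    phi = cfg.noise_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng.poisson(lam)

    expression = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                              columns=tx)

    # clinical table with messy free-text site strings
    met_sites: list[str] = []
    for j, sid in enumerate(sample_ids):
        hits = [s for (c, s), mask in pos_mask.items() if mask[j]]
        raw = [SITE_VARIANTS[s][rng.integers(len(SITE_VARIANTS[s]))] for s in hits]
        met_sites.append("; ".join(raw))
    metastatic = np.array([bool(s) for s in met_sites])
    timing = np.where(metastatic, "metachronous", "")
    met_idx = np.flatnonzero(metastatic)
    n_sync = int(round(cfg.synchronous_fraction * len(met_idx)))
    sync_idx = rng.choice(met_idx, size=n_sync, replace=False) if n_sync else np.array([], int)
    timing = timing.astype(object)
    for j in sync_idx:
        timing[j] = "synchronous"

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "cancer_code": rows_cancer,
        "metastatic tissue": met_sites,
        "progression_timing": timing,
    }).set_index("sample_id")

    truth = GroundTruth(
        signatures={k: [tx[i] for i in v] for k, v in signatures.items()},
        site_cores={s: [tx[i] for i in v] for s, v in site_core.items()},
        type_signatures={c: [tx[i] for i in v] for c, v in type_sig.items()},
        positives=positives,
        synchronous_ids=sorted(sample_ids[j] for j in sync_idx),
    )
    return expression, clinical, truth


def generate_go_annotation(
    config: GoConfig,
    transcript_ids,
    seed_sets: dict[str, list[str]] | None = None,
) -> tuple[GmtAnnotation, list[tuple[str, str]]]:
    """Generate a GO-BP-like annotation (GMT mapping + rooted acyclic DAG).

    Each transcript maps to ``1 + Poisson(skew * Exp(1))`` distinct terms, a
    long-tailed multiplicity with skew=0 degenerating to exactly one term per
    transcript. Undersized terms are repaired by *moving* transcripts from
    oversized terms so the multiplicity distribution is preserved. When
    ``seed_sets`` is given (e.g. planted signature transcripts), extra terms
    concentrating each set are appended so planted signal is enrichable.
    """
    cfg = config
    tx = list(transcript_ids)
    if not tx:
        raise ValueError("transcript_ids must be nonempty")
    lo, hi = cfg.term_size_range
    if lo > len(tx):
        raise ValueError(f"term_size_range min {lo} exceeds {len(tx)} transcripts")
    rng = np.random.default_rng(cfg.seed)

    terms = [f"GO:{i:07d}" for i in range(1, cfg.n_terms + 1)]
    membership: dict[str, set[str]] = {t: set() for t in terms}
    m = 1 + rng.poisson(cfg.multiplicity_skew * rng.exponential(1.0, size=len(tx)))
    m = np.minimum(m, cfg.n_terms)
    for t_id, mult in zip(tx, m):
        for ti in rng.choice(cfg.n_terms, size=int(mult), replace=False):
            membership[terms[ti]].add(t_id)

    # repair undersized terms by moving members out of oversized terms
    for t in terms:
        while len(membership[t]) < lo:
            donors = [d for d in terms if d != t and len(membership[d]) > lo
                      and membership[d] - membership[t]]
            if donors:
                d = donors[int(rng.integers(len(donors)))]
                movable = sorted(membership[d] - membership[t])
                g = movable[int(rng.integers(len(movable)))]
                membership[d].discard(g)
                membership[t].add(g)
            else:  # no donor left: add a fresh random transcript
                candidates = sorted(set(tx) - membership[t])
                membership[t].add(candidates[int(rng.integers(len(candidates)))])

    if seed_sets:
        for name in sorted(seed_sets):
            members = [g for g in seed_sets[name] if g in set(tx)]
            if not members:
                continue
            n_extra = max(1, (len(members) + hi - 1) // hi)
            chunks = np.array_split(np.array(members, dtype=object), n_extra)
            for chunk in chunks:
                tid = f"GO:{len(terms) + 1:07d}"
                terms.append(tid)
                mem = set(chunk.tolist())
                while len(mem) < lo:  # pad tiny chunks with random transcripts
                    mem.add(tx[int(rng.integers(len(tx)))])
                membership[tid] = mem

    annotation = GmtAnnotation({t: frozenset(v) for t, v in membership.items()})

    # rooted acyclic DAG over term ids: levels 1..dag_depth, edges child -> parent
    root = "GO:0008150"
    levels = {t: int(rng.integers(1, cfg.dag_depth + 1)) for t in terms}
    by_level: dict[int, list[str]] = {0: [root]}
    for t in terms:
        by_level.setdefault(levels[t], []).append(t)
    present = sorted(k for k in by_level if k > 0)
    edges: list[tuple[str, str]] = []
    for t in terms:
        lvl = levels[t]
        lower = [k for k in present if k < lvl]
        parent_level = lower[-1] if lower else 0
        parents = by_level[parent_level]
        edges.append((t, parents[int(rng.integers(len(parents)))]))
        # occasional second parent from any strictly lower level keeps it a DAG
        if rng.random() < 0.3:
            cand_levels = [k for k in ([0] + present) if k < lvl]
            kl = cand_levels[int(rng.integers(len(cand_levels)))]
            p2 = by_level[kl][int(rng.integers(len(by_level[kl])))]
            if p2 != t and (t, p2) not in edges:
                edges.append((t, p2))
    return annotation, edges


def write_cohort(out_dir: str | Path, expression: pd.DataFrame,
                 clinical: pd.DataFrame, truth: GroundTruth | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expression.to_csv(out / "expression.tsv", sep="\t")
    clinical.to_csv(out / "clinical.tsv", sep="\t")
    if truth is not None:
        truth.save(out / "ground_truth.json")


def write_dag_edges(edges, path: str | Path) -> None:
    pd.DataFrame(edges, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def read_dag_edges(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["child"], df["parent"]))
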