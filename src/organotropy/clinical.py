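"""Clinical-table harmonization and progression-label construction.

TCGA-style clinical files record distant metastases as free text under one of
several column names ("metastatic tissue", "sites of metastases", "metastatic
tissue site"), with inconsistent case, stray whitespace and multi-site cells.
This module canonicalizes those strings, excludes rows whose progression
timing is "synchronous" (the clinical ordering of primary and metastasis is
ambiguous there), decomposes the cohort into per-(cancer, site) binary label
sets, and filters to analyzable pairs: at least 8 positive annotations for a
site and a total population strictly over 50.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

RECOGNIZED_SITE_COLUMNS = ("metastatic tissue", "sites of metastases", "metastatic tissue site")
SITE_DELIMITERS = (";", ",", "|")
TIMING_COLUMN = "progression_timing"
HARMONIZED_COLUMN = "harmonized_sites"
COADREAD_CODES = ("COAD", "READ")


@dataclass
class PairFilterConfig:
    """Thresholds for retaining a (cancer, site) pair.

    "at least eight" positives is read as >= 8 and "over fifty" patients as a
    strict > 50.
    """

    min_site_annotations: int = 8
    min_population: int = 50
    merge_coadread: bool = True

    def __post_init__(self) -> None:
        if self.min_site_annotations < 1 or self.min_population < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass
class ProgressionLabelSet:
    """Binary progression outcome for one (cancer, site) pair."""

    cancer_code: str
    site: str
    labels: pd.Series  # index: sample id, values 0/1
    n_pos: int
    n_total: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.cancer_code, self.site)


def _canonical_site(raw: str) -> str:
    s = re.sub(r"\s+", " ", raw.strip())
    return s.title() if s else ""


def _split_sites(cell: str, delimiters=SITE_DELIMITERS) -> list[str]:
    parts = re.split("|".join(map(re.escape, delimiters)), cell)
    out = []
    for p in parts:
        c = _canonical_site(p)
        if c and c not in out:
            out.append(c)
    return out


def harmonize_sites(table: pd.DataFrame, delimiters=SITE_DELIMITERS) -> pd.DataFrame:
    """Canonicalize metastatic-site free text into ``harmonized_sites``.

    Site strings are trimmed, whitespace-collapsed and title-cased; multi-site
    cells are split on ``delimiters``. Rows whose timing contains
    "synchronous" get ``synchronous=True`` and are excluded from metastatic
    labeling downstream. Idempotent: re-harmonizing a harmonized table is a
    no-op.
    """
    cols = [c for c in table.columns if c.strip().lower() in RECOGNIZED_SITE_COLUMNS]
    if HARMONIZED_COLUMN in table.columns:
        cols = [HARMONIZED_COLUMN]
    if not cols:
        raise ValueError(
            "no recognized metastatic-site column; expected one of "
            f"{RECOGNIZED_SITE_COLUMNS}")
    out = table.copy()
    merged: list[str] = []
    for _, row in out.iterrows():
        sites: list[str] = []
        for c in cols:
            cell = row[c]
            if isinstance(cell, str) and cell.strip():
                for s in _split_sites(cell, delimiters):
                    if s not in sites:
                        sites.append(s)
        merged.append(";".join(sorted(sites)))
    out[HARMONIZED_COLUMN] = merged
    if "synchronous" in out.columns:
        sync = out["synchronous"].astype(bool)
    elif TIMING_COLUMN in out.columns:
        sync = out[TIMING_COLUMN].fillna("").astype(str).str.lower().str.contains("synchronous")
    else:
        sync = pd.Series(False, index=out.index)
    out["synchronous"] = sync
    return out


def merge_coadread(table: pd.DataFrame, code_column: str = "cancer_code") -> pd.DataFrame:
    """Collapse COAD and READ project codes into a single COADREAD cohort."""
    out = table.copy()
    out[code_column] = out[code_column].replace({c: "COADREAD" for c in COADREAD_CODES})
    return out


def build_progression_labels(table: pd.DataFrame, cancer_code: str, site: str,
                             code_column: str = "cancer_code") -> ProgressionLabelSet:
    """Binary labels for one pair: 1 iff ``site`` is among a sample's sites.

    Requires a harmonized table. Synchronous rows contribute to neither
    class. A site absent from the cohort yields n_pos = 0, which is valid.
    """
    if HARMONIZED_COLUMN not in table.columns:
        raise ValueError("table is not harmonized; call harmonize_sites first")
    sub = table[(table[code_column] == cancer_code) & ~table["synchronous"].astype(bool)]
    canon = _canonical_site(site)
    labels = sub[HARMONIZED_COLUMN].fillna("").map(
        lambda cell: int(canon in cell.split(";")) if cell else 0)
    labels.name = f"{cancer_code}|{canon}"
    return ProgressionLabelSet(cancer_code, canon, labels,
                               n_pos=int(labels.sum()), n_total=int(len(labels)))


def enumerate_pairs(table: pd.DataFrame, code_column: str = "cancer_code") -> list[tuple[str, str]]:
    """All (cancer, site) pairs with at least one positive annotation."""
    if HARMONIZED_COLUMN not in table.columns:
        raise ValueError("table is not harmonized; call harmonize_sites first")
    pairs = set()
    ok = ~table["synchronous"].astype(bool)
    for code, cell in zip(table.loc[ok, code_column], table.loc[ok, HARMONIZED_COLUMN]):
        if isinstance(cell, str) and cell:
            for s in cell.split(";"):
                pairs.add((code, s))
    return sorted(pairs)


def filter_pairs(label_sets, cfg: PairFilterConfig | None = None) -> pd.DataFrame:
    """Pair catalog of label sets passing both population thresholds.

    Keeps a pair iff n_pos >= min_site_annotations and n_total >
    min_population; sorted by (cancer, site). An empty catalog is allowed.
    """
    cfg = cfg or PairFilterConfig()
    rows = []
    for ls in label_sets:
        if ls.n_pos >= cfg.min_site_annotations and ls.n_total > cfg.min_population:
            rows.append({"cancer_code": ls.cancer_code, "site": ls.site,
                         "n_pos": ls.n_pos, "n_total": ls.n_total})
    cat = pd.DataFrame(rows, columns=["cancer_code", "site", "n_pos", "n_total"])
    return cat.sort_values(["cancer_code", "site"]).reset_index(drop=True)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
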