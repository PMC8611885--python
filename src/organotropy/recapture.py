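"""Fisher's exact recapture statistics for selected-feature lists.

Independently derived top-feature lists (across metastatic sites within a
cancer, or across cancers seeding the same site) are tested for
greater-than-chance overlap against a shared background — the full
transcriptome, since every selection started from all transcripts. The 2x2
table is [[a, b], [c, d]] with a = |A∩B|, b = |A\\B|, c = |B\\A|,
d = N - a - b - c; the p-value is the one-sided (enrichment) hypergeometric
upper tail, Bonferroni-corrected across tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from scipy.stats import fisher_exact as _scipy_fisher


@dataclass
class ContingencyTable:
    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # N - a - b - c
    N: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d != self.N:
            raise ValueError("cells must sum to the background size")


@dataclass
class OverlapTestResult:
    table: ContingencyTable
    odds_ratio: float  # math.inf when b*c == 0 and a*d > 0
    p: float
    p_adj: float | None = None

    @property
    def odds_ratio_str(self) -> str:
        return "Inf" if math.isinf(self.odds_ratio) else f"{self.odds_ratio:.6g}"


def fisher_overlap(list_a, list_b, background_ids, *, alternative: str = "greater",
                   haldane: bool = False) -> OverlapTestResult:
    """One-sided Fisher's exact test of the overlap of two ID lists.

    Both lists must be subsets of the background; duplicates are removed.
    The default alternative "greater" tests for enrichment of the overlap;
    ``haldane`` adds the 0.5 continuity correction to the odds ratio only.
    """
    A, B = set(list_a), set(list_b)
    bg = set(background_ids)
    stray = (A | B) - bg
    if stray:
        raise ValueError(f"ids outside background: {sorted(stray)[:10]}")
    N = len(bg)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    tab = ContingencyTable(a, b, c, d, N)

    if haldane:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    elif b * c == 0:
        orr = math.inf if a * d > 0 else 0.0
    else:
        orr = (a * d) / (b * c)
    if a == 0:
        orr = 0.0 if not haldane else orr

    if alternative == "greater":
        # upper tail of Hypergeom(N, |A|, |B|) at the observed overlap
        p = float(hypergeom.sf(a - 1, N, a + b, a + c))
    elif alternative == "two-sided":
        p = float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return OverlapTestResult(tab, orr, min(p, 1.0))


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p) elementwise; m defaults to the number of tests."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def recapture_matrix(lists: dict[str, list[str]], background_ids) -> "pd.DataFrame":
    """All pairwise overlap tests among named lists, Bonferroni-adjusted."""
    import pandas as pd

    names = sorted(lists)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            r = fisher_overlap(lists[na], lists[nb], background_ids)
            rows.append({"list_a": na, "list_b": nb, "a": r.table.a, "b": r.table.b,
                         "c": r.table.c, "d": r.table.d,
                         "odds_ratio": r.odds_ratio_str, "p": r.p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bonferroni_adjust(df["p"])
    return df
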