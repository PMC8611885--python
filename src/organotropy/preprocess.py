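"""Expression normalization used throughout the pipeline.

Counts are library-size normalized to counts-per-million and log1p
transformed. The generator is normalization-agnostic; this is the pipeline's
choice and every stage (selection, classification, SMOTE distances) operates
on this scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p counts-per-million per sample (rows = samples)."""
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    cpm = counts.to_numpy(dtype=float) / lib[:, None] * 1e6
    return pd.DataFrame(np.log1p(cpm), index=counts.index, columns=counts.columns)
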