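import numpy as np
import pandas as pd
import pytest

import organotropy as ot
from organotropy.preprocess import log_cpm
from organotropy.simulate import GoConfig, generate_go_annotation


@pytest.fixture(scope="session")
def small_cohort():
    """3 cancer types x 80 samples x 600 transcripts, one site, strong signal."""
    cfg = ot.CohortConfig(n_cancer_types=3, samples_per_type=80, n_transcripts=600,
                          sites=["Liver"], tropism_signature_size=10, effect_size=2.0,
                          positive_fraction=0.25, type_signature_size=30, seed=7)
    expr, clinical, truth = ot.generate_cohort(cfg)
    return cfg, expr, clinical, truth


@pytest.fixture(scope="session")
def small_cohort_normalized(small_cohort):
    cfg, expr, clinical, truth = small_cohort
    return cfg, log_cpm(expr), clinical, truth


@pytest.fixture(scope="session")
def small_annotation():
    """150-term annotation over 1000 transcript ids with a long-tailed multiplicity."""
    tx = [f"ENST{i:011d}" for i in range(1, 1001)]
    ann, edges = generate_go_annotation(
        GoConfig(n_terms=150, term_size_range=(5, 30), multiplicity_skew=1.0, seed=5), tx)
    return ann, edges, tx


@pytest.fixture
def toy_clinical():
    """Hand-written messy clinical table exercising harmonization."""
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(10)],
        "cancer_code": ["BRCA"] * 6 + ["COAD"] * 2 + ["READ"] * 2,
        "metastatic tissue": [" Lung ", "lung", "Liver; Lung", "", "bone", "",
                              "Liver", "", "liver", ""],
        "progression_timing": ["metachronous", "", "synchronous", "", "metachronous",
                               "", "metachronous", "", "", ""],
    }).set_index("sample_id")


def rng(seed=0):
    return np.random.default_rng(seed)
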