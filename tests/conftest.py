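import numpy as np
import pandas as pd
import pytest

import lncscape as L


@pytest.fixture
def rng():
    return np.random.default_rng(20161234)


@pytest.fixture
def small_matrix():
    """5 transcripts x 6 samples FPKM matrix with metadata."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(rng.gamma(2.0, 5.0, size=(5, 6)),
                          index=[f"T{i}" for i in range(5)],
                          columns=[f"S{i}" for i in range(6)])
    transcripts = pd.DataFrame({
        "length_bp": [1000, 2000, 1500, 800, 3000],
        "biotype": ["lncRNA", "protein_coding", "lncRNA",
                    "protein_coding", "protein_coding"],
    }, index=values.index)
    samples = pd.DataFrame({
        "cohort": ["tumor"] * 4 + ["normal"] * 2,
        "er_status": ["positive", "positive", "negative", "negative", "NA", "NA"],
        "pam50": ["LumA", "LumB", "Basal", "Her2", "NA", "NA"],
    }, index=values.columns)
    return L.ExpressionMatrix(values, "FPKM", transcripts=transcripts, samples=samples)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted cohort shared by read-only tests."""
    cfg = L.CohortConfig(seed=42)
    return cfg, *L.simulate_cohort(cfg)
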