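import numpy as np
import pandas as pd
import pytest

from sitelearn.cohort import CohortConfig, generate_cohort
from sitelearn.table import SubjectTable


@pytest.fixture(scope="session")
def small_cohort():
    """Six equal sites, mild diagnosis signal, light missingness."""
    cfg = CohortConfig(
        n_sites=6, site_size_range=(50, 50), case_fraction=0.5,
        diagnosis_effect=(20, 0.5), medication_effect=(20, 0.5),
        missing_rate=0.01, heavy_missing_fraction=0.02, seed=101,
    )
    table, gt = generate_cohort(cfg)
    return table, gt, cfg


@pytest.fixture(scope="session")
def clean_cohort():
    """No missingness; used where masks would get in the way."""
    cfg = CohortConfig(
        n_sites=5, site_size_range=(40, 40), case_fraction=0.5,
        diagnosis_effect=(10, 0.6), medication_effect=(10, 0.4),
        missing_rate=0.0, heavy_missing_fraction=0.0, seed=202,
    )
    table, gt = generate_cohort(cfg)
    return table, gt, cfg


def make_toy_table(n=12, p=6, n_sites=2, seed=0, missing=()):
    """Tiny hand-adjustable table for contract tests."""
    rng = np.random.default_rng(seed)
    dx = [(i // n_sites) % 2 for i in range(n)]  # alternates within each site
    meta = pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "site_id": [f"site{i % n_sites}" for i in range(n)],
        "diagnosis": dx,
        "age": rng.uniform(10, 60, n),
        "sex": ["M" if i % 3 else "F" for i in range(n)],
        "medicated": [float(i % 4 == 2) if dx[i] else np.nan for i in range(n)],
        "ybocs": [float(20 + i % 10) if dx[i] else np.nan for i in range(n)],
        "age_of_onset": [float(10 + i % 15) if dx[i] else np.nan for i in range(n)],
        "illness_duration": [float(3 + i % 9) if dx[i] else np.nan for i in range(n)],
    })
    X = rng.normal(size=(n, p))
    feats = pd.DataFrame(X, columns=[f"feat{j}" for j in range(p)])
    for i, j in missing:
        feats.iat[i, j] = np.nan
    return SubjectTable(meta, feats)
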