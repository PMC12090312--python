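import numpy as np
import pandas as pd
import pytest

from fndconn.connectome_io import COHORT_COLUMNS


def make_cohort(n_fnd: int, n_hc: int, rng: np.random.Generator) -> pd.DataFrame:
    """Minimal valid cohort table with random demographics and mood scores."""
    n = n_fnd + n_hc
    group = ["FND"] * n_fnd + ["HC"] * n_hc
    fnd = np.array([g == "FND" for g in group])
    df = pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "group": group,
        "age": rng.uniform(20, 60, n),
        "sex": rng.choice(["female", "male"], n),
        "medication_any_psychotropic": fnd & (rng.random(n) < 0.4),
        "bdi": rng.uniform(0, 30, n),
        "stai_state": rng.uniform(20, 60, n),
        "stai_trait": rng.uniform(20, 60, n),
        "sf36_physical_health": rng.uniform(0, 100, n),
        "sf36_mental_health": rng.uniform(0, 100, n),
        "sf36_general_health": rng.uniform(0, 100, n),
        "sf36_physical_functioning": rng.uniform(0, 100, n),
        "sfmdrs": np.where(fnd, rng.uniform(0, 30, n), np.nan),
        "cgi": np.where(fnd, rng.integers(0, 8, n).astype(float), np.nan),
        "illness_duration_months": np.where(fnd, rng.uniform(1, 120, n), np.nan),
    })
    return df[COHORT_COLUMNS]


def random_symmetric_fa(rng: np.random.Generator, n: int = 84) -> np.ndarray:
    """Random symmetric FA-like matrix with zero diagonal, values in (0, 1)."""
    upper = rng.uniform(0.05, 0.9, size=(n, n))
    mat = np.triu(upper, k=1)
    return mat + mat.T


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
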