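import numpy as np
import pandas as pd
import pytest

from hiequity import generate, preset_charls_like


def make_records(n: int = 8, **overrides) -> pd.DataFrame:
    """Small hand-controllable respondent table with valid defaults."""
    base = {
        "outpatient": [0, 1] * (n // 2) + [0] * (n % 2),
        "inpatient": [0] * n,
        "gender": [1, 0] * (n // 2) + [1] * (n % 2),
        "age": [50 + i for i in range(n)],
        "self_health": [1 + (i % 5) for i in range(n)],
        "chronic": [i % 2 for i in range(n)],
        "married": [1] * n,
        "education": [i % 4 for i in range(n)],
        "income": [10.0 * (i + 1) for i in range(n)],
        "region": ["east", "central", "west"] * (n // 3) + ["east"] * (n % 3),
        "community": [0] * n,
        "scheme": ["URRBMI", "NCMS"] * (n // 2) + ["URRBMI"] * (n % 2),
        "weight": [1.0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def preset_dataset():
    """One realization of the frozen survey preset (full study size)."""
    cfg = preset_charls_like()
    cfg.seed = 7
    records, truth = generate(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150801)
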