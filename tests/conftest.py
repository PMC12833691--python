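import numpy as np
import pandas as pd
import pytest

from opineq import GeneratorConfig, generate, preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_records():
    """A small synthetic patient table shared across tests."""
    return generate(GeneratorConfig(n=3000, seed=7, env_share=0.3))


@pytest.fixture(scope="session")
def small_prep(small_records):
    return preprocess(small_records)


@pytest.fixture
def toy_records():
    """Five diagnosis groups of sizes 10, 30, 31, 100, 2 (all age >= 45)."""
    sizes = {"I100": 10, "I200": 30, "I300": 31, "I400": 100, "I500": 2}
    rows = []
    rng = np.random.default_rng(0)
    for code, size in sizes.items():
        for _ in range(size):
            rows.append({"age": 50.0, "icd10_group": code,
                         "primary_dx": int(rng.integers(1, 5)),
                         "total_expenses": float(rng.lognormal(9, 0.5))})
    return pd.DataFrame(rows)
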