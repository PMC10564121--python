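import numpy as np
import pandas as pd
import pytest

from polydev.cohort import build_pairs, standardize


def bivariate_pairs(n: int, rho: float, seed: int) -> pd.DataFrame:
    """Standardized pairs with (population) correlation rho."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    ids = np.array([f"id{i}" for i in range(n)], dtype=object)
    return build_pairs(ids, standardize(x), standardize(y))


def raw_pairs(ids, ps, pheno) -> pd.DataFrame:
    """Pair table without enforcing the standardisation contract (for
    constructed classifier fixtures)."""
    return pd.DataFrame(
        {"individual_id": np.asarray(ids, dtype=object), "ps_z": ps, "pheno_z": pheno}
    )


@pytest.fixture(scope="session")
def null_pairs():
    """A mid-sized null cohort shared by classifier unit tests."""
    return bivariate_pairs(20_000, 0.562, seed=7)
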