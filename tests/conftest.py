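import numpy as np
import pandas as pd
import pytest

from irgpi import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-sample, 50-gene cohort with the default planted signature."""
    spec = CohortSpec(n_samples=100, n_genes=50, seed=11)
    return simulate_cohort(spec)


@pytest.fixture()
def toy_expression():
    """4 genes x 6 samples with distinct values (no ties)."""
    rng = np.random.default_rng(3)
    vals = rng.uniform(1, 100, size=(4, 6))
    return pd.DataFrame(
        vals, index=["GA", "GB", "GC", "GD"], columns=[f"s{i}" for i in range(6)]
    )


def monotone_distort_per_sample(expr: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Apply an independent strictly increasing transform to every sample."""
    rng = np.random.default_rng(seed)
    out = expr.copy()
    for j, col in enumerate(out.columns):
        a = rng.uniform(0.5, 3.0)
        b = rng.uniform(-0.5, 2.0)
        kind = j % 3
        x = out[col].to_numpy()
        if kind == 0:
            out[col] = a * x + b + 1.0
        elif kind == 1:
            out[col] = np.exp(a * np.log(x + 1.0) + b)
        else:
            out[col] = np.sqrt(x) * a + b
    return out
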