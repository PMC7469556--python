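import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from adiposcan.datamodel import ExpressionMatrix, SampleTable
from adiposcan.synthetic import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, hand-set log2 values."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[8.0, 8.5, 9.0, 7.5], [6.0, 6.1, 5.9, 6.0], [10.0, 9.0, 11.0, 10.5]],
            index=["LMNA", "PPARG", "AKT2"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def small_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "group": ["control", "control", "case", "case"],
                "sex": ["M", "F", "M", "F"],
                "LDL": [90.0, 95.0, 110.0, 105.0],
            },
            index=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic cohort shared across tests."""
    cfg = SimulationConfig(seed=11)
    return cfg, simulate_dataset(cfg)


def two_group_matrix(
    rng: np.random.Generator,
    n_genes: int = 200,
    n_per_group: int = 30,
    sigma: float = 0.5,
    delta_genes: dict[int, float] | None = None,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Plain two-group Gaussian matrix with optional per-gene case shifts."""
    n = 2 * n_per_group
    x = 8.0 + rng.normal(0.0, sigma, size=(n_genes, n))
    for gi, d in (delta_genes or {}).items():
        x[gi, n_per_group:] += d
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"c{i:02d}" for i in range(n_per_group)] + [
        f"d{i:02d}" for i in range(n_per_group)
    ]
    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))
    tab = SampleTable(
        pd.DataFrame(
            {"group": ["control"] * n_per_group + ["case"] * n_per_group},
            index=samples,
        )
    )
    return expr, tab
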