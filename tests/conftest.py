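import numpy as np
import pandas as pd
import pytest

from m6ascape.io import ExpressionMatrix
from m6ascape.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A mid-size two-cohort simulated dataset shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_samples=100, seed=13))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(
        SimulationConfig(n_samples=40, n_background_genes=50, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def expr_2x2(tmp_path):
    p = tmp_path / "expr.tsv"
    p.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\n")
    return p


def make_expression(values: np.ndarray, prefix_g="g", prefix_s="s") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values,
        index=[f"{prefix_g}{i}" for i in range(values.shape[0])],
        columns=[f"{prefix_s}{j}" for j in range(values.shape[1])]))
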