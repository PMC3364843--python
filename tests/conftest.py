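import numpy as np
import pandas as pd
import pytest

from methbench import MethylationMatrix, Phenotype, SimulationConfig, simulate_beta_matrix


@pytest.fixture(scope="session")
def small_binary_study():
    """A modest signal-bearing binary study shared across read-only tests."""
    cfg = SimulationConfig(
        n_features=3000, n_true=300, target_effect_size=1.5, n_per_group=30, seed=101
    )
    return simulate_beta_matrix(cfg)


@pytest.fixture(scope="session")
def null_binary_study():
    cfg = SimulationConfig(n_features=3000, n_true=0, n_per_group=30, seed=103)
    return simulate_beta_matrix(cfg)


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        np.array(
            [
                [0.10, 0.20, 0.30, 0.40, 0.50, 0.60],
                [0.80, 0.70, 0.60, 0.30, 0.20, 0.10],
                [0.50, 0.50, 0.50, 0.50, 0.50, 0.50],
            ]
        ),
        index=["cg000", "cg001", "cg002"],
        columns=[f"S{i}" for i in range(6)],
    )
    return MethylationMatrix(values, "beta")


@pytest.fixture
def tiny_binary_phenotype():
    return Phenotype(
        pd.Series([0, 0, 0, 1, 1, 1], index=[f"S{i}" for i in range(6)]), "binary"
    )
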