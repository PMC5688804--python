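import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_cfg():
    """A fast but complete scenario configuration for end-to-end tests."""
    from tnbc_targets.simulate import SimulationConfig

    return SimulationConfig(
        n_tnbc=30,
        n_nontnbc=60,
        n_normal=20,
        n_genes=600,
        n_up=60,
        n_down=60,
        n_common_up=15,
        n_common_down=10,
        n_probes=800,
        n_islands=80,
        n_protein_genes=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scenario(small_sim_cfg):
    from tnbc_targets.simulate import simulate_scenario

    return simulate_scenario(small_sim_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def expression_fixture():
    """Tiny counts matrix with two clearly shifted genes (a, b) at 4x."""
    from tnbc_targets.io import ExpressionMatrix

    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(8)]
    base = rng.poisson(100, size=(20, 8)).astype(float)
    base[0, :4] *= 4
    base[1, :4] /= 4
    return ExpressionMatrix(pd.DataFrame(base, index=genes, columns=samples), unit="counts")
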