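import matplotlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mtrc

matplotlib.use("Agg")

settings.register_profile(
    "mtrc",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mtrc")


@pytest.fixture(scope="session")
def mtrc4_design() -> mtrc.MixtureDesign:
    return mtrc.MixtureDesign.mtrc4()


@pytest.fixture(scope="session")
def mtrc3_design() -> mtrc.MixtureDesign:
    return mtrc.MixtureDesign.mtrc3()


#: desk-scale simulation settings shared by most tests (smaller array than
#: the default study conditions, same structure)
@pytest.fixture(scope="session")
def small_config() -> mtrc.SimulationConfig:
    return mtrc.SimulationConfig(
        n_probes=3000,
        n_selective={"HBRR": 120, "liver": 90, "UHRR": 70, "skeletal muscle": 60},
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_noise_run(small_config, mtrc4_design):
    """Matrix + truth + fitted results for sd = 0, no floor/ceiling."""
    config = small_config.replace(
        noise_sd=0.0, background_floor=None, saturation_ceiling=None, seed=5
    )
    matrix, truth = mtrc.simulate_mix_experiment(config, mtrc4_design, n_replicates=3)
    results = mtrc.run_benchmark(matrix, truth, mtrc4_design)
    return matrix, truth, results


@pytest.fixture(scope="session")
def noisy_run(small_config, mtrc4_design):
    """Default-style compressed, noisy run at desk scale."""
    matrix, truth = mtrc.simulate_mix_experiment(small_config, mtrc4_design, n_replicates=3)
    results = mtrc.run_benchmark(matrix, truth, mtrc4_design)
    return matrix, truth, results


def make_matrix(values, probes=None, samples=None, roles=None) -> mtrc.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    return mtrc.ExpressionMatrix(data, roles)
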