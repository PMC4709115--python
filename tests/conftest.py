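import numpy as np
import pytest

import mkdfe as M


@pytest.fixture(scope="session")
def neutral_dataset():
    """A large neutral-truth dataset (theta=0.01, f_neutral=0.4, A=0)."""
    params = M.ModelParams(
        theta=0.02, r=np.ones(7), T=0.08, A=0.0,
        dfe=M.make_dfe("neutral", f_neutral=0.4),
    )
    scenario = M.SimScenario(params=params, n_chrom=8, L_N=1_000_000.0,
                             L_S=1_000_000.0, seed=11, label="neutral")
    return scenario, M.sample_dataset(scenario, 0)


@pytest.fixture(scope="session")
def gamma_dataset():
    """Moderate-size Gamma-truth dataset with a divergence excess A."""
    params = M.ModelParams(
        theta=0.01, r=np.ones(5), T=0.1, A=300.0,
        dfe=M.make_dfe("gamma", shape=0.5, mean_del=800.0),
    )
    scenario = M.SimScenario(params=params, n_chrom=6, L_N=300_000.0,
                             L_S=300_000.0, seed=23, label="gamma")
    return scenario, M.sample_dataset(scenario, 0)


@pytest.fixture(scope="session")
def gamma_fit(gamma_dataset):
    _, ds = gamma_dataset
    return M.fit(ds, "gamma", restarts=2, seed=1)
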