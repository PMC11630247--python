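import numpy as np
import pytest

import sysmap as sm

#: fixed basis domains matching the generator's physical ranges, so fitted
#: coefficient vectors are directly comparable with generating ones
DOMAINS = {"TR": (0.0, 6.0), "VWC": (0.0, 0.5)}


@pytest.fixture(scope="session")
def baseline():
    return sm.default_baseline_model()


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario dataset (32 x 5, 6 days, 3-min grid, 200 SNPs)."""
    return sm.simulate_population(sm.ScenarioConfig(seed=101))


@pytest.fixture(scope="session")
def small_sim():
    """A light dataset for IO/CLI tests: 6 lines x 2 reps, 4 days, 30-min grid."""
    cfg = sm.ScenarioConfig(
        n_genotypes=6, n_replicates=2, days=4, grid_minutes=30.0, n_snps=15, seed=7
    )
    return sm.simulate_population(cfg)


def theta_vector(model: sm.SystemModel) -> np.ndarray:
    """All coefficients of a two-trait model in a fixed order."""
    parts = [model.independent[t].theta for t in model.traits]
    parts += [model.dependent[p].theta for p in sorted(model.dependent)]
    return np.concatenate(parts)
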