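import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort for fast end-to-end exercises."""
    from phenoscreen.simulate import SimulationConfig

    return SimulationConfig(seed=7, n_wt=12, n_mut=14, n_genes=300, n_signature=30)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from phenoscreen.simulate import generate_cohort

    return generate_cohort(small_config)


@pytest.fixture()
def toy_phenotypes():
    """Three animals x two traits x two timepoints, hand-valued."""
    rows = []
    vals = {
        ("a1", "rotarod", "wk11"): 50.0, ("a1", "rotarod", "wk13"): 30.0,
        ("a2", "rotarod", "wk11"): 40.0, ("a2", "rotarod", "wk13"): 40.0,
        ("a3", "rotarod", "wk11"): 60.0, ("a3", "rotarod", "wk13"): 55.0,
        ("a1", "weight", "wk11"): 25.0, ("a1", "weight", "wk13"): 26.0,
        ("a2", "weight", "wk11"): 27.0, ("a2", "weight", "wk13"): 27.5,
        ("a3", "weight", "wk11"): 26.0, ("a3", "weight", "wk13"): 28.0,
    }
    for (aid, trait, tp), v in vals.items():
        rows.append((aid, "mut", "litter1", trait, tp, v))
    return pd.DataFrame(
        rows, columns=["animal_id", "genotype", "litter", "trait", "timepoint", "value"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
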