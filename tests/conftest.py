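import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import beechsurv as bs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-plot synthetic forest shared by prep/report tests."""
    cfg = bs.SimulationConfig(
        seed=7, n_plots=20, n_transects=8, stems_per_subplot=2.5
    )
    return bs.simulate_forest(cfg)


@pytest.fixture(scope="session")
def small_obs(small_dataset):
    obs, _ = bs.assemble_observations(small_dataset.trees, small_dataset.plots)
    return obs


@pytest.fixture(scope="session")
def small_fit(small_obs):
    """A quick selected-model fit on the small forest (shared, read-only)."""
    est = bs.BayesianTreeSurvival(
        seed=11, chains=3, iterations=900, burn_in=300, thin=3
    )
    with np.errstate(all="ignore"):
        est.fit(small_obs)
    return est


def make_degenerate_fit(columns_values: dict, n_obs: int = 4) -> bs.PosteriorFit:
    """A single-draw posterior container for degenerate-case tests."""
    draws = pd.DataFrame({k: [v] for k, v in columns_values.items()})
    return bs.PosteriorFit(
        draws=draws,
        pointwise_loglik=np.zeros((1, n_obs), dtype=np.float32),
        chains=1,
        iterations=1,
        burn_in=0,
        thin=1,
        seed=0,
        spec=bs.ModelSpec.selected(),
        plot_ids=[],
        rhat=pd.Series(dtype=float),
        ess=pd.Series(dtype=float),
        convergence_warnings=[],
    )


@pytest.fixture()
def degenerate_fit_factory():
    return make_degenerate_fit
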