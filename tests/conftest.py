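import warnings

import numpy as np
import pandas as pd
import pytest

import edattrib as ea
from edattrib.features import build_lag_design
from edattrib.gam import fit_gam


@pytest.fixture(autouse=True)
def _quiet_extrapolation_warnings():
    """Basis-reduction / extrapolation warnings are expected in bulk fits."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside the training range.*")
        warnings.filterwarnings("ignore", message=".*reducing basis dimension.*")
        yield


@pytest.fixture(scope="session")
def exposures_261():
    return ea.generate_exposures(n_weeks=261, seed=1)


@pytest.fixture(scope="session")
def resp_truth():
    return ea.default_truth("Respiratory infection")


@pytest.fixture(scope="session")
def resp_fit(exposures_261, resp_truth):
    """One full 3-lag Poisson fit on a synthetic respiratory-infection series."""
    adm = ea.generate_admissions(exposures_261, resp_truth, seed=2)
    design = build_lag_design(adm, exposures_261, max_lag=3)
    model = fit_gam(design, "poisson")
    return model, design


@pytest.fixture(scope="session")
def single_smooth_fit():
    """Small single-smooth Poisson fit with a known sinusoidal log-rate."""
    rng = np.random.default_rng(7)
    n = 261
    x = rng.uniform(0.0, 1.0, n)
    eta = np.log(150.0) + 0.3 * np.sin(2 * np.pi * x)
    y = rng.poisson(np.exp(eta))
    X = pd.DataFrame({"x": x})
    from edattrib.basis import SmoothSpec
    from edattrib.gam import CountGAM

    model = CountGAM(terms=[SmoothSpec("x", k=8)]).fit(X, y)
    return model, X, y
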