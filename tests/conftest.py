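import numpy as np
import pytest
from hypothesis import settings

from pentafit.dose_response import HillFit

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from pentafit.synthetic import DoseResponseScenario, simulate_dose_response


@pytest.fixture()
def hek_wildtype_truth() -> HillFit:
    """Hill truth resembling a 1:1-transfected wild-type receptor."""
    return HillFit(i_max=6.67, ec50=91.1, n_h=1.65)


@pytest.fixture()
def noiseless_cells(hek_wildtype_truth):
    scen = DoseResponseScenario(
        true_hill=hek_wildtype_truth, noise_cv=0.0, rundown_per_application=0.0, n_cells=3
    )
    cells, truth = simulate_dose_response(scen, seed=1)
    return cells, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
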