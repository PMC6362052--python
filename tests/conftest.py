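import numpy as np
import pytest

from episeg import synth
from episeg.config import default_config
from episeg.pipeline import run_experiment


@pytest.fixture(scope="session")
def small_phantom():
    return synth.make_phantom((24, 24, 8), n_cortical=3, n_subcortical=3,
                              seed=7)


@pytest.fixture(scope="session")
def small_fieldmap(small_phantom):
    return synth.make_fieldmap(small_phantom, peak_hz=60.0, width_mm=3.0,
                               seed=7)


@pytest.fixture(scope="session")
def desk_report(tmp_path_factory):
    """One full two-arm desk-scale experiment, shared across tests."""
    out = tmp_path_factory.mktemp("desk")
    cfg = default_config()
    return run_experiment(cfg, out, save_images=False)


def constant_volume(value=10.0, shape=(4, 4, 2), n_t=16, tr=2.0):
    return synth.Volume4D(np.full(shape + (n_t,), float(value)),
                          (1.0, 1.0, 1.0), tr)
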