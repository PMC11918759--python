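import numpy as np
import pytest

from fnirscad import synth
from fnirscad.montage import build_default_montage


@pytest.fixture(scope="session")
def montage68():
    return build_default_montage(68)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, variability-free single-class configuration."""
    return synth.SyntheticCohortConfig(
        n_mdd=0,
        n_hc=1,
        noise=synth.NoiseModel.zero(),
        amp_subject_sd=0.0,
        pair_gain_sd=0.0,
        emit_od=True,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_subject(clean_config):
    return synth.generate_subject(clean_config, synth.HC, 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
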