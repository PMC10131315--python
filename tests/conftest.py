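import numpy as np
import pytest

from cardioclamp import synthdata as sd


@pytest.fixture(scope="session")
def wt_model() -> sd.GatingModel:
    return sd.wt_gating_model()


@pytest.fixture(scope="session")
def ap_trace_clean():
    """Noiseless 10-s AP train at the WT feature targets."""
    spec = sd.APWaveformSpec(rate_bpm=60.0, apd50_ms=209.9, apd90_ms=253.6,
                             amplitude_mV=114.8, mdp_mV=-72.0, seed=11)
    return spec, sd.simulate_ap_train(spec, duration_s=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
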