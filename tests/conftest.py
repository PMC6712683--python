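import numpy as np
import pytest

from oursoft.synthetic import NoiseConfig, SimConfig, simulate_fedbatch

#: dynamic temperature schedule giving conductivity variation
DYNAMIC_SCHEDULE = ((0.0, 37.0), (72.0, 34.0), (120.0, 37.0), (192.0, 31.0))


@pytest.fixture(scope="session")
def noiseless_run():
    """Static 37 C fed-batch without measurement noise (shared, read-only)."""
    return simulate_fedbatch(SimConfig(noise=NoiseConfig.noiseless()))


@pytest.fixture(scope="session")
def noisy_dynamic_run():
    """Fed-batch with temperature shifts and default channel noise."""
    return simulate_fedbatch(
        SimConfig(temp_schedule=DYNAMIC_SCHEDULE, duration_h=240.0)
    )


@pytest.fixture(scope="session")
def softsensor_trace(noiseless_run):
    from oursoft.our import our_softsensor_trace

    truth = noiseless_run.truth
    return our_softsensor_trace(
        noiseless_run.records(), truth.kla_model, truth.solubility
    )
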