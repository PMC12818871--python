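import numpy as np
import pytest

from cortexkit.network import (NeuronParams, PopulationSpec, build_surrogate,
                               default_populations)


@pytest.fixture(scope="session")
def small_network():
    """9 x 50 surrogate used by fast simulation tests."""
    return build_surrogate(default_populations(50), seed=7)


@pytest.fixture(scope="session")
def full_network():
    """The 9 x 200 surrogate of the calibration study conditions."""
    return build_surrogate(default_populations(200), seed=7)


@pytest.fixture()
def two_pop_network():
    pops = [
        PopulationSpec(name="L4_E", synapse_class="E", count=10,
                       depth_range=(665.0, 865.0),
                       neuron_params=NeuronParams(threshold_jitter_sd=0.0)),
        PopulationSpec(name="L23_E", synapse_class="E", count=10,
                       depth_range=(165.0, 665.0),
                       neuron_params=NeuronParams(threshold_jitter_sd=0.0)),
    ]
    return build_surrogate(pops, {"p_conn": 1.0}, seed=3)
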