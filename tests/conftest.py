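import numpy as np
import pytest

from gifgain import InputModel, NeuronParameters, sigma_I_for_rate, tau_s

#: running example: resonator with an intrinsic frequency near 19 Hz
DEFAULT = NeuronParameters(tau_V=10.0, g=3.0, tau_w=20.0, theta=1.0)
TAU_I = 1.0


@pytest.fixture(scope="session")
def default_neuron() -> NeuronParameters:
    return DEFAULT


@pytest.fixture(scope="session")
def default_drive(default_neuron) -> InputModel:
    """Noise level calibrated so that nu_0 * tau_s = 0.01 (sparse spiking)."""
    ts = tau_s(default_neuron, InputModel(tau_I=TAU_I, sigma_I=1.0))
    sigma = sigma_I_for_rate(default_neuron, TAU_I, 0.01 / ts)
    return InputModel(tau_I=TAU_I, sigma_I=sigma)


def random_stable_neurons(rng: np.random.Generator, n: int):
    """Random stable parameter sets spanning several decades of timescales."""
    tau_V = 10.0 ** rng.uniform(0, 2, n)
    tau_w = 10.0 ** rng.uniform(-0.5, 2.5, n)
    g = np.where(
        rng.random(n) < 0.3,
        rng.uniform(-0.95, 0.0, n),  # depolarizing branch
        10.0 ** rng.uniform(-1.5, 1.0, n),
    )
    return [NeuronParameters(tau_V=tv, g=gv, tau_w=tw)
            for tv, gv, tw in zip(tau_V, g, tau_w)]
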