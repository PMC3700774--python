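import numpy as np
import pytest

import ciliamotion as cm
from ciliamotion.movie import MovieStack


@pytest.fixture(scope="session")
def renal_scenario():
    return cm.get_scenario("renal_anesthetized")


@pytest.fixture(scope="session")
def renal_sim(renal_scenario):
    """Noisy simulated movie + ground-truth traces, seed 1."""
    return cm.simulate_field(renal_scenario)


@pytest.fixture(scope="session")
def noiseless_renal(renal_scenario):
    """Noiseless rendered movie + truth traces (no Poisson sampling)."""
    frames, truth = cm.render_movie(renal_scenario)
    stack = MovieStack(frames=frames, fps=renal_scenario.fps, source="synthetic-noiseless")
    return stack, truth


@pytest.fixture(scope="session")
def renal_analysis(renal_sim):
    """Full-chain analysis of the noisy seed-1 movie."""
    stack, _ = renal_sim
    return cm.analyze_movie(stack)


@pytest.fixture(scope="session")
def renal_analytic_trace(renal_scenario):
    return cm.angle_trace(renal_scenario)


def dense_sinusoid_trace(freq=0.01, amplitude=53.0, center=90.0, n=10**6, dt=1e-3):
    """Sinusoidal angle trace sampled over an integer number of cycles."""
    t = np.arange(n) * dt
    return cm.AngleTrace(t, center + amplitude * np.sin(2 * np.pi * freq * t))
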