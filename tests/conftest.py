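import numpy as np
import pytest

from memperm.synthgen import CallablePmf, sample_umbrella_window


@pytest.fixture(scope="session")
def flat_pmf():
    return CallablePmf(lambda z: np.zeros_like(z), z_range=(-1.2, 1.2))


@pytest.fixture(scope="session")
def harmonic_pmf():
    """½κz² generating potential, κ = 10 kJ mol⁻¹ nm⁻²."""
    return CallablePmf(lambda z: 0.5 * 10.0 * z**2, z_range=(-1.2, 1.2))


def make_windows(model, centers, k=3000.0, n=5000, seed0=0, dt=1.0):
    """Umbrella windows at the given centers with per-window derived seeds."""
    return [
        sample_umbrella_window(model, z0=z0, k=k, n=n, seed=seed0 + i, dt=dt)
        for i, z0 in enumerate(centers)
    ]
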