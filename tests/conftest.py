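"""Shared fixtures: small analytic models used across the unit tests."""

import numpy as np
import pytest

from hopdyn.models import ModelSystem


def _two_state_1d(label, v11, v22, v12, dv11, dv22, dv12, mass=2000.0):
    def diabatic(R):
        x = np.asarray(R, dtype=float)[..., 0]
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = v11(x)
        out[..., 1, 1] = v22(x)
        out[..., 0, 1] = out[..., 1, 0] = v12(x)
        return out

    def gradient(R):
        x = np.asarray(R, dtype=float)[..., 0]
        out = np.empty(x.shape + (2, 2))
        out[..., 0, 0] = dv11(x)
        out[..., 1, 1] = dv22(x)
        out[..., 0, 1] = out[..., 1, 0] = dv12(x)
        return out[..., None, :, :]

    return ModelSystem(label=label, n_states=2, n_dof=1,
                       masses=np.array([mass]), diabatic=diabatic,
                       diabatic_gradient=gradient)


@pytest.fixture(scope="session")
def flat_model():
    """Two flat uncoupled surfaces separated by 0.5 Ha (free motion)."""
    z = np.zeros_like
    return _two_state_1d("flat", z, lambda x: np.full_like(x, 0.5), z, z, z, z)


@pytest.fixture(scope="session")
def flat_gap_model():
    """Two flat uncoupled surfaces separated by 0.01 Ha (spawn tests)."""
    z = np.zeros_like
    return _two_state_1d("flat_gap", z, lambda x: np.full_like(x, 0.01),
                         z, z, z, z)


@pytest.fixture(scope="session")
def harmonic_model():
    """Parallel harmonic surfaces (omega^2 m = k = 0.005), gap 0.2 Ha."""
    k = 0.005
    z = np.zeros_like
    return _two_state_1d(
        "harmonic",
        lambda x: 0.5 * k * x * x, lambda x: 0.5 * k * x * x + 0.2, z,
        lambda x: k * x, lambda x: k * x, z)
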