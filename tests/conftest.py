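import numpy as np
import pytest

from dsoct import GNRBatch, OpticalConfig, PhantomSpec, make_phantom_stack


@pytest.fixture(scope="session")
def optics_62k5():
    """Standard stationary-sample acquisition: 62.5 kHz, 800 nm, n=1.33."""
    return OpticalConfig(
        center_wavelength_nm=800.0,
        refractive_index=1.33,
        aline_period_s=1.6e-5,
        depth_pixel_um=1.5,
    )


@pytest.fixture(scope="session")
def optics_250k():
    """Fast acquisition (250 kHz) capturing short rotational decays."""
    return OpticalConfig(aline_period_s=4e-6)


@pytest.fixture(scope="session")
def batch_68x19():
    return GNRBatch(length_nm=68.0, width_nm=19.0)


@pytest.fixture(scope="session")
def uniform_stack(optics_62k5):
    """Homogeneous phantom with comfortable decay times at 62.5 kHz."""
    spec = PhantomSpec.uniform(
        2.0, 2000.0, 64, surface_index=10, noise_level=0.05, n_times=20000, seed=42
    )
    return make_phantom_stack(spec, optics_62k5)


def analytic_curves(q, dt_coef, dr_coef, lags):
    """Exact field autocorrelations of the rod scattering model."""
    trans = np.exp(-(q * q) * dt_coef * lags)
    rot = np.exp(-6.0 * dr_coef * lags)
    g_hh = trans * (5.0 / 9.0 + 4.0 / 9.0 * rot)
    g_hv = trans * rot
    return g_hh, g_hv
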