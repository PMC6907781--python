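import numpy as np
import pytest

from hpflux.kinetics import KineticParams, simulate_dynamics
from hpflux.phantom import AcqParams, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def acq_params() -> AcqParams:
    return AcqParams()


@pytest.fixture(scope="session")
def calibrated_curves():
    """Default-parameter dynamics on the standard 0-90 s grid."""
    return simulate_dynamics(KineticParams(), t_end=90.0, dt=0.1)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def spectrum_fwhm_hz(spec) -> float:
    """Half-max crossing width of the tallest absorption-mode peak.

    Uses the real part (the magnitude of a complex Lorentzian is
    sqrt(3) wider than its absorption line); linear interpolation of
    the crossings.
    """
    mag = spec.values.real
    i = int(np.argmax(mag))
    half = mag[i] / 2
    lo = i
    while lo > 0 and mag[lo] > half:
        lo -= 1
    hi = i
    while hi < len(mag) - 1 and mag[hi] > half:
        hi += 1
    f = spec.ppm * spec.f0_mhz
    f_lo = np.interp(half, [mag[lo], mag[lo + 1]], [f[lo], f[lo + 1]])
    f_hi = np.interp(half, [mag[hi], mag[hi - 1]], [f[hi], f[hi - 1]])
    return float(f_hi - f_lo)
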