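import numpy as np
import pytest

from fructanuf import SolutePair, UFSystemSpec
from fructanuf.datasets import MEMBRANE_AREA_M2, pilot_design_table, pilot_flux_params


@pytest.fixture(scope="session")
def design():
    return pilot_design_table()


@pytest.fixture(scope="session")
def flux_params():
    return pilot_flux_params()


@pytest.fixture
def batch_spec(flux_params):
    """Reference batch scenario: 100 L of the low-ratio feed batch."""
    return UFSystemSpec(
        area=MEMBRANE_AREA_M2,
        v0=0.1,
        c0=SolutePair(fc=71.6, fos=17.1),
        ro=SolutePair(fc=0.795, fos=0.55),
        flux_params=flux_params,
    )


def rk4_trajectory(spec, t_end, dt):
    """Fixed-step classical RK4 on the 3-state balances (independent oracle)."""
    from fructanuf import rhs

    y = np.array([spec.v0, spec.c0.fc, spec.c0.fos])
    ts, ys = [0.0], [y.copy()]
    t = 0.0
    while t < t_end - 1e-12:
        h = min(dt, t_end - t)
        k1 = rhs(y, spec)
        k2 = rhs(y + h / 2 * k1, spec)
        k3 = rhs(y + h / 2 * k2, spec)
        k4 = rhs(y + h * k3, spec)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        ts.append(t)
        ys.append(y.copy())
    return np.array(ts), np.array(ys)
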