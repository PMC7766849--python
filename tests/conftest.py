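"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the package's matrix-exponential propagation:
``rk4_profile`` integrates the ODE system with a fixed-step classical
Runge-Kutta scheme, and ``cyclic_steady_state`` uses the closed-form periodic
fixed point.  Both exist only to cross-check the implementation.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from buppk import ThetaSet
from buppk.model_core import MG_TO_UG, build_rate_matrix


@pytest.fixture(scope="session")
def theta():
    return ThetaSet()


def rk4_profile(theta, doses, times, step=1e-3):
    """Fixed-step RK4 integration of the compartment ODEs; doses are bolus
    additions to the depot.  Returns concentrations shaped (len(times), 4)."""
    A = build_rate_matrix(theta)
    vols = theta.volumes
    events = sorted(doses, key=lambda d: d.time)
    x = np.zeros(7)
    t = 0.0
    out = np.empty((len(times), 4))

    def integrate_to(x, t, t_end):
        while t < t_end - 1e-12:
            h = min(step, t_end - t)
            k1 = A @ x
            k2 = A @ (x + 0.5 * h * k1)
            k3 = A @ (x + 0.5 * h * k2)
            k4 = A @ (x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        return x

    di = 0
    for i, tobs in enumerate(times):
        while di < len(events) and events[di].time < tobs:
            x = integrate_to(x, t, events[di].time)
            t = events[di].time
            x[0] += events[di].amount_mg * MG_TO_UG
            di += 1
        x = integrate_to(x, t, tobs)
        t = tobs
        out[i] = x[[2, 4, 5, 6]] / vols
        while di < len(events) and events[di].time == tobs:
            x[0] += events[di].amount_mg * MG_TO_UG
            di += 1
    return out


def cyclic_steady_state(theta, dose_mg, tau):
    """Closed-form pre-dose steady state of the periodic map s -> P(s + d)."""
    P = expm(build_rate_matrix(theta) * tau)
    d = np.zeros(7)
    d[0] = dose_mg * MG_TO_UG
    return np.linalg.solve(np.eye(7) - P, P @ d)


def random_theta(rng, spread=0.5):
    """A random positive parameter set scattered around the defaults."""
    base = ThetaSet().as_array()
    return ThetaSet.from_array(base * np.exp(rng.normal(0.0, spread, base.size)))
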