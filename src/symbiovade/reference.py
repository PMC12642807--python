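"""Fixed-step 4th-order Runge-Kutta reference integrators.

These exist as an independent cross-check on the adaptive solver: same
equations, different numerical route.  The reduced-system kernel is compiled
with numba because reference runs use very small steps (1e-4), i.e. millions
of RHS evaluations per trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core_model import ModelParams, ReducedParams, compute_Q
from .dynamics import _full_rhs_raw

__all__ = ["rk4_reduced", "rk4_full"]


@njit(cache=False)
def _rk4_reduced_kernel(p0, m0, horizon, h, r_p, Q_p, Q_m, mu_p, mu_m, d):
    n = int(round(horizon / h))
    p = p0
    m = m0

    for _ in range(n):
        # k1
        den = p / d + m
        s = p * m / den if den > 0.0 else 0.0
        k1p = r_p * p + s * Q_p - mu_p * p * p
        k1m = s * Q_m - mu_m * m * m
        # k2
        p2 = p + 0.5 * h * k1p
        m2 = m + 0.5 * h * k1m
        den = p2 / d + m2
        s = p2 * m2 / den if den > 0.0 else 0.0
        k2p = r_p * p2 + s * Q_p - mu_p * p2 * p2
        k2m = s * Q_m - mu_m * m2 * m2
        # k3
        p3 = p + 0.5 * h * k2p
        m3 = m + 0.5 * h * k2m
        den = p3 / d + m3
        s = p3 * m3 / den if den > 0.0 else 0.0
        k3p = r_p * p3 + s * Q_p - mu_p * p3 * p3
        k3m = s * Q_m - mu_m * m3 * m3
        # k4
        p4 = p + h * k3p
        m4 = m + h * k3m
        den = p4 / d + m4
        s = p4 * m4 / den if den > 0.0 else 0.0
        k4p = r_p * p4 + s * Q_p - mu_p * p4 * p4
        k4m = s * Q_m - mu_m * m4 * m4

        p = p + (h / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        m = m + (h / 6.0) * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
    return p, m


def rk4_reduced(rp: ReducedParams, init, horizon: float, h: float = 1e-4) -> np.ndarray:
    """Final (p, m) after a fixed-step RK4 integration of the reduced system."""
    p0, m0 = (float(v) for v in init)
    Q_p, Q_m = compute_Q(rp)
    p, m = _rk4_reduced_kernel(
        p0, m0, float(horizon), float(h),
        rp.r_p, Q_p, Q_m, rp.mu_p, rp.mu_m, rp.d,
    )
    return np.array([p, m])


def rk4_full(params: ModelParams, init, horizon: float, h: float = 1e-3) -> np.ndarray:
    """Final state after a fixed-step RK4 integration of the full system.

    Pure-Python loop; intended for short test horizons, not production runs.
    """
    y = np.asarray(tuple(init), dtype=float)
    n = int(round(horizon / h))
    for _ in range(n):
        k1 = _full_rhs_raw(y, params)
        k2 = _full_rhs_raw(y + 0.5 * h * k1, params)
        k3 = _full_rhs_raw(y + 0.5 * h * k2, params)
        k4 = _full_rhs_raw(y + h * k3, params)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
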