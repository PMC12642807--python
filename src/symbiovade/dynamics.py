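"""Numerical integration, equilibrium location, and linear stability.

The exchange fluxes are rational functions of the state, smooth everywhere
except the all-zero origin, so the systems are integrated with an adaptive
stiff-capable solver (LSODA) at tight tolerances (rtol=1e-9, atol=1e-12) so
that downstream extinction-threshold decisions (1e-6 relative) sit far above
solver noise.  Equilibria are located with a hybrid Newton iteration using the
analytic Jacobian and classified by the eigenvalues of that Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .core_model import ModelParams, ReducedParams, compute_Q

__all__ = [
    "Trajectory",
    "Equilibrium",
    "ConvergenceResult",
    "IntegrationError",
    "integrate",
    "find_equilibrium",
    "jacobian",
    "run_to_convergence",
    "RTOL",
    "ATOL",
    "CONV_TOL",
]

RTOL = 1e-9
ATOL = 1e-12
#: ||rhs||_inf below which the system is declared at equilibrium
CONV_TOL = 1e-10
#: trajectory components above this (negative) floor are solver noise and
#: are clipped to zero on output
NEG_CLIP = -1e-9

Params = Union[ModelParams, ReducedParams]


class IntegrationError(RuntimeError):
    """Solver failure; carries the partial trajectory if one exists."""

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class Trajectory:
    """Time series of states with solver metadata."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), dim)
    columns: tuple[str, ...]
    converged: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def final(self) -> np.ndarray:
        return self.y[-1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.y, columns=list(self.columns)).assign(t=self.t)[
            ["t", *self.columns]
        ]


@dataclass
class Equilibrium:
    """A root of the RHS with its linear-stability classification."""

    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stability: str  # "stable" | "unstable" | "marginal"


@dataclass
class ConvergenceResult:
    state: np.ndarray
    converged: bool
    limit_cycle: bool
    t_end: float


# ---------------------------------------------------------------------------
# raw RHS evaluations (no nonnegativity checks: adaptive solvers probe
# slightly negative states; the fluxes remain well defined there)


def _full_rhs_raw(x: np.ndarray, pr: ModelParams) -> np.ndarray:
    p_n, m_n, p_i, m_i = x
    D_a = (p_n + p_i) / pr.d + m_n + m_i
    D_b = p_n + p_i + pr.d * (m_n + m_i)
    if D_a > 0.0 and D_b > 0.0:
        A_n = pr.alpha_nn * m_n + pr.alpha_in * m_i
        B_n = pr.beta_nn * m_n + pr.beta_ni * m_i
        G_n = pr.beta_nn * p_n + pr.beta_in * p_i
        H_n = pr.alpha_nn * p_n + pr.alpha_ni * p_i
        A_i = pr.alpha_ni * m_n + pr.alpha_ii * m_i
        B_i = pr.beta_in * m_n + pr.beta_ii * m_i
        G_i = pr.beta_ni * p_n + pr.beta_ii * p_i
        H_i = pr.alpha_in * p_n + pr.alpha_ii * p_i
        F_pn = pr.q_hpn * p_n * A_n / D_a - pr.q_cpn * p_n * B_n / D_b
        F_mn = pr.q_cmn * m_n * G_n / D_b - pr.q_hmn * m_n * H_n / D_a
        F_pi = pr.q_hpi * p_i * A_i / D_a - pr.q_cpi * p_i * B_i / D_b
        F_mi = pr.q_cmi * m_i * G_i / D_b - pr.q_hmi * m_i * H_i / D_a
    else:
        F_pn = F_mn = F_pi = F_mi = 0.0
    return np.array(
        [
            pr.r_pn * p_n + F_pn - pr.c_p_in * p_n * p_i - pr.mu_pn * p_n * p_n,
            F_mn - pr.c_m_in * m_n * m_i - pr.mu_mn * m_n * m_n,
            pr.r_pi * p_i + F_pi - pr.c_p_ni * p_n * p_i - pr.mu_pi * p_i * p_i,
            F_mi - pr.c_m_ni * m_n * m_i - pr.mu_mi * m_i * m_i,
        ]
    )


def _reduced_rhs_raw(x: np.ndarray, rp: ReducedParams, Q: tuple[float, float]) -> np.ndarray:
    p, m = x
    denom = p / rp.d + m
    s = p * m / denom if denom > 0 else 0.0
    Q_p, Q_m = Q
    return np.array(
        [rp.r_p * p + s * Q_p - rp.mu_p * p * p, s * Q_m - rp.mu_m * m * m]
    )


def _make_rhs(params: Params):
    if isinstance(params, ModelParams):
        return 4, ("p_n", "m_n", "p_i", "m_i"), lambda t, y: _full_rhs_raw(y, params)
    if isinstance(params, ReducedParams):
        Q = compute_Q(params)
        return 2, ("p", "m"), lambda t, y: _reduced_rhs_raw(y, params, Q)
    raise TypeError(f"params must be ModelParams or ReducedParams, got {type(params)!r}")


# ---------------------------------------------------------------------------
# analytic Jacobians


def _ratio_term_grad(J_row, sign, q, s_idx, x, coefs, N, D, Dgrad):
    """Accumulate d/dx_k of sign*q*x[s_idx]*N/D into a Jacobian row.

    N = coefs . x is linear; D is a positive linear denominator with constant
    gradient Dgrad.
    """
    xs = x[s_idx]
    J_row[s_idx] += sign * q * N / D
    J_row += sign * q * xs * (np.asarray(coefs) / D - N * np.asarray(Dgrad) / (D * D))


def _full_jacobian_analytic(x: np.ndarray, pr: ModelParams) -> np.ndarray:
    p_n, m_n, p_i, m_i = x
    D_a = (p_n + p_i) / pr.d + m_n + m_i
    D_b = p_n + p_i + pr.d * (m_n + m_i)
    Dg_a = (1.0 / pr.d, 1.0, 1.0 / pr.d, 1.0)
    Dg_b = (1.0, pr.d, 1.0, pr.d)
    J = np.zeros((4, 4))

    # p_n row: +q_hpn p_n A_n/D_a  - q_cpn p_n B_n/D_b
    A_n = (0.0, pr.alpha_nn, 0.0, pr.alpha_in)
    B_n = (0.0, pr.beta_nn, 0.0, pr.beta_ni)
    _ratio_term_grad(J[0], +1, pr.q_hpn, 0, x, A_n, np.dot(A_n, x), D_a, Dg_a)
    _ratio_term_grad(J[0], -1, pr.q_cpn, 0, x, B_n, np.dot(B_n, x), D_b, Dg_b)
    J[0, 0] += pr.r_pn - pr.c_p_in * p_i - 2.0 * pr.mu_pn * p_n
    J[0, 2] += -pr.c_p_in * p_n

    # m_n row: +q_cmn m_n G_n/D_b - q_hmn m_n H_n/D_a
    G_n = (pr.beta_nn, 0.0, pr.beta_in, 0.0)
    H_n = (pr.alpha_nn, 0.0, pr.alpha_ni, 0.0)
    _ratio_term_grad(J[1], +1, pr.q_cmn, 1, x, G_n, np.dot(G_n, x), D_b, Dg_b)
    _ratio_term_grad(J[1], -1, pr.q_hmn, 1, x, H_n, np.dot(H_n, x), D_a, Dg_a)
    J[1, 1] += -pr.c_m_in * m_i - 2.0 * pr.mu_mn * m_n
    J[1, 3] += -pr.c_m_in * m_n

    # p_i row: +q_hpi p_i A_i/D_a - q_cpi p_i B_i/D_b
    A_i = (0.0, pr.alpha_ni, 0.0, pr.alpha_ii)
    B_i = (0.0, pr.beta_in, 0.0, pr.beta_ii)
    _ratio_term_grad(J[2], +1, pr.q_hpi, 2, x, A_i, np.dot(A_i, x), D_a, Dg_a)
    _ratio_term_grad(J[2], -1, pr.q_cpi, 2, x, B_i, np.dot(B_i, x), D_b, Dg_b)
    J[2, 2] += pr.r_pi - pr.c_p_ni * p_n - 2.0 * pr.mu_pi * p_i
    J[2, 0] += -pr.c_p_ni * p_i

    # m_i row: +q_cmi m_i G_i/D_b - q_hmi m_i H_i/D_a
    G_i = (pr.beta_ni, 0.0, pr.beta_ii, 0.0)
    H_i = (pr.alpha_in, 0.0, pr.alpha_ii, 0.0)
    _ratio_term_grad(J[3], +1, pr.q_cmi, 3, x, G_i, np.dot(G_i, x), D_b, Dg_b)
    _ratio_term_grad(J[3], -1, pr.q_hmi, 3, x, H_i, np.dot(H_i, x), D_a, Dg_a)
    J[3, 3] += -pr.c_m_ni * m_n - 2.0 * pr.mu_mi * m_i
    J[3, 1] += -pr.c_m_ni * m_i

    return J


def _reduced_jacobian_analytic(x: np.ndarray, rp: ReducedParams) -> np.ndarray:
    p, m = x
    Q_p, Q_m = compute_Q(rp)
    denom = p / rp.d + m
    # ds/dp, ds/dm of s = p*m/(p/d + m)
    ds_dp = (m * m) / (denom * denom)
    ds_dm = (p * p / rp.d) / (denom * denom)
    return np.array(
        [
            [rp.r_p + Q_p * ds_dp - 2.0 * rp.mu_p * p, Q_p * ds_dm],
            [Q_m * ds_dp, Q_m * ds_dm - 2.0 * rp.mu_m * m],
        ]
    )


def _fd_jacobian(f, x: np.ndarray, lower_bound: float = 0.0) -> np.ndarray:
    """One-sided/central finite differences, respecting the x >= 0 boundary."""
    n = len(x)
    J = np.zeros((n, n))
    scale = max(1.0, float(np.max(np.abs(x))))
    h = 1e-7 * scale
    for k in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[k] += h
        if x[k] - h >= lower_bound:
            xm[k] -= h
            J[:, k] = (f(xp) - f(xm)) / (2 * h)
        else:
            J[:, k] = (f(xp) - f(x)) / h
    return J


def jacobian(params: Params, state) -> np.ndarray:
    """Jacobian of the RHS at ``state`` (analytic partial derivatives).

    The fluxes are rational functions, smooth wherever the shared denominators
    are positive (everywhere except the all-zero origin); at the origin a
    one-sided finite-difference stencil is used instead.
    """
    x = np.asarray(tuple(state), dtype=float)
    if isinstance(params, ModelParams):
        D_a = (x[0] + x[2]) / params.d + x[1] + x[3]
        if D_a > 0:
            return _full_jacobian_analytic(x, params)
        return _fd_jacobian(lambda y: _full_rhs_raw(np.maximum(y, 0.0), params), x)
    if isinstance(params, ReducedParams):
        if x[0] / params.d + x[1] > 0:
            return _reduced_jacobian_analytic(x, params)
        Q = compute_Q(params)
        return _fd_jacobian(lambda y: _reduced_rhs_raw(np.maximum(y, 0.0), params, Q), x)
    raise TypeError(f"unsupported params type {type(params)!r}")


# ---------------------------------------------------------------------------
# integration


def integrate(
    params: Params,
    init,
    horizon: float,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
    terminate_at_equilibrium: bool = False,
    conv_tol: float = CONV_TOL,
    t_eval: Optional[np.ndarray] = None,
) -> Trajectory:
    """Integrate from ``init`` for ``horizon`` time units.

    With ``terminate_at_equilibrium`` the run stops early once
    ``||RHS||_inf < conv_tol`` and the trajectory is marked converged.
    Output states are clipped to zero from below (solver excursions beyond
    −1e-9 would indicate a genuine failure and raise).
    """
    dim, columns, rhs = _make_rhs(params)
    y0 = np.asarray(tuple(init), dtype=float)
    if y0.shape != (dim,):
        raise ValueError(f"init must have {dim} components for {type(params).__name__}")
    if np.any(y0 < 0):
        raise ValueError(f"init must be nonnegative, got {y0}")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")

    events = None
    converged_at_start = False
    if terminate_at_equilibrium:
        if float(np.max(np.abs(rhs(0.0, y0)))) < conv_tol:
            converged_at_start = True
        else:

            def _eq_event(t, y):
                return float(np.max(np.abs(rhs(t, y)))) - conv_tol

            _eq_event.terminal = True
            _eq_event.direction = -1
            events = [_eq_event]

    if converged_at_start:
        t = np.array([0.0, horizon])
        y = np.vstack([y0, y0])
        return Trajectory(
            t=t, y=y, columns=columns, converged=True,
            metadata={"rtol": rtol, "atol": atol, "method": method, "nfev": 0,
                      "min_component": float(y0.min()), "status": "already_at_equilibrium"},
        )

    sol = solve_ivp(
        rhs, (0.0, horizon), y0, method=method, rtol=rtol, atol=atol,
        events=events, t_eval=t_eval, dense_output=False,
    )
    traj_y = sol.y.T
    min_comp = float(traj_y.min()) if traj_y.size else 0.0
    clipped = np.clip(traj_y, 0.0, None)
    converged = bool(events and sol.t_events and len(sol.t_events[0]) > 0)
    traj = Trajectory(
        t=sol.t, y=clipped, columns=columns, converged=converged,
        metadata={"rtol": rtol, "atol": atol, "method": method,
                  "nfev": int(sol.nfev), "min_component": min_comp,
                  "status": sol.message},
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", trajectory=traj)
    if min_comp < NEG_CLIP:
        raise IntegrationError(
            f"trajectory fell below the nonnegativity noise floor ({min_comp:g})",
            trajectory=traj,
        )
    return traj


def find_equilibrium(params: Params, guess, *, residual_tol: float = 1e-9,
                     stability_tol: float = 1e-10) -> Optional[Equilibrium]:
    """Locate a nonnegative root of the RHS near ``guess``.

    Uses a hybrid Newton iteration with the analytic Jacobian, projecting
    solver noise onto the nonnegative orthant.  Returns ``None`` (not an
    exception) when no root with residual below ``residual_tol`` is found.
    Stability is read off the Jacobian eigenvalues: all real parts below
    −``stability_tol`` is stable, any above +``stability_tol`` unstable,
    otherwise marginal.
    """
    dim, _, rhs = _make_rhs(params)
    x0 = np.asarray(tuple(guess), dtype=float)
    if x0.shape != (dim,):
        raise ValueError(f"guess must have {dim} components")
    if np.any(x0 < 0):
        raise ValueError("guess must be nonnegative")

    f = lambda y: rhs(0.0, y)
    # only skip the Newton polish when the guess is already a root to near
    # machine precision (e.g. the all-zero state)
    if float(np.max(np.abs(f(x0)))) < 1e-13:
        x = x0.copy()
    else:
        sol = _scipy_root(f, x0, jac=lambda y: jacobian(params, np.maximum(y, 0.0)),
                          method="hybr", tol=1e-13)
        x = sol.x
        # project solver noise back onto the orthant
        x = np.where((x < 0) & (x > NEG_CLIP), 0.0, x)
        if np.any(x < 0):
            return None
    residual = float(np.max(np.abs(f(x))))
    if residual >= residual_tol:
        return None
    eig = np.linalg.eigvals(jacobian(params, x))
    re = eig.real
    if np.all(re < -stability_tol):
        stability = "stable"
    elif np.any(re > stability_tol):
        stability = "unstable"
    else:
        stability = "marginal"
    return Equilibrium(state=x, residual=residual, eigenvalues=eig, stability=stability)


def run_to_convergence(
    params: Params,
    init,
    *,
    t_cap: float = 1e5,
    window: float = 1e3,
    conv_tol: float = CONV_TOL,
    cycle_tol: float = 1e-6,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[ConvergenceResult, Trajectory]:
    """Integrate until equilibrium or a hard time cap.

    Convergence means ``||RHS||_inf < conv_tol``.  If the cap is reached and
    any component's range over the final window exceeds ``cycle_tol``, the
    run is flagged as a limit cycle and the window time-average is reported as
    the final state; otherwise it is reported non-converged at the last state.
    """
    traj = integrate(params, init, t_cap, rtol=rtol, atol=atol,
                     terminate_at_equilibrium=True, conv_tol=conv_tol)
    if traj.converged:
        return (
            ConvergenceResult(state=traj.final.copy(), converged=True,
                              limit_cycle=False, t_end=float(traj.t[-1])),
            traj,
        )
    tail = traj.t >= traj.t[-1] - window
    y_tail = traj.y[tail]
    t_tail = traj.t[tail]
    osc = float(np.max(y_tail.max(axis=0) - y_tail.min(axis=0))) if len(y_tail) > 1 else 0.0
    if osc > cycle_tol:
        avg = (
            np.trapezoid(y_tail, t_tail, axis=0) / (t_tail[-1] - t_tail[0])
            if len(t_tail) > 1 and t_tail[-1] > t_tail[0]
            else traj.final.copy()
        )
        return (
            ConvergenceResult(state=avg, converged=False, limit_cycle=True,
                              t_end=float(traj.t[-1])),
            traj,
        )
    return (
        ConvergenceResult(state=traj.final.copy(), converged=False,
                          limit_cycle=False, t_end=float(traj.t[-1])),
        traj,
    )
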