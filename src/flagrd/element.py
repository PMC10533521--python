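"""Isolated freely shearing element: the zero-dimensional motor oscillator.

A small section of flagellum that experiences no contact forces from its
neighbours obeys the tangential force balance ``f_t = 0``: the active
tug-of-war force, the motor friction and the elastic shear restoring
force cancel at every instant.  Combined with the motor rate equations
this gives a three-variable ODE system ``(gamma, n+, n-)`` whose
equilibrium ``(0, n0, n0)`` loses stability in a Hopf bifurcation at
``nu_a = nu_a_crit``, producing limit-cycle shear oscillations.

The nondimensional shear velocity is obtained in closed form from the
force balance::

    gamma_t = (nu_a*(n_minus - n_plus) - gamma) / (nu_a*zeta*(n_minus + n_plus))

and is substituted into the load-dependent detachment rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .stability import derived_motor_quantities, nu_a_crit

__all__ = [
    "ElementState",
    "ElementSeries",
    "LimitCycleMetrics",
    "NotConvergedError",
    "element_rhs",
    "element_forces",
    "simulate_element",
    "limit_cycle_metrics",
    "find_hopf_nu_a",
]

# exponent clip guards against overflow in trial steps of the stiff solver
_EXP_CLIP = 500.0


class NotConvergedError(RuntimeError):
    """Trajectory does not contain enough post-transient cycles."""


@dataclass(frozen=True)
class ElementState:
    """State of the isolated element: shear angle and bound fractions."""

    gamma: float
    n_plus: float
    n_minus: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma, self.n_plus, self.n_minus], dtype=float)


@dataclass
class ElementSeries:
    """Time series of an element simulation (time in units of tau)."""

    t: np.ndarray
    gamma: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    nu_a: float
    zeta: float
    eta: float
    fstar: float


@dataclass
class LimitCycleMetrics:
    """Amplitude, period and the three force components along the cycle.

    Forces are per unit length in units of ``a*K`` (the shear stiffness
    scale): ``f_active = nu_a*(n_minus - n_plus)``, ``f_elastic = -gamma``
    and ``f_friction = -nu_a*zeta*(n_plus + n_minus)*gamma_t``; the
    tangential force balance requires them to sum to zero.
    """

    amplitude: float
    period: float
    t: np.ndarray
    f_active: np.ndarray
    f_elastic: np.ndarray
    f_friction: np.ndarray


def _gamma_t(gamma, n_plus, n_minus, nu_a, zeta):
    n_bar = n_minus + n_plus
    return (nu_a * (n_minus - n_plus) - gamma) / (nu_a * zeta * n_bar)


def element_rhs(
    state: np.ndarray, nu_a: float, zeta: float, eta: float, fstar: float
) -> np.ndarray:
    """Time derivative of ``(gamma, n+, n-)`` for the isolated element.

    Raises ``ZeroDivisionError``-like ValueError when ``n+ + n- = 0``
    (singular mass: no attached motors to balance the elastic force).
    """
    gamma, n_plus, n_minus = float(state[0]), float(state[1]), float(state[2])
    n_bar = n_plus + n_minus
    if n_bar <= 0.0:
        raise ValueError("n_plus + n_minus must be positive (singular mass)")
    gt = _gamma_t(gamma, n_plus, n_minus, nu_a, zeta)
    ex_p = np.exp(np.clip(fstar * (1.0 + zeta * gt), -_EXP_CLIP, _EXP_CLIP))
    ex_m = np.exp(np.clip(fstar * (1.0 - zeta * gt), -_EXP_CLIP, _EXP_CLIP))
    dn_p = eta * (1.0 - n_plus) - (1.0 - eta) * n_plus * ex_p
    dn_m = eta * (1.0 - n_minus) - (1.0 - eta) * n_minus * ex_m
    return np.array([gt, dn_p, dn_m])


def element_forces(series: ElementSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Active, elastic and friction force traces (units of a*K) along a series."""
    gt = _gamma_t(series.gamma, series.n_plus, series.n_minus, series.nu_a, series.zeta)
    f_active = series.nu_a * (series.n_minus - series.n_plus)
    f_elastic = -series.gamma
    f_friction = -series.nu_a * series.zeta * (series.n_plus + series.n_minus) * gt
    return f_active, f_elastic, f_friction


def simulate_element(
    nu_a: float,
    zeta: float,
    eta: float,
    fstar: float,
    initial: ElementState | None = None,
    t_end: float = 100.0,
    dt_out: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ElementSeries:
    """Integrate the element ODEs with a stiff solver.

    The default initial condition is a small shear perturbation
    ``gamma = 1e-3`` with motors at equilibrium, mirroring the PDE
    initial condition.  The exponential detachment terms are stiff at
    large ``fstar*zeta*gamma_t``, hence the tight tolerances and BDF.
    """
    d = derived_motor_quantities(eta, zeta, fstar)
    if initial is None:
        initial = ElementState(gamma=1e-3, n_plus=d.n0, n_minus=d.n0)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(
        lambda t, y: element_rhs(y, nu_a, zeta, eta, fstar),
        (0.0, t_end),
        initial.as_array(),
        method="BDF",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"element integration failed: {sol.message}")
    return ElementSeries(
        t=sol.t, gamma=sol.y[0], n_plus=sol.y[1], n_minus=sol.y[2],
        nu_a=nu_a, zeta=zeta, eta=eta, fstar=fstar,
    )


def limit_cycle_metrics(series: ElementSeries, transient_fraction: float = 0.5) -> LimitCycleMetrics:
    """Characterise the limit cycle of an element trajectory.

    The first ``transient_fraction`` of the record is discarded; the
    period is the mean spacing of upward zero crossings of
    ``gamma - mean(gamma)`` and at least five full cycles are required.
    Force traces are certified to balance (`|sum| < 1e-8 * max|term|`).
    """
    start = int(len(series.t) * transient_fraction)
    t = series.t[start:]
    g = series.gamma[start:]
    g0 = g - g.mean()
    up = np.flatnonzero((g0[:-1] < 0.0) & (g0[1:] >= 0.0))
    if len(up) < 6:
        raise NotConvergedError(
            f"fewer than 5 full cycles detected after transient ({max(len(up) - 1, 0)} found)"
        )
    # linear interpolation of the crossing instants
    frac = -g0[up] / (g0[up + 1] - g0[up])
    t_cross = t[up] + frac * (t[up + 1] - t[up])
    period = float(np.diff(t_cross).mean())
    amplitude = 0.5 * float(g.max() - g.min())
    sub = ElementSeries(t=t, gamma=g, n_plus=series.n_plus[start:], n_minus=series.n_minus[start:],
                        nu_a=series.nu_a, zeta=series.zeta, eta=series.eta, fstar=series.fstar)
    f_a, f_e, f_f = element_forces(sub)
    residual = np.abs(f_a + f_e + f_f).max()
    scale = max(np.abs(f_a).max(), np.abs(f_e).max(), np.abs(f_f).max())
    if scale > 0 and residual > 1e-8 * scale:
        raise RuntimeError(f"force balance violated: |sum| = {residual:.3g} vs scale {scale:.3g}")
    return LimitCycleMetrics(
        amplitude=amplitude, period=period, t=t,
        f_active=f_a, f_elastic=f_e, f_friction=f_f,
    )


def _max_real_eigenvalue(nu_a: float, zeta: float, eta: float, fstar: float) -> complex:
    """Leading eigenvalue of the numerically linearized element at equilibrium."""
    d = derived_motor_quantities(eta, zeta, fstar)
    y0 = np.array([0.0, d.n0, d.n0])
    h = 1e-7
    J = np.empty((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        J[:, j] = (element_rhs(y0 + e, nu_a, zeta, eta, fstar)
                   - element_rhs(y0 - e, nu_a, zeta, eta, fstar)) / (2.0 * h)
    eigs = np.linalg.eigvals(J)
    return eigs[np.argmax(eigs.real)]


def find_hopf_nu_a(
    zeta: float, eta: float, fstar: float,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Locate the Hopf onset by bisection on ``nu_a``.

    Bisects on the sign of the leading real part of the Jacobian of the
    element vector field at the equilibrium (the Jacobian is computed by
    central finite differences, independently of the closed-form
    theory).  Returns ``(nu_a_onset, omega_onset)`` where the frequency
    is the imaginary part of the leading eigenvalue at onset.
    """
    if bracket is None:
        guess = nu_a_crit(eta, zeta, fstar)
        bracket = (0.2 * guess, 5.0 * guess)
    lo, hi = bracket
    if _max_real_eigenvalue(lo, zeta, eta, fstar).real >= 0:
        raise ValueError("lower bracket is not subcritical")
    if _max_real_eigenvalue(hi, zeta, eta, fstar).real <= 0:
        raise ValueError("upper bracket is not supercritical")
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        if _max_real_eigenvalue(mid, zeta, eta, fstar).real > 0:
            hi = mid
        else:
            lo = mid
    onset = 0.5 * (lo + hi)
    omega = abs(_max_real_eigenvalue(onset, zeta, eta, fstar).imag)
    return onset, omega
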