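"""Closed-form linear-stability theory of the reaction-diffusion beat model.

Linearizing the model about the quiescent equilibrium ``(gamma, n±) =
(0, n0)`` yields a Hopf bifurcation in the motor activity ``mu_a``.  The
critical activity, the intrinsic frequency, and the growth rate and
frequency of the unstable standing-wave mode are all available in closed
form and are implemented here.  All rates are per unit ``tau`` (the
motor kinetic timescale); the theory assumes the oscillatory regime
``omega0_sq > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BelowOscillationThresholdError",
    "OverdampedError",
    "DerivedMotorQuantities",
    "StabilitySummary",
    "equilibrium_attachment",
    "intrinsic_frequency_sq",
    "zeta_bar",
    "derived_motor_quantities",
    "nu_a_crit",
    "critical_activity",
    "bifurcation_distance",
    "rate_per_tau",
    "linear_growth_and_frequency",
    "stability_summary",
    "standing_wave_solution",
]


class BelowOscillationThresholdError(ValueError):
    """Motor parameters give ``omega0_sq <= 0``: no oscillatory instability."""


class OverdampedError(ValueError):
    """Linear frequency formula gives a negative square: overdamped regime."""


@dataclass(frozen=True)
class DerivedMotorQuantities:
    """Motor quantities derived from ``(eta, zeta, fstar)``.

    Attributes
    ----------
    n0 : float
        Equilibrium attached fraction, in (0, 1).
    omega0_sq : float
        Squared intrinsic (critical) frequency ``(1-n0) fstar - 1`` in
        units of ``1/tau**2``; oscillations require it to be positive.
    zeta_bar : float
        Friction parameter on the slow timescale ``tau_bar``:
        ``zeta_bar = zeta (eta + (1-eta) e^{fstar}) >= zeta``.
    """

    n0: float
    omega0_sq: float
    zeta_bar: float


@dataclass(frozen=True)
class StabilitySummary:
    """Linear-stability summary of a parameter set (alpha, omega per ``tau_bar``)."""

    mu_a_crit: float
    nu_a_crit: float
    epsilon: float
    alpha: float
    omega: float


def equilibrium_attachment(eta: float, fstar: float) -> float:
    """Equilibrium attached motor fraction ``n0``.

    In terms of the base rates, ``n0 = pi0/(pi0 + eps0 e^{fstar})``;
    dividing through by ``pi0 + eps0`` gives the duty-ratio form
    ``n0 = eta/(eta + (1-eta) e^{fstar})`` used here.
    """
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must lie in (0, 1), got {eta}")
    if fstar < 0:
        raise ValueError(f"fstar must be non-negative, got {fstar}")
    return eta / (eta + (1.0 - eta) * math.exp(fstar))


def intrinsic_frequency_sq(n0: float, fstar: float) -> float:
    """Squared intrinsic frequency ``omega0^2 = (1-n0) fstar - 1``.

    May be non-positive (below the oscillation threshold); the caller
    decides whether that is an error.
    """
    if not 0.0 < n0 < 1.0:
        raise ValueError(f"n0 must lie in (0, 1), got {n0}")
    return (1.0 - n0) * fstar - 1.0


def zeta_bar(eta: float, zeta: float, fstar: float) -> float:
    """Friction parameter ``zeta_bar = a/(v0 tau_bar)`` expressed via ``zeta``.

    The slow timescale is ``tau_bar = 1/(pi0 + eps0 e^{fstar})`` while
    ``tau = 1/(pi0 + eps0)``, hence ``tau/tau_bar = (pi0 + eps0 e^{fstar})
    /(pi0 + eps0) = eta + (1-eta) e^{fstar}`` and therefore
    ``zeta_bar = zeta (eta + (1-eta) e^{fstar})``.
    """
    return zeta * (eta + (1.0 - eta) * math.exp(fstar))


def derived_motor_quantities(eta: float, zeta: float, fstar: float) -> DerivedMotorQuantities:
    n0 = equilibrium_attachment(eta, fstar)
    return DerivedMotorQuantities(
        n0=n0,
        omega0_sq=intrinsic_frequency_sq(n0, fstar),
        zeta_bar=zeta_bar(eta, zeta, fstar),
    )


def nu_a_crit(eta: float, zeta: float, fstar: float) -> float:
    """Single-element critical activity ratio ``nu_a^crit = 1/(2 zeta_bar n0 omega0^2)``.

    At ``nu_a = rho f0/(a K)`` above this value an isolated freely
    shearing element undergoes a Hopf bifurcation to limit-cycle shear
    oscillations.
    """
    d = derived_motor_quantities(eta, zeta, fstar)
    if d.omega0_sq <= 0:
        raise BelowOscillationThresholdError(
            f"omega0_sq = {d.omega0_sq:.6g} <= 0: motor parameters below oscillation threshold"
        )
    return 1.0 / (2.0 * d.zeta_bar * d.n0 * d.omega0_sq)


def critical_activity(mu: float, eta: float, zeta: float, fstar: float) -> float:
    """Hopf bifurcation point of the spatially extended model.

    ``mu_a^crit = (pi^2 + 4 mu)/(8 n0 zeta_bar omega0^2)``.  Setting the
    ``pi^2`` summand (the bending-diffusion contribution of the slowest
    spatial mode) to zero reduces this to ``mu * nu_a_crit``, the
    single-element case.
    """
    if mu < 0:
        raise ValueError(f"mu must be non-negative, got {mu}")
    d = derived_motor_quantities(eta, zeta, fstar)
    if d.omega0_sq <= 0:
        raise BelowOscillationThresholdError(
            f"omega0_sq = {d.omega0_sq:.6g} <= 0: motor parameters below oscillation threshold"
        )
    return (math.pi**2 + 4.0 * mu) / (8.0 * d.n0 * d.zeta_bar * d.omega0_sq)


def bifurcation_distance(mu_a: float, mu: float, eta: float, zeta: float, fstar: float) -> float:
    """Relative distance to the Hopf point, ``epsilon = (mu_a - mu_a^crit)/mu_a^crit``.

    Negative when subcritical, zero exactly at the bifurcation.
    """
    crit = critical_activity(mu, eta, zeta, fstar)
    return (mu_a - crit) / crit


def rate_per_tau(rate: float, eta: float, fstar: float) -> float:
    """Convert a rate from ``1/tau_bar`` to ``1/tau`` units.

    The closed-form growth rate, frequency and ``omega0`` are rates per
    unit of the slow motor timescale ``tau_bar = 1/(pi0+eps0 e^{fstar})``;
    simulations integrate in units of ``tau = 1/(pi0+eps0)``.  The
    conversion factor is ``tau/tau_bar = eta + (1-eta) e^{fstar}``
    (equal to ``zeta_bar/zeta``).
    """
    return rate * (eta + (1.0 - eta) * math.exp(fstar))


def linear_growth_and_frequency(epsilon: float, omega0_sq: float) -> tuple[float, float]:
    """Growth rate and angular frequency of the linearly unstable mode.

    ``alpha = epsilon omega0^2 / (2 (1+epsilon))`` and
    ``omega^2 = [(1 + epsilon - omega0^2 epsilon^2/4)/(1+epsilon)^2] omega0^2``.
    Both are rates per unit ``tau_bar`` (like ``omega0`` itself); use
    :func:`rate_per_tau` to compare with simulations that integrate in
    ``tau`` units.  Raises :class:`OverdampedError` when the bracket is
    negative (no oscillatory linear mode).
    """
    if epsilon <= -1.0:
        raise ValueError(f"epsilon must exceed -1, got {epsilon}")
    if omega0_sq <= 0:
        raise BelowOscillationThresholdError(
            f"omega0_sq = {omega0_sq:.6g} <= 0: below oscillation threshold"
        )
    alpha = epsilon * omega0_sq / (2.0 * (1.0 + epsilon))
    omega_sq = (1.0 + epsilon - 0.25 * omega0_sq * epsilon**2) / (1.0 + epsilon) ** 2 * omega0_sq
    if omega_sq < 0:
        raise OverdampedError(
            f"linear frequency squared is negative ({omega_sq:.6g}) at epsilon = {epsilon:.6g}"
        )
    return alpha, math.sqrt(omega_sq)


def stability_summary(mu_a: float, mu: float, eta: float, zeta: float, fstar: float) -> StabilitySummary:
    """Full closed-form stability characterisation of a parameter set.

    Far above onset the closed-form frequency bracket goes negative
    (the linear theory no longer predicts an oscillatory mode there);
    ``omega`` is then NaN while ``epsilon`` and ``alpha`` remain valid.
    """
    d = derived_motor_quantities(eta, zeta, fstar)
    crit = critical_activity(mu, eta, zeta, fstar)
    eps = (mu_a - crit) / crit
    try:
        alpha, omega = linear_growth_and_frequency(eps, d.omega0_sq)
    except OverdampedError:
        alpha = eps * d.omega0_sq / (2.0 * (1.0 + eps))
        omega = float("nan")
    return StabilitySummary(
        mu_a_crit=crit,
        nu_a_crit=nu_a_crit(eta, zeta, fstar),
        epsilon=eps,
        alpha=alpha,
        omega=omega,
    )


def standing_wave_solution(
    A: float, alpha: float, omega: float, s_grid: np.ndarray, t: float | np.ndarray
) -> np.ndarray:
    """Linear standing-wave solution ``Re[A e^{(alpha+i omega) t} sin(pi s/2)]``.

    The spatial sinusoid satisfies the boundary conditions gamma(0)=0 and
    gamma_s(1)=0; all points oscillate in phase (no interior nodes), so
    the linear mode is a self-organised standing wave.  ``s_grid`` is
    nondimensional arclength in [0, 1]; ``t`` may be a scalar or array
    (broadcast over a leading time axis).
    """
    s = np.asarray(s_grid, dtype=float)
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError("s_grid must lie within [0, 1]")
    t_arr = np.asarray(t, dtype=float)
    envelope = A * np.exp(alpha * t_arr)
    phase = np.cos(omega * t_arr)
    profile = np.sin(0.5 * np.pi * s)
    if t_arr.ndim == 0:
        return envelope * phase * profile
    return (envelope * phase)[:, None] * profile[None, :]
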