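"""Spectral decomposition and shape analysis of beating waveforms.

A periodic beat is characterised by its fundamental Fourier mode: the
complex coefficient ``gamma_tilde(s)`` of the dominant temporal
frequency at each arclength sample, under the one-sided convention

    gamma(s, t) ~ gamma_bar(s) + gamma_tilde(s) e^{i omega t} + c.c.

The mode shape carries both the amplitude envelope and the phase
profile of the wave (a flat phase is a standing wave; a monotone phase
gradient is a travelling wave).  Fit quality between two modes is the
phase-aligned R^2 score; the spatial wavenumber is estimated from the
time-averaged spatial autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kymograph import Kymograph

__all__ = [
    "FourierMode",
    "CenterlineShape",
    "InsufficientRecordError",
    "fundamental_mode",
    "optimal_phase",
    "r_squared",
    "wavenumber",
    "reconstruct_centerline",
    "reconstruct_beat",
    "apply_static_curvature",
]


class InsufficientRecordError(ValueError):
    """Record too short, or no oscillatory component above the noise floor."""


@dataclass
class FourierMode:
    """Fundamental complex mode of a kymograph.

    Attributes
    ----------
    mode : complex ndarray
        ``gamma_tilde(s)`` at each arclength sample.
    omega_fund : float
        Fundamental angular frequency (rad per time unit of the input).
    s_grid : ndarray
        Arclength samples.
    mean_profile : ndarray
        Time-mean ``gamma_bar(s)``, removed before the transform.
    spectrum_freqs, spectrum_power : ndarray
        Spatially averaged one-sided power spectrum.
    record_periods : float
        Number of fundamental periods in the analysed window.
    bin_width : float
        Angular frequency resolution of the transform.
    """

    mode: np.ndarray
    omega_fund: float
    s_grid: np.ndarray
    mean_profile: np.ndarray
    spectrum_freqs: np.ndarray
    spectrum_power: np.ndarray
    record_periods: float
    bin_width: float


@dataclass
class CenterlineShape:
    """Planar centerline coordinates at arclength samples (units of L)."""

    s_grid: np.ndarray
    x: np.ndarray
    y: np.ndarray


def _peak_bin(values: np.ndarray) -> tuple[int, np.ndarray]:
    """Index of the maximal non-DC bin of the spatially averaged periodogram."""
    F = np.fft.rfft(values, axis=0)
    power = (np.abs(F) ** 2).mean(axis=1)
    power[0] = 0.0
    k = int(np.argmax(power))
    if k == 0 or power[k] <= 0.0:
        raise InsufficientRecordError("no non-DC spectral peak above the floor")
    return k, power


def fundamental_mode(kym: Kymograph, min_periods: float = 20.0) -> FourierMode:
    """Extract the fundamental Fourier mode of a kymograph.

    The time-mean profile is removed first and reported separately.  The
    fundamental frequency is the peak of the spatially averaged power
    spectrum (raw periodogram bin, no window, no interpolation); the
    record is truncated to an integer number of estimated periods before
    the final transform to limit leakage.  Raises
    :class:`InsufficientRecordError` when the window holds fewer than
    ``min_periods`` estimated periods, or when the signal has no
    oscillatory component (e.g. constant in time).
    """
    raw = kym.values
    values = raw - raw.mean(axis=0, keepdims=True)
    if float(np.max(np.abs(values))) < 1e-300:
        raise InsufficientRecordError("signal is constant in time")
    n = values.shape[0]
    k0, p0 = _peak_bin(values)
    # provisional frequency from parabolic interpolation of the peak,
    # used only to truncate the record to an integer number of periods
    # (the reported frequency is the raw bin of the final transform)
    if 1 <= k0 < p0.size - 1 and p0[k0 - 1] > 0 and p0[k0 + 1] > 0:
        la, lb, lc = np.log(p0[k0 - 1: k0 + 2])
        denom = la - 2.0 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    samples_per_period = n / (k0 + delta)
    n_trunc = int(np.floor(n / samples_per_period) * samples_per_period)
    if n_trunc >= max(2, int(samples_per_period)):
        raw = raw[:n_trunc]
        n = n_trunc
    # the mean over whole periods is the static profile with minimal
    # leakage from the oscillatory part
    mean_profile = raw.mean(axis=0)
    values = raw - mean_profile[None, :]
    k, power = _peak_bin(values)
    record_periods = float(k)
    if record_periods < min_periods:
        raise InsufficientRecordError(
            f"record holds ~{record_periods:.1f} periods; {min_periods} required"
        )
    F = np.fft.rfft(values, axis=0)
    duration = n * kym.dt
    omega = 2.0 * np.pi * k / duration
    freqs = 2.0 * np.pi * np.arange(power.size) / duration
    # one-sided convention gamma ~ gamma_tilde e^{i omega t} + c.c.:
    # the +omega component contributes N*gamma_tilde to the rfft bin
    mode = F[k] / n
    return FourierMode(
        mode=mode,
        omega_fund=float(omega),
        s_grid=kym.s_grid.copy(),
        mean_profile=mean_profile,
        spectrum_freqs=freqs,
        spectrum_power=power / n**2,
        record_periods=record_periods,
        bin_width=float(2.0 * np.pi / duration),
    )


def optimal_phase(exp_mode: np.ndarray, sim_mode: np.ndarray) -> float:
    """Phase ``phi`` aligning a simulated mode with an experimental one.

    ``phi = arg(sum_i exp_i conj(sim_i))`` minimises
    ``sum_i |exp_i - e^{i phi} sim_i|^2``: expanding the square, the
    phase-dependent term is ``-2 Re[e^{-i phi} sum exp conj(sim)]``,
    maximised when ``phi`` equals the argument of the inner product.
    """
    exp_mode = np.asarray(exp_mode)
    sim_mode = np.asarray(sim_mode)
    if exp_mode.shape != sim_mode.shape:
        raise ValueError("modes must share the same arclength grid")
    inner = np.sum(exp_mode * np.conj(sim_mode))
    if np.abs(inner) == 0.0:
        if not (np.any(exp_mode) and np.any(sim_mode)):
            raise ValueError("phase undefined: a mode is identically zero")
        return 0.0  # orthogonal modes: any phase is equally (un)informative
    return float(np.angle(inner))


def r_squared(exp_mode: np.ndarray, sim_mode: np.ndarray) -> tuple[float, float]:
    """Phase-aligned R^2 between two fundamental modes.

    ``R^2 = 1 - sum |exp - e^{i phi} sim|^2 / sum |exp|^2`` with ``phi``
    the optimal alignment phase.  Returns ``(R2, phi)``.  ``R2 <= 1``,
    with equality iff the modes are identical up to a global phase.
    """
    exp_mode = np.asarray(exp_mode)
    sim_mode = np.asarray(sim_mode)
    denom = float(np.sum(np.abs(exp_mode) ** 2))
    if denom == 0.0:
        raise ValueError("R^2 undefined for a zero experimental mode")
    if not np.any(sim_mode):
        return 0.0, 0.0
    phi = optimal_phase(exp_mode, sim_mode)
    num = float(np.sum(np.abs(exp_mode - np.exp(1j * phi) * sim_mode) ** 2))
    return 1.0 - num / denom, phi


def wavenumber(kym: Kymograph, length: float = 1.0) -> float:
    """Spatial wavenumber from the time-averaged spatial autocorrelation.

    For each time sample the unbiased autocorrelation over arclength lag
    is computed (sum of products divided by the overlap count) and
    averaged over time.  Extrema are located where the lag-derivative
    changes sign (the final lag counts as an extremum when the sequence
    is still rising or falling there).  The wavelength is the lag of the
    maximal-magnitude peak, or twice the lag of the maximal-magnitude
    valley when the record holds less than one full spatial oscillation;
    ``q = 2 pi/lambda`` in units of 1/``length``.  Returns 0 (with a
    warning) when no extremum beyond lag zero exists.
    """
    theta = kym.values - kym.values.mean(axis=0, keepdims=True)
    m = theta.shape[1]
    h = kym.ds * length
    ac = np.empty(m)
    for k in range(m):
        prod = theta[:, : m - k] * theta[:, k:]
        ac[k] = prod.sum(axis=1).mean() / (m - k)
    d = np.diff(ac)
    sign = np.sign(d)
    peaks, valleys = [], []
    for k in range(1, m - 1):
        if sign[k - 1] > 0 and sign[k] <= 0:
            peaks.append(k)
        elif sign[k - 1] < 0 and sign[k] >= 0:
            valleys.append(k)
    # boundary extremum at the last lag
    if sign[-1] > 0:
        peaks.append(m - 1)
    elif sign[-1] < 0:
        valleys.append(m - 1)
    peaks = [k for k in peaks if ac[k] > 0]
    valleys = [k for k in valleys if ac[k] < 0]

    def best_lag(cands: list[int]) -> int:
        # a periodic field repeats its extremum at multiples of the
        # wavelength with near-equal magnitude (large lags rest on few
        # overlap points and are noisy): among near-ties take the
        # smallest lag, which is the wavelength itself
        top = max(abs(ac[k]) for k in cands)
        return min(k for k in cands if abs(ac[k]) >= 0.95 * top)

    if peaks:
        lam = best_lag(peaks) * h
    elif valleys:
        lam = 2.0 * best_lag(valleys) * h
    else:
        warnings.warn("no autocorrelation extremum beyond lag zero: no wave detected")
        return 0.0
    return float(2.0 * np.pi / lam)


def reconstruct_centerline(gamma_profile: np.ndarray, s_grid: np.ndarray | None = None,
                           ) -> CenterlineShape:
    """Integrate the tangent ``(cos gamma, sin gamma)`` into a centerline.

    Cumulative trapezoidal integration from the base (origin); arclength
    is preserved to second order in the grid spacing.
    """
    gamma_profile = np.asarray(gamma_profile, dtype=float)
    if s_grid is None:
        s_grid = np.linspace(0.0, 1.0, gamma_profile.size)
    x = cumulative_trapezoid(np.cos(gamma_profile), s_grid, initial=0.0)
    y = cumulative_trapezoid(np.sin(gamma_profile), s_grid, initial=0.0)
    return CenterlineShape(s_grid=np.asarray(s_grid), x=x, y=y)


def reconstruct_beat(
    gamma_bar: np.ndarray,
    mode: FourierMode,
    times: np.ndarray,
) -> Kymograph:
    """Rebuild the real beat ``gamma_bar + 2 Re[gamma_tilde e^{i omega t}]``."""
    gamma_bar = np.asarray(gamma_bar, dtype=float)
    if gamma_bar.shape != mode.mode.shape:
        raise ValueError("gamma_bar and mode must share the arclength grid")
    times = np.asarray(times, dtype=float)
    osc = 2.0 * np.real(mode.mode[None, :] * np.exp(1j * mode.omega_fund * times)[:, None])
    return Kymograph(values=gamma_bar[None, :] + osc, times=times, s_grid=mode.s_grid,
                     field_name="shear_angle",
                     metadata={"reconstructed": True, "omega_fund": mode.omega_fund})


def apply_static_curvature(kym: Kymograph, C: float) -> Kymograph:
    """Subtract the static linear-in-s shear component ``C*s``.

    The transformation ``gamma -> gamma - C s`` leaves both the time
    derivative and the second space derivative of the field unchanged,
    so the oscillatory dynamics superpose on a static circular-arc
    component; a signed ``C`` undoes itself (``C`` then ``-C`` is the
    identity).
    """
    values = kym.values - C * kym.s_grid[None, :]
    meta = dict(kym.metadata)
    meta["static_curvature_removed"] = meta.get("static_curvature_removed", 0.0) + C
    return Kymograph(values=values, times=kym.times.copy(), s_grid=kym.s_grid.copy(),
                     field_name=kym.field_name, metadata=meta)
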