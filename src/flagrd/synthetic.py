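"""Experiment-like synthetic fixtures generated from the model itself.

Emulates the two experimental data dialects (tangent angle at 19
arclength points every 1 ms; curvature at 30 points every 4 ms) by
simulating the reaction-diffusion model to its limit cycle, mapping
simulation time to physical time through a target beat frequency,
downsampling to the dialect grid, optionally superposing a static
curvature component, and adding seeded i.i.d. Gaussian measurement
noise.  A ground-truth sidecar records everything needed to regenerate
the record exactly; the fitter never reads it.

What is emulated: grid geometry, sampling rate, additive Gaussian
sensor noise, an optional static (asymmetric) beat component.  What is
not: cell-body yaw, lab-frame drift, tracking artifacts, non-Gaussian
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import CubicSpline

from .fitting import DIALECTS, ExperimentalRecord
from .params import NondimParams
from .solver import measure_frequency, simulate_rd
from .stability import bifurcation_distance

__all__ = ["SyntheticSpec", "generate_synthetic_experiment"]

#: default physical beat frequency per dialect (Hz); sets the tau -> s mapping
DEFAULT_BEAT_HZ = {"chlamy_theta_19pt_1ms": 50.0, "bull_curvature_30pt_4ms": 20.0}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic record.

    ``noise_sigma`` is the sd of the additive Gaussian noise in the
    units of the dialect field (rad for tangent angle, rad per unit
    arclength for curvature); ``static_C`` adds a static circular-arc
    component ``gamma -> gamma + C*s``; ``n_periods`` sets the record
    length (at least 20 for spectral analysis); ``beat_hz`` fixes the
    simulation-to-physical time mapping.
    """

    params: NondimParams
    dialect: str = "chlamy_theta_19pt_1ms"
    noise_sigma: float = 0.02
    static_C: float = 0.0
    n_periods: int = 25
    seed: int = 0
    beat_hz: float | None = None
    allow_decay: bool = False
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_periods < 1:
            raise ValueError("n_periods must be positive")


def generate_synthetic_experiment(
    spec: SyntheticSpec,
    m: int = 101,
    transient: float = 60.0,
    method: str = "semi",
) -> tuple[ExperimentalRecord, dict[str, Any]]:
    """Generate one record in the requested dialect plus its ground truth.

    The model is first run past the transient to measure the limit-cycle
    frequency, then long enough to hold ``n_periods`` beats.  Returns
    ``(record, ground_truth)``; the ground truth holds the generating
    parameters, the time mapping, the seed and the window, sufficient to
    regenerate the record bitwise.
    """
    p = spec.params
    eps = bifurcation_distance(p.mu_a, p.mu, p.eta, p.zeta, p.fstar)
    if eps <= 0.0 and not spec.allow_decay:
        raise ValueError(
            f"parameters are subcritical (epsilon = {eps:.3g}); "
            "set allow_decay=True for decay fixtures")

    # pass 1: measure the beat period past the transient
    probe = simulate_rd(p, t_end=transient + 40.0, m=m, method=method, dt_out=0.02)
    gam = probe["shear_angle"]
    omega_nd = measure_frequency(gam, t_start=transient)
    period_nd = 2.0 * np.pi / omega_nd

    beat_hz = spec.beat_hz if spec.beat_hz is not None else DEFAULT_BEAT_HZ[spec.dialect]
    tau_phys = omega_nd / (2.0 * np.pi * beat_hz)  # seconds per tau
    dial = DIALECTS[spec.dialect]
    dt_nd = dial["dt"] / tau_phys

    window_nd = spec.n_periods * period_nd
    t_end = transient + window_nd + 2.0 * period_nd
    if t_end > probe["shear_angle"].times[-1]:
        kym = simulate_rd(p, t_end=t_end, m=m, method=method, dt_out=0.02)["shear_angle"]
    else:
        kym = gam

    n_t = int(np.floor(window_nd / dt_nd)) + 1
    t_samples = transient + dt_nd * np.arange(n_t)
    gamma_t = CubicSpline(kym.times, kym.values, axis=0)(t_samples)
    gamma_t = gamma_t + spec.static_C * kym.s_grid[None, :]

    s_dial = np.linspace(0.0, 1.0, dial["n_s"])
    if dial["field"] == "tangent_angle":
        # theta in the body frame; the basal value is ~0 by construction
        field_fine = gamma_t
    else:
        # curvature by central differences of theta on the fine grid
        field_fine = np.gradient(gamma_t, kym.s_grid, axis=1)
    values = CubicSpline(kym.s_grid, field_fine, axis=1)(s_dial)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)

    record = ExperimentalRecord(
        values=values, dt=dial["dt"], s_positions=s_dial,
        dialect=spec.dialect, fieldkind=dial["field"],
        metadata={"synthetic": True, **spec.metadata},
    )
    ground_truth = {
        "params": p.to_dict(),
        "epsilon": eps,
        "dialect": spec.dialect,
        "noise_sigma": spec.noise_sigma,
        "static_C": spec.static_C,
        "n_periods": spec.n_periods,
        "seed": spec.seed,
        "beat_hz": beat_hz,
        "tau_phys_s": tau_phys,
        "omega_nd": omega_nd,
        "transient": transient,
        "m": m,
        "method": method,
    }
    return record, ground_truth
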