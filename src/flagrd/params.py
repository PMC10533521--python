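"""Parameter sets for the flagellar reaction-diffusion model.

The axoneme is projected onto two filaments at fixed spacing ``a``,
cross-linked by elastic nexin links (shear stiffness ``K``) and by two
antagonistic teams of dynein motors with linear force-velocity relation
``F± = f0 (1 ± Δ_t/v0)``.  Motors attach at base rate ``pi0`` and detach
at base rate ``eps0`` modulated exponentially by the load relative to a
characteristic unbinding force ``fc`` (load-dependent detachment, i.e.
sliding control).  The flagellum of length ``L`` and bending rigidity
``B`` resists the active shear moment elastically.

The dynamics depend on dimensional parameters only through five
dimensionless groups:

=========  ==========================  =============================
symbol     definition                  meaning
=========  ==========================  =============================
``mu_a``   a·rho·f0·L²/B               motor activity vs bending
``mu``     a²·K·L²/B                   shear vs bending stiffness
``eta``    pi0·tau = pi0/(pi0+eps0)    duty ratio of the motors
``zeta``   a/(v0·tau)                  motor friction parameter
``fstar``  f0/fc                       stall force vs unbinding force
=========  ==========================  =============================

with ``tau = 1/(pi0+eps0)`` the motor kinetic timescale.  Time is
measured in units of ``tau``, arclength in units of ``L`` and angles in
radians throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Any

__all__ = [
    "DimensionalParams",
    "NondimParams",
    "nondimensionalize",
    "CHLAMY_WT",
    "CHLAMY_MBO2",
    "BULL_SPERM",
]

_NONDIM_KEYS = ("mu_a", "mu", "eta", "zeta", "fstar")
_DIM_KEYS = ("a", "rho", "f0", "v0", "K", "B", "L", "pi0", "eps0", "fc")


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional parameters of the two-filament axoneme model.

    Parameters
    ----------
    a : float
        Inter-filament spacing (length).
    rho : float
        Line density of motors (1/length).
    f0 : float
        Motor stall force (force).
    v0 : float
        Zero-load motor velocity (length/time).
    K : float
        Inter-filament elastic shear stiffness (force/length**2).
    B : float
        Bending rigidity of the filament bundle (force*length**2).
    L : float
        Flagellum length (length).
    pi0 : float
        Motor attachment base rate (1/time).
    eps0 : float
        Motor detachment base rate (1/time).
    fc : float
        Characteristic unbinding force (force).

    All fields must be strictly positive; any consistent unit system may
    be used since only dimensionless combinations enter the dynamics.
    """

    a: float
    rho: float
    f0: float
    v0: float
    K: float
    B: float
    L: float
    pi0: float
    eps0: float
    fc: float
    provenance: str = "user input"

    def __post_init__(self) -> None:
        for name in _DIM_KEYS:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"parameter {name!r} must be a finite number, got {value!r}")
            if value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")

    @property
    def xi_m(self) -> float:
        """Internal motor drag coefficient ``f0/v0``."""
        return self.f0 / self.v0

    @property
    def tau(self) -> float:
        """Motor kinetic timescale ``1/(pi0+eps0)``."""
        return 1.0 / (self.pi0 + self.eps0)

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in _DIM_KEYS + ("provenance",)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DimensionalParams":
        payload = json.loads(text)
        return cls(**payload)


@dataclass(frozen=True)
class NondimParams:
    """The five dimensionless constants of the reaction-diffusion model.

    Invariants: ``mu_a > 0``, ``mu >= 0``, ``0 < eta < 1``, ``zeta > 0``,
    ``fstar >= 0``.
    """

    mu_a: float
    mu: float
    eta: float
    zeta: float
    fstar: float
    provenance: str = "user input"

    def __post_init__(self) -> None:
        if not self.mu_a > 0:
            raise ValueError(f"mu_a must be positive, got {self.mu_a}")
        if self.mu < 0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must lie in (0, 1), got {self.eta}")
        if not self.zeta > 0:
            raise ValueError(f"zeta must be positive, got {self.zeta}")
        if self.fstar < 0:
            raise ValueError(f"fstar must be non-negative, got {self.fstar}")

    @property
    def nu_a(self) -> float:
        """Single-element activity ratio ``nu_a = mu_a/mu = rho*f0/(a*K)``."""
        if self.mu == 0:
            raise ValueError("nu_a undefined for mu = 0")
        return self.mu_a / self.mu

    def replace(self, **changes: Any) -> "NondimParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _NONDIM_KEYS}

    def to_json(self) -> str:
        payload: dict[str, Any] = self.to_dict()
        payload["provenance"] = self.provenance
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NondimParams":
        payload = json.loads(text)
        unknown = set(payload) - set(_NONDIM_KEYS) - {"provenance"}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**payload)


def nondimensionalize(p: DimensionalParams) -> NondimParams:
    """Form the five dimensionless groups from dimensional parameters.

    ``mu_a = a rho f0 L^2/B``, ``mu = a^2 K L^2/B``,
    ``eta = pi0/(pi0+eps0)``, ``zeta = a (pi0+eps0)/v0``,
    ``fstar = f0/fc``.
    """
    return NondimParams(
        mu_a=p.a * p.rho * p.f0 * p.L**2 / p.B,
        mu=p.a**2 * p.K * p.L**2 / p.B,
        eta=p.pi0 / (p.pi0 + p.eps0),
        zeta=p.a * (p.pi0 + p.eps0) / p.v0,
        fstar=p.f0 / p.fc,
        provenance=f"nondimensionalized from: {p.provenance}",
    )


# Mean fitted parameter sets for the three cell types (mu fixed per
# species; fstar = 2 reproduces the published distances to bifurcation).
CHLAMY_WT = NondimParams(mu_a=1570.0, mu=10.0, eta=0.096, zeta=0.96, fstar=2.0,
                         provenance="mean fitted, wild-type C. reinhardtii")
CHLAMY_MBO2 = NondimParams(mu_a=490.0, mu=10.0, eta=0.332, zeta=0.880, fstar=2.0,
                           provenance="mean fitted, mbo2-mutant C. reinhardtii")
BULL_SPERM = NondimParams(mu_a=2000.0, mu=100.0, eta=0.34, zeta=0.6, fstar=2.0,
                          provenance="fitted, bull sperm")
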