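"""Kymograph container: a space-time matrix of an angle-like field.

This is the universal exchange object of the package: simulations emit
kymographs, the spectral and fitting layers consume them.  On disk a
kymograph is a delimited-text matrix (rows = time samples, columns =
arclength samples) next to a JSON sidecar holding the grid metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["Kymograph", "write_kymograph", "read_kymograph"]

_FIELD_NAMES = {"shear_angle", "tangent_angle", "curvature", "n_plus", "n_minus"}


@dataclass
class Kymograph:
    """Field samples on a uniform (time x arclength) grid.

    ``values[j, i]`` is the field at time ``times[j]`` and arclength
    ``s_grid[i]``.  Times must be strictly increasing and uniformly
    spaced; ``field_name`` is one of shear_angle, tangent_angle,
    curvature, n_plus, n_minus.
    """

    values: np.ndarray
    times: np.ndarray
    s_grid: np.ndarray
    field_name: str = "shear_angle"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if self.field_name not in _FIELD_NAMES:
            raise ValueError(f"field_name must be one of {sorted(_FIELD_NAMES)}, got {self.field_name!r}")
        if self.values.shape != (self.times.size, self.s_grid.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.times.size} times x {self.s_grid.size} arclength samples"
            )
        dt = np.diff(self.times)
        if self.times.size > 1:
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def ds(self) -> float:
        return float(self.s_grid[1] - self.s_grid[0])

    def window(self, t_start: float, t_end: float | None = None) -> "Kymograph":
        """Sub-kymograph restricted to ``t_start <= t <= t_end``."""
        if t_end is None:
            t_end = float(self.times[-1])
        mask = (self.times >= t_start - 1e-12) & (self.times <= t_end + 1e-12)
        if mask.sum() < 2:
            raise ValueError("window contains fewer than two time samples")
        return Kymograph(self.values[mask], self.times[mask], self.s_grid,
                         self.field_name, dict(self.metadata))


def write_kymograph(kym: Kymograph, path: str | Path) -> None:
    """Write ``<path>`` (CSV matrix) and ``<path>.json`` (sidecar)."""
    path = Path(path)
    np.savetxt(path, kym.values, delimiter=",")
    sidecar = {
        "field_name": kym.field_name,
        "m": int(kym.s_grid.size),
        "dt": kym.dt if kym.times.size > 1 else None,
        "t0": float(kym.times[0]),
        "s_grid": kym.s_grid.tolist(),
        "metadata": kym.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_kymograph(path: str | Path) -> Kymograph:
    """Read a kymograph written by :func:`write_kymograph`.

    Accepts comma- or tab-delimited matrices.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    times = sidecar["t0"] + sidecar["dt"] * np.arange(values.shape[0])
    return Kymograph(
        values=values,
        times=times,
        s_grid=np.asarray(sidecar["s_grid"], dtype=float),
        field_name=sidecar["field_name"],
        metadata=sidecar.get("metadata", {}),
    )
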