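"""Steady-state forward model of skin-surface temperature.

An embedded tumour is modelled as an equivalent point/spherical heat source
in a homogeneous, isotropic medium. In steady state the radial conduction
solution is T(r) = Q/(4 pi k r) + T0, and balancing the source power against
surface convection gives the surface temperature at lateral offset ``a``
from the point directly above the source centre:

    T(a) = T_env + Q / (4 pi h0 [(d + R)^2 + a^2])

with Q the source intensity (W), d the depth of the source top (m), R its
radius (m) and h0 the surface heat exchange coefficient (W/(m^2 K)). A
sphere of radius R at depth d is, by construction, identical to a point
source at effective depth d + R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import HeatSource, TissueParams

FOUR_PI = 4.0 * math.pi

__all__ = [
    "TemperatureProfile",
    "surface_temperature",
    "surface_profile",
    "point_source_field",
    "parameter_sweep",
]


@dataclass(frozen=True)
class TemperatureProfile:
    """1D surface-temperature profile along a line through the hotspot.

    ``offsets`` are signed lateral distances (m) from the surface point
    above the source centre, strictly increasing; ``temps`` are the surface
    temperatures (degC) at those offsets; ``T_env_C`` the ambient (degC).
    """

    offsets: np.ndarray
    temps: np.ndarray
    T_env_C: float

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        if offsets.ndim != 1 or offsets.size == 0:
            raise ValueError("offsets must be a non-empty 1D array")
        if temps.shape != offsets.shape:
            raise ValueError("temps and offsets must have the same length")
        if not np.all(np.diff(offsets) > 0):
            raise ValueError("offsets must be strictly increasing")
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "temps", temps)

    @property
    def peak_temperature(self) -> float:
        return float(self.temps.max())

    @property
    def peak_offset(self) -> float:
        return float(self.offsets[int(np.argmax(self.temps))])

    @property
    def span(self) -> float:
        """Temperature difference between the hottest and coldest point, degC."""
        return float(self.temps.max() - self.temps.min())


def surface_temperature(source: HeatSource, tissue: TissueParams, a):
    """Surface temperature (degC) at lateral offset ``a`` (m) from the hotspot.

    Accepts a scalar or array offset; the result has the same shape.
    Symmetric in ``a``; equals the ambient exactly when Q = 0.
    """
    a = np.asarray(a, dtype=float)
    elevation = source.Q / (FOUR_PI * tissue.h0 * (source.d_eff**2 + a**2))
    result = tissue.T_env_C + elevation
    return float(result) if result.ndim == 0 else result


def surface_profile(source: HeatSource, tissue: TissueParams,
                    offsets) -> TemperatureProfile:
    """Evaluate the surface model over a strictly increasing set of offsets."""
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets must be non-empty")
    temps = surface_temperature(source, tissue, offsets)
    return TemperatureProfile(offsets=offsets, temps=np.asarray(temps),
                              T_env_C=tissue.T_env_C)


def point_source_field(Q: float, k: float, T0: float, r):
    """Radial steady-state temperature field of a point source in tissue.

    T(r) = Q/(4 pi k r) + T0 with Q in W, k in W/(m K), r in m.
    Singular at the origin: r must be strictly positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radial distance r must be strictly positive")
    if k <= 0:
        raise ValueError("thermal conductivity k must be strictly positive")
    result = Q / (FOUR_PI * k * r) + T0
    return float(result) if result.ndim == 0 else result


def parameter_sweep(base: HeatSource, tissue: TissueParams, param: str,
                    values, offsets) -> list[TemperatureProfile]:
    """One surface profile per value of one source parameter.

    ``param`` names a HeatSource field ("Q", "d" or "R"); all other fields
    are held at their ``base`` values.
    """
    if param not in ("Q", "d", "R"):
        raise ValueError(f"unknown heat-source parameter {param!r}; "
                         "expected one of 'Q', 'd', 'R'")
    return [
        surface_profile(base.replace(**{param: float(v)}), tissue, offsets)
        for v in values
    ]
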