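"""Tissue constants and heat-source descriptions.

The tissue defaults are the standard thermophysical constants for sound
breast tissue used throughout the bioheat-thermography literature:
conduction, surface convection, blood properties, perfusion, and metabolic
heat generation. Temperatures are stored in Kelvin (as tabulated) with
Celsius accessors; everything the surface model computes depends only on
temperature differences, so the unit choice is observationally neutral.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class TissueParams:
    """Thermal and biological constants of the tissue/environment system.

    Parameters
    ----------
    k : float
        Thermal conductivity, W/(m K).
    h0 : float
        Heat exchange (convection) coefficient at the skin surface,
        W/(m^2 K).
    c_b : float
        Blood specific heat, J/(kg K).
    rho_b : float
        Blood density, kg/m^3.
    q_m : float
        Metabolic heat generation of healthy breast tissue, W/m^3.
    Q_t_range : tuple of float
        Plausible tumour metabolic heat generation interval, W/m^3.
    omega_b : float
        Blood perfusion rate, 1/s.
    T_arterial : float
        Arterial blood temperature, K.
    T_env : float
        Environment (ambient) temperature, K.
    rho, c : float, optional
        Tissue density (kg/m^3) and specific heat (J/(kg K)); they enter
        only the transient term of the bioheat equation and are unused by
        the steady-state model, kept for completeness.
    """

    k: float = 0.52
    h0: float = 8.77
    c_b: float = 4186.0
    rho_b: float = 1000.0
    q_m: float = 700.0
    Q_t_range: tuple[float, float] = (25_000.0, 90_000.0)
    omega_b: float = 0.00052
    T_arterial: float = 310.15
    T_env: float = 300.15
    rho: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        for name in ("k", "h0", "c_b", "rho_b", "q_m", "omega_b",
                     "T_arterial", "T_env"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        lo, hi = self.Q_t_range
        if not (lo > 0 and lo < hi):
            raise ValueError(
                f"Q_t_range must satisfy 0 < lower < upper, got {self.Q_t_range!r}"
            )
        for name in ("rho", "c"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be positive when given, got {value!r}")

    @property
    def T_arterial_C(self) -> float:
        """Arterial blood temperature in degrees Celsius."""
        return self.T_arterial - KELVIN_OFFSET

    @property
    def T_env_C(self) -> float:
        """Ambient temperature in degrees Celsius."""
        return self.T_env - KELVIN_OFFSET

    def with_env_C(self, t_env_c: float) -> "TissueParams":
        """Return a copy with the ambient temperature set in Celsius."""
        return dataclasses.replace(self, T_env=t_env_c + KELVIN_OFFSET)


@dataclass(frozen=True)
class HeatSource:
    """An embedded spherical (or point, R=0) heat source.

    Attributes
    ----------
    Q : float
        Total heat intensity, W.
    d : float
        Depth of the top of the source below the skin surface, m.
    R : float
        Source radius, m. A sphere of radius R at depth d is equivalent,
        for the surface model, to a point source at effective depth d+R.
    """

    Q: float
    d: float
    R: float = 0.0

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError(f"intensity Q must be non-negative, got {self.Q!r}")
        if self.d < 0 or self.R < 0:
            raise ValueError(
                f"depth and radius must be non-negative, got d={self.d!r}, R={self.R!r}"
            )
        if not self.d + self.R > 0:
            raise ValueError("effective depth d + R must be strictly positive "
                             "(a source on the surface is singular)")

    @property
    def d_eff(self) -> float:
        """Effective depth d + R of the equivalent point source, m."""
        return self.d + self.R

    def replace(self, **changes) -> "HeatSource":
        return dataclasses.replace(self, **changes)
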