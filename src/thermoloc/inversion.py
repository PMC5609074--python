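"""Analytic inversion of surface temperatures to heat-source parameters.

Given the peak surface temperature T_max, one local surface temperature
T(a) at lateral offset a, and the ambient T_e, the surface model inverts in
closed form:

    effective depth   d_eff = a * sqrt((T(a) - T_e) / (T_max - T(a)))
    intensity         Q     = 4 pi h0 a^2 (T(a) - T_e)(T_max - T_e) / (T_max - T(a))
    radius            R     = (Q / (Q_m A_t))^(1/3)

and, eliminating the intensity, the radius follows directly from one local
temperature and the depth:

    R^3 = (T(a) - T_e)(a^2 + d_eff^2) * 4 pi h0 / (q_m * 1e-6)

The depth formula provably returns the *effective* depth d + R of the
equivalent point source; the reported geometric depth is the decomposition
d = d_eff - R, floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forward import FOUR_PI, TemperatureProfile
from .params import HeatSource, TissueParams

__all__ = [
    "ObservationPair",
    "InversionResult",
    "NoSourceDetectedError",
    "depth_from_temps",
    "intensity_from_temps",
    "radius_from_intensity",
    "radius_depth_relation",
    "localize_from_thermogram",
    "estimate_source",
    "ApplicationEstimate",
]

DEFAULT_CELL_VOLUME = 1e-6  # A_t constant of the radius formula


class NoSourceDetectedError(ValueError):
    """Raised when the thermogram shows no elevation above ambient."""


@dataclass(frozen=True)
class ObservationPair:
    """The three temperatures plus offset that the inversion consumes.

    T_max: peak surface temperature (degC); T_a: surface temperature (degC)
    at lateral offset ``a`` (m) from the peak; T_env: ambient (degC).
    """

    T_max: float
    T_a: float
    a: float
    T_env: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"offset a must be strictly positive, got {self.a!r}")
        if not self.T_a > self.T_env:
            raise ValueError(
                f"local temperature ({self.T_a!r}) must exceed ambient ({self.T_env!r})"
            )
        if not self.T_max > self.T_a:
            raise ValueError(
                f"peak temperature ({self.T_max!r}) must exceed the local "
                f"reading ({self.T_a!r})"
            )


@dataclass(frozen=True)
class InversionResult:
    """Estimated source parameters with the observations that produced them."""

    d_eff: float
    Q: float
    R: float
    d: float
    observations: tuple[ObservationPair, ...]
    method_flags: dict = field(default_factory=dict)

    @property
    def source(self) -> HeatSource:
        return HeatSource(Q=self.Q, d=self.d, R=self.R)


def depth_from_temps(obs: ObservationPair) -> float:
    """Effective depth d+R (m) from one peak/local temperature pair.

    Exact on noiseless forward data: the ratio
    (T_a - T_env)/(T_max - T_a) equals d_eff^2 / a^2.
    """
    return obs.a * math.sqrt((obs.T_a - obs.T_env) / (obs.T_max - obs.T_a))


def intensity_from_temps(obs: ObservationPair, h0: float) -> float:
    """Source intensity Q (W) from one peak/local temperature pair."""
    if not h0 > 0:
        raise ValueError(f"h0 must be strictly positive, got {h0!r}")
    return (FOUR_PI * h0 * obs.a**2
            * (obs.T_a - obs.T_env) * (obs.T_max - obs.T_env)
            / (obs.T_max - obs.T_a))


def radius_from_intensity(Q: float, Q_m: float,
                          A_t: float = DEFAULT_CELL_VOLUME) -> float:
    """Source radius from its intensity and the metabolic generation rate.

    R = (Q / (Q_m * A_t))^(1/3); cube-root scaling, so R(8Q) = 2 R(Q).
    """
    if Q < 0:
        raise ValueError(f"intensity Q must be non-negative, got {Q!r}")
    if not (Q_m > 0 and A_t > 0):
        raise ValueError("Q_m and A_t must be strictly positive")
    return (Q / (Q_m * A_t)) ** (1.0 / 3.0)


def radius_depth_relation(T_a: float, T_env: float, a: float, d: float,
                          h0: float, q_m: float,
                          A_t: float = DEFAULT_CELL_VOLUME) -> float:
    """Source radius without the intensity, from one local temperature.

    R^3 = (T_a - T_env)(a^2 + d^2) * 4 pi h0 / (q_m * A_t) where ``d`` is
    the effective depth. On noiseless data this is exactly
    radius_from_intensity(intensity_from_temps(...), q_m, A_t).
    """
    if T_a < T_env:
        raise ValueError(
            f"local temperature ({T_a!r}) must not be below ambient ({T_env!r})"
        )
    if not (q_m > 0 and A_t > 0):
        raise ValueError("q_m and A_t must be strictly positive")
    cubed = (T_a - T_env) * (a**2 + d**2) * FOUR_PI * h0 / (q_m * A_t)
    return cubed ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Thermogram-level localization


def _observations_from_profile(profile: TemperatureProfile,
                               eps: float = 1e-12) -> tuple[float, list[ObservationPair]]:
    temps = profile.temps
    t_max = float(temps.max())
    peak_offset = profile.peak_offset
    pairs = []
    for off, t in zip(profile.offsets, temps):
        a = abs(float(off) - peak_offset)
        if a <= 0:
            continue
        if t - profile.T_env_C > eps and t_max - t > eps:
            pairs.append(ObservationPair(T_max=t_max, T_a=float(t), a=a,
                                         T_env=profile.T_env_C))
    return t_max, pairs


def _observations_from_grid(grid, offsets, eps: float = 1e-12):
    """Peak location (centroid of the argmax set) and axis-sampled pairs."""
    temps = np.asarray(grid.temps, dtype=float)
    t_max = float(temps.max())
    peak_mask = temps >= t_max - eps
    rows, cols = np.nonzero(peak_mask)
    ci, cj = float(rows.mean()), float(cols.mean())
    warnings = []
    if (rows.min() == 0 or cols.min() == 0
            or rows.max() == temps.shape[0] - 1
            or cols.max() == temps.shape[1] - 1):
        warnings.append("peak-on-boundary")

    pi, pj = int(round(ci)), int(round(cj))
    pitch = grid.pixel_pitch
    if offsets is None:
        max_steps = min(temps.shape) // 2
        steps = [s for s in (2, 3, 4) if s <= max_steps] or [1]
        offsets = [s * pitch for s in steps]

    pairs = []
    for a in offsets:
        step = int(round(a / pitch))
        if step < 1:
            continue
        samples = []
        for di, dj in ((step, 0), (-step, 0), (0, step), (0, -step)):
            i, j = pi + di, pj + dj
            if 0 <= i < temps.shape[0] and 0 <= j < temps.shape[1]:
                samples.append(temps[i, j])
        if not samples:
            continue
        t_a = float(np.mean(samples))
        if t_a - grid.T_env_C > eps and t_max - t_a > eps:
            pairs.append(ObservationPair(T_max=t_max, T_a=t_a,
                                         a=step * pitch, T_env=grid.T_env_C))
    return t_max, pairs, (ci, cj), warnings


def localize_from_thermogram(data, tissue: TissueParams, *,
                             offsets=None,
                             radius_method: str = "eq-intensity-free",
                             A_t: float = DEFAULT_CELL_VOLUME) -> InversionResult:
    """Estimate (d, Q, R) of the source underlying a profile or grid.

    Parameters
    ----------
    data : TemperatureProfile or ThermogramGrid
        Surface temperatures with an ambient reference. The peak must be a
        genuine elevation above ambient.
    tissue : TissueParams
        Supplies h0 and q_m.
    offsets : sequence of float, optional
        Lateral offsets (m) at which to read the local temperature. For a
        grid they are snapped to whole pixels and the four axis-aligned
        pixels at each offset are averaged; default uses 2-4 pixel radii.
        For a profile the default uses every usable sample.
    radius_method : {"eq-intensity-free", "from-intensity"}
        Whether R comes from the intensity-free relation (default) or from
        the estimated intensity via the cube-root formula.
    A_t : float
        Volume constant of the radius formula.

    Per-offset estimates are combined by the median (robust to noise);
    on noiseless data every offset gives the identical value.
    """
    if radius_method not in ("eq-intensity-free", "from-intensity"):
        raise ValueError(f"unknown radius_method {radius_method!r}")

    warnings: list[str] = []
    if isinstance(data, TemperatureProfile):
        t_env = data.T_env_C
        t_max, pairs = _observations_from_profile(data)
        if offsets is not None and pairs:
            chosen = {min(pairs, key=lambda p: abs(p.a - a)) for a in offsets}
            pairs = [p for p in pairs if p in chosen]
        if data.peak_offset in (data.offsets[0], data.offsets[-1]):
            warnings.append("peak-on-boundary")
    else:  # ThermogramGrid (duck-typed: temps, pixel_pitch, T_env_C)
        t_env = data.T_env_C
        t_max, pairs, _centroid, grid_warnings = _observations_from_grid(
            data, offsets)
        warnings.extend(grid_warnings)

    if t_max - t_env <= 1e-9 or not pairs:
        raise NoSourceDetectedError(
            "no source detected: thermogram shows no usable elevation above ambient"
        )

    d_effs = np.array([depth_from_temps(p) for p in pairs])
    qs = np.array([intensity_from_temps(p, tissue.h0) for p in pairs])
    d_eff = float(np.median(d_effs))
    q = float(np.median(qs))

    if radius_method == "eq-intensity-free":
        rs = np.array([
            radius_depth_relation(p.T_a, p.T_env, p.a, d_eff, tissue.h0,
                                  tissue.q_m, A_t)
            for p in pairs
        ])
        r = float(np.median(rs))
    else:
        r = radius_from_intensity(q, tissue.q_m, A_t)

    return InversionResult(
        d_eff=d_eff, Q=q, R=r, d=max(d_eff - r, 0.0),
        observations=tuple(pairs),
        method_flags={"radius_method": radius_method, "A_t": A_t,
                      "n_offsets": len(pairs), "warnings": warnings},
    )


# ---------------------------------------------------------------------------
# Application workflow: three scalars, optional depth range


@dataclass(frozen=True)
class ApplicationEstimate:
    """Output of the three-temperature clinical workflow."""

    d_eff: float
    Q: float
    R: float
    d: float
    depth_grid: np.ndarray | None = None
    Q_over_depths: np.ndarray | None = None
    Q_mean: float | None = None


def estimate_source(T_env: float, T_skin: float, T_max: float, a: float,
                    tissue: TissueParams, *,
                    depth_range: tuple[float, float] | None = None,
                    n_depths: int = 9,
                    A_t: float = DEFAULT_CELL_VOLUME) -> ApplicationEstimate:
    """Clinical-style estimate from ambient, local-skin and peak temperatures.

    ``T_skin`` is the surface temperature read at lateral offset ``a`` from
    the hottest point. When only a depth *range* is plausible (e.g. sources
    shallower than the emission depth of the dermis), the intensity is also
    reported over a uniform grid of effective depths in that range together
    with its mean.
    """
    obs = ObservationPair(T_max=T_max, T_a=T_skin, a=a, T_env=T_env)
    d_eff = depth_from_temps(obs)
    q = intensity_from_temps(obs, tissue.h0)
    r = radius_depth_relation(T_skin, T_env, a, d_eff, tissue.h0,
                              tissue.q_m, A_t)
    depth_grid = q_over = q_mean = None
    if depth_range is not None:
        lo, hi = depth_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid depth range {depth_range!r}")
        depth_grid = np.linspace(lo, hi, n_depths)
        q_over = (FOUR_PI * tissue.h0 * (T_skin - T_env)
                  * (depth_grid**2 + a**2))
        q_mean = float(q_over.mean())
    return ApplicationEstimate(d_eff=d_eff, Q=q, R=r,
                               d=max(d_eff - r, 0.0),
                               depth_grid=depth_grid, Q_over_depths=q_over,
                               Q_mean=q_mean)
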