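"""Sensitivity studies: parameter perturbations and temperature errors.

Two questions drive this module: how much does the surface temperature move
when one source parameter (intensity, depth, radius) is mis-estimated by a
given fraction, and how much does a random measurement error on the
temperatures themselves corrupt the readings the inversion consumes. The
third piece is the relative-error bookkeeping used to compare true vs
recovered source parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import TemperatureProfile, surface_profile
from .params import HeatSource, TissueParams

__all__ = [
    "PerturbationResult",
    "perturb_parameter",
    "TemperaturePerturbation",
    "temperature_perturbation_study",
    "relative_error_table",
]


@dataclass(frozen=True)
class PerturbationResult:
    """Effect of changing one source parameter on the surface profile."""

    param: str
    base_value: float
    perturbed_value: float
    fraction: float           # signed relative change, exact
    delta_Tmax: float         # |peak(base) - peak(perturbed)|, degC
    delta_profile: np.ndarray  # per-offset perturbed - base, degC
    base_profile: TemperatureProfile
    perturbed_profile: TemperatureProfile


def perturb_parameter(base: HeatSource, tissue: TissueParams, param: str,
                      fraction: float | None = None,
                      offsets=None,
                      new_value: float | None = None) -> PerturbationResult:
    """Perturb one of {Q, d, R} and report the surface-temperature change.

    Exactly one of ``fraction`` (signed relative change) or ``new_value``
    (explicit perturbed value) must be given. Deterministic.
    """
    if param not in ("Q", "d", "R"):
        raise ValueError(f"param must be one of 'Q', 'd', 'R', got {param!r}")
    if (fraction is None) == (new_value is None):
        raise ValueError("give exactly one of fraction or new_value")
    base_value = getattr(base, param)
    if new_value is None:
        new_value = base_value * (1.0 + fraction)
    if base_value != 0:
        fraction = (new_value - base_value) / base_value
    elif fraction is None:
        fraction = float("inf") if new_value != 0 else 0.0
    if offsets is None:
        offsets = np.linspace(-0.1, 0.1, 401)
    perturbed = base.replace(**{param: new_value})  # validates d+R > 0 etc.
    base_prof = surface_profile(base, tissue, offsets)
    pert_prof = surface_profile(perturbed, tissue, offsets)
    delta = pert_prof.temps - base_prof.temps
    return PerturbationResult(
        param=param, base_value=base_value, perturbed_value=new_value,
        fraction=fraction,
        delta_Tmax=abs(pert_prof.peak_temperature - base_prof.peak_temperature),
        delta_profile=delta,
        base_profile=base_prof, perturbed_profile=pert_prof,
    )


@dataclass(frozen=True)
class TemperaturePerturbation:
    """A randomly perturbed profile with its deviation summary."""

    perturbed: TemperatureProfile
    max_deviation: float      # max |perturbed - original| realized, degC
    worst_case_bound: float   # analytic bound on the deviation, degC
    mode: str
    fraction: float
    seed: int


def temperature_perturbation_study(profile: TemperatureProfile,
                                   fraction: float, mode: str = "absolute",
                                   seed: int = 0) -> TemperaturePerturbation:
    """Apply a random +/-fraction measurement error to a profile.

    mode="absolute": each temperature (degC) is multiplied by (1 + u) with
    u ~ Uniform(-fraction, fraction) i.i.d.; the worst case deviation is
    fraction * max(T).

    mode="range": each temperature is shifted by u * (T_max - T_min), i.e.
    the error is scaled by the profile's span rather than its absolute
    level; the worst case deviation is fraction * span.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction!r}")
    if mode not in ("absolute", "range"):
        raise ValueError(f"mode must be 'absolute' or 'range', got {mode!r}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-fraction, fraction, size=profile.temps.shape)
    if mode == "absolute":
        new_temps = profile.temps * (1.0 + u)
        bound = fraction * float(np.max(np.abs(profile.temps)))
    else:
        span = profile.span
        new_temps = profile.temps + u * span
        bound = fraction * span
    perturbed = TemperatureProfile(offsets=profile.offsets, temps=new_temps,
                                   T_env_C=profile.T_env_C)
    return TemperaturePerturbation(
        perturbed=perturbed,
        max_deviation=float(np.max(np.abs(new_temps - profile.temps))),
        worst_case_bound=bound, mode=mode, fraction=fraction, seed=seed,
    )


def relative_error_table(true_params: HeatSource,
                         estimated_params: HeatSource,
                         denominator: str = "original") -> pd.DataFrame:
    """Per-parameter relative errors between a true and an estimated source.

    Returns a DataFrame with columns parameter / original_value /
    optimized_value / error_percent, the latter rounded to 2 decimals.
    ``denominator`` selects the convention: "original" (default) divides by
    the true value, "optimized" by the estimate. A zero denominator leaves
    the row's error as NaN and sets the ``undefined`` flag instead of
    dividing.
    """
    if denominator not in ("original", "optimized"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    rows = []
    for name in ("d", "R", "Q"):
        true = getattr(true_params, name)
        est = getattr(estimated_params, name)
        denom = true if denominator == "original" else est
        if denom == 0:
            err, undefined = float("nan"), True
        else:
            err, undefined = round(100.0 * abs(est - true) / denom, 2), False
        rows.append({"parameter": name, "original_value": true,
                     "optimized_value": est, "error_percent": err,
                     "undefined": undefined})
    return pd.DataFrame(rows)
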