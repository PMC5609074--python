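"""Synthetic thermograms, CSV serialization, and configuration.

A thermogram is a rectangular grid of surface temperatures (degC) with an
isotropic pixel pitch (m/pixel) and an ambient reference, standing in for
a calibrated IR image. Synthetic grids evaluate the forward surface model
at the radial distance of every pixel from the hotspot centre and record
full provenance (source, ambient, noise kind/magnitude/seed) so any
artifact can be regenerated from its own header.

File dialect: ``# key = value`` header lines (T_env_C, pixel_pitch_m,
origin_m, optionally offsets_m for 1D profiles, provenance as JSON),
followed by a plain comma-separated numeric matrix. Pixel (0,0) is the
top-left; physical coordinates are origin + index * pixel_pitch, metres.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .forward import TemperatureProfile, surface_temperature
from .params import HeatSource, TissueParams

__all__ = [
    "ThermogramGrid",
    "NoiseSpec",
    "ThermogramParseError",
    "generate_synthetic_thermogram",
    "generate_synthetic_profile",
    "write_thermogram",
    "read_thermogram",
    "write_profile",
    "load_tissue_config",
]

_NOISE_KINDS = ("none", "elevation_percent", "absolute_percent",
                "gaussian_additive")


class ThermogramParseError(ValueError):
    """Raised when a thermogram CSV is malformed."""


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description for synthetic thermograms.

    kind="elevation_percent" multiplies the elevation above ambient by
    (1+u), u ~ Uniform(-magnitude, magnitude) — ambient stays exact, the
    natural model when the ambient is measured independently.
    kind="absolute_percent" multiplies the absolute temperature (degC).
    kind="gaussian_additive" adds N(0, magnitude) degC.
    """

    kind: str = "none"
    magnitude: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; "
                             f"expected one of {_NOISE_KINDS}")
        if self.magnitude < 0:
            raise ValueError(f"noise magnitude must be >= 0, got {self.magnitude!r}")
        if self.kind != "none" and self.seed is None:
            raise ValueError(f"a seed is mandatory for noise kind {self.kind!r}")

    def apply(self, temps: np.ndarray, t_env_c: float) -> np.ndarray:
        if self.kind == "none":
            return temps
        rng = np.random.default_rng(self.seed)
        if self.kind == "elevation_percent":
            u = rng.uniform(-self.magnitude, self.magnitude, size=temps.shape)
            return t_env_c + (temps - t_env_c) * (1.0 + u)
        if self.kind == "absolute_percent":
            u = rng.uniform(-self.magnitude, self.magnitude, size=temps.shape)
            return temps * (1.0 + u)
        return temps + rng.normal(0.0, self.magnitude, size=temps.shape)


@dataclass(frozen=True)
class ThermogramGrid:
    """2D surface-temperature image with spatial metadata.

    temps: row-major degC array; pixel_pitch: m per pixel (isotropic);
    origin: physical (x, y) of pixel (0, 0) in m; T_env_C: ambient degC;
    provenance: generator parameters and seed, or {"source": "measured"}.
    """

    temps: np.ndarray
    pixel_pitch: float
    T_env_C: float
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: dict = field(default_factory=lambda: {"source": "measured"})

    def __post_init__(self) -> None:
        temps = np.asarray(self.temps, dtype=float)
        if temps.ndim != 2 or temps.size == 0:
            raise ValueError("temps must be a non-empty 2D array")
        if not self.pixel_pitch > 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch!r}")
        object.__setattr__(self, "temps", temps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps.shape


def generate_synthetic_thermogram(source: HeatSource, tissue: TissueParams,
                                  shape: tuple[int, int],
                                  pixel_pitch: float,
                                  center: tuple[float, float] | None = None,
                                  noise: NoiseSpec = NoiseSpec()) -> ThermogramGrid:
    """Forward-model thermogram on a rows x cols pixel lattice.

    ``center`` is the physical (x, y) position of the hotspot in metres;
    by default it sits exactly on the central pixel so noiseless grids
    invert to machine precision. Deterministic for a given noise seed.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"grid shape must be positive, got {shape!r}")
    if center is None:
        center = ((cols // 2) * pixel_pitch, (rows // 2) * pixel_pitch)
    x = np.arange(cols) * pixel_pitch
    y = np.arange(rows) * pixel_pitch
    rr = np.hypot(x[None, :] - center[0], y[:, None] - center[1])
    temps = surface_temperature(source, tissue, rr)
    temps = noise.apply(np.asarray(temps, dtype=float), tissue.T_env_C)
    provenance = {
        "source": {"Q": source.Q, "d": source.d, "R": source.R},
        "T_env_C": tissue.T_env_C, "h0": tissue.h0,
        "shape": [rows, cols], "pixel_pitch_m": pixel_pitch,
        "center_m": list(center),
        "noise": {"kind": noise.kind, "magnitude": noise.magnitude,
                  "seed": noise.seed},
    }
    return ThermogramGrid(temps=temps, pixel_pitch=pixel_pitch,
                          T_env_C=tissue.T_env_C, provenance=provenance)


def generate_synthetic_profile(source: HeatSource, tissue: TissueParams,
                               offsets, noise: NoiseSpec = NoiseSpec()
                               ) -> TemperatureProfile:
    """1D forward-model profile with optional noise, same conventions."""
    offsets = np.asarray(offsets, dtype=float)
    temps = np.asarray(surface_temperature(source, tissue, offsets))
    temps = noise.apply(temps, tissue.T_env_C)
    return TemperatureProfile(offsets=offsets, temps=temps,
                              T_env_C=tissue.T_env_C)


# ---------------------------------------------------------------------------
# CSV dialect

_MANDATORY_KEYS = ("T_env_C", "pixel_pitch_m")


def _format_matrix(arr: np.ndarray, decimals: int | None) -> list[str]:
    if decimals is None:
        fmt = lambda v: repr(float(v))
    else:
        fmt = ("{:." + str(decimals) + "f}").format
    return [",".join(fmt(v) for v in row) for row in np.atleast_2d(arr)]


def write_thermogram(grid: ThermogramGrid, path, decimals: int | None = 6) -> None:
    """Write a grid in the ``# key = value`` + CSV-matrix dialect.

    ``decimals`` controls the serialized precision (None = full repr).
    """
    lines = [
        f"# T_env_C = {float(grid.T_env_C)!r}",
        f"# pixel_pitch_m = {float(grid.pixel_pitch)!r}",
        f"# origin_m = {float(grid.origin[0])!r},{float(grid.origin[1])!r}",
        f"# provenance = {json.dumps(grid.provenance)}",
    ]
    lines += _format_matrix(grid.temps, decimals)
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile(profile: TemperatureProfile, path,
                  decimals: int | None = 6) -> None:
    """Write a 1D profile: offsets in the header, one temperature row."""
    lines = [
        f"# T_env_C = {float(profile.T_env_C)!r}",
        "# pixel_pitch_m = 0.0",
        f"# offsets_m = {','.join(repr(float(o)) for o in profile.offsets)}",
        f"# provenance = {json.dumps({'source': 'profile'})}",
    ]
    lines += _format_matrix(profile.temps, decimals)
    Path(path).write_text("\n".join(lines) + "\n")


def read_thermogram(path):
    """Read the dialect back; returns ThermogramGrid, or TemperatureProfile
    when an ``offsets_m`` header marks a 1D profile.

    Raises ThermogramParseError naming the missing header key or the index
    of a ragged row.
    """
    header: dict[str, str] = {}
    data_rows: list[list[float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
            continue
        try:
            data_rows.append([float(tok) for tok in line.split(",")])
        except ValueError as exc:
            raise ThermogramParseError(
                f"non-numeric entry in data row {len(data_rows)} "
                f"(line {lineno}): {exc}") from None
    for key in _MANDATORY_KEYS:
        if key not in header:
            raise ThermogramParseError(f"missing mandatory header key {key!r}")
    if not data_rows:
        raise ThermogramParseError("no data rows found")
    width = len(data_rows[0])
    for i, row in enumerate(data_rows):
        if len(row) != width:
            raise ThermogramParseError(
                f"ragged data: row {i} has {len(row)} values, expected {width}")

    t_env = float(header["T_env_C"])
    temps = np.asarray(data_rows, dtype=float)

    if "offsets_m" in header:
        offsets = np.array([float(tok) for tok in header["offsets_m"].split(",")])
        flat = temps.ravel()
        if offsets.size != flat.size:
            raise ThermogramParseError(
                f"offsets_m has {offsets.size} entries but the matrix has "
                f"{flat.size} values")
        return TemperatureProfile(offsets=offsets, temps=flat, T_env_C=t_env)

    origin = (0.0, 0.0)
    if "origin_m" in header:
        ox, oy = header["origin_m"].split(",")
        origin = (float(ox), float(oy))
    provenance = (json.loads(header["provenance"])
                  if "provenance" in header else {"source": "measured"})
    return ThermogramGrid(temps=temps, pixel_pitch=float(header["pixel_pitch_m"]),
                          T_env_C=t_env, origin=origin, provenance=provenance)


def load_tissue_config(path) -> TissueParams:
    """Tissue parameters from a flat YAML mapping; absent keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("tissue config must be a flat key: value mapping")
    known = {f.name for f in dataclasses.fields(TissueParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown tissue parameter(s) in config: {sorted(unknown)}")
    if "Q_t_range" in raw:
        raw["Q_t_range"] = tuple(raw["Q_t_range"])
    return TissueParams(**raw)
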