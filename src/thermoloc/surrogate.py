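"""Neural surrogate of the forward model and parameter refinement.

A small feed-forward network — three inputs (Q, d, R), one hidden layer of
sigmoidal units, linear output — is trained on seeded samples of the
forward model and then used as a cheap stand-in during parameter
refinement: a derivative-free bounded search adjusts an initial (Q, d, R)
guess to minimize the mismatch between the surrogate's predicted surface
profile and an observed one.

Two numerical choices matter. First, the network is trained on the
*logarithm of the elevation* above ambient (per-output min-max normalized)
rather than on raw temperatures: the elevation spans orders of magnitude
across the parameter ranges and a 10-unit network only reaches
hundredth-of-a-degree peak accuracy on the log scale. Second, the surface
model depends on depth and radius only through their sum d + R, so the
profile mismatch has an exactly flat ridge along (d + delta, R - delta);
the refinement objective adds a small proximity penalty toward the initial
guess, which deterministically selects the ridge point nearest the initial
values instead of drifting arbitrarily along it.

Training goes through scikit-learn's MLPRegressor (L-BFGS, deterministic
for a fixed seed, best of a few seeded restarts); prediction is a plain
numpy forward pass from the stored weights, so a serialized model reloads
bit-exactly and predicts without any fitted estimator state.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .forward import TemperatureProfile, surface_temperature
from .params import HeatSource, TissueParams

__all__ = [
    "SurrogateConfig",
    "TrainingSet",
    "SurrogateModel",
    "RefinementResult",
    "sample_training_data",
    "train_surrogate",
    "refine_parameters",
]

PARAM_ORDER = ("Q", "d", "R")

# neighbourhood of the low-intensity reference source (Q=0.35 W, d=2 cm,
# R=5 mm) that the default accuracy threshold is calibrated for
DEFAULT_RANGES = {"Q": (0.30, 0.42), "d": (0.015, 0.025), "R": (0.0, 0.008)}
DEFAULT_OFFSETS = tuple(np.linspace(-0.05, 0.05, 21))


@dataclass(frozen=True)
class SurrogateConfig:
    """Training-time knobs of the surrogate.

    hidden_units: width of the single hidden layer (default 10).
    training_set_size: number of (Q, d, R) samples drawn uniformly from
    ``parameter_ranges`` (low/high per parameter). ``offsets`` fixes the
    lateral grid (m) of the profile target; target="peak" trains on the
    peak temperature only. ``n_restarts`` seeded weight initializations
    are trained and the one with the best held-out error kept.
    ``regularization`` is the weight of the proximity penalty used during
    refinement (see module docstring). All randomness flows from ``seed``.
    """

    hidden_units: int = 10
    training_set_size: int = 500
    parameter_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    seed: int = 0
    max_epochs: int = 15000
    tolerance: float = 1e-10
    target: str = "profile"
    offsets: tuple = DEFAULT_OFFSETS
    validation_fraction: float = 0.2
    rmse_threshold: float = 0.05
    n_restarts: int = 5
    output_transform: str = "log-elevation"
    regularization: float = 0.01

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.target not in ("profile", "peak"):
            raise ValueError(f"target must be 'profile' or 'peak', got {self.target!r}")
        if self.output_transform not in ("log-elevation", "identity"):
            raise ValueError(f"unknown output_transform {self.output_transform!r}")
        if set(self.parameter_ranges) != set(PARAM_ORDER):
            raise ValueError(f"parameter_ranges must have keys {PARAM_ORDER}")
        for name, (lo, hi) in self.parameter_ranges.items():
            if lo > hi:
                raise ValueError(f"range for {name} must have low <= high, "
                                 f"got ({lo!r}, {hi!r})")
            if lo < 0:
                raise ValueError(f"range for {name} must be non-negative")
        d_lo = self.parameter_ranges["d"][0]
        r_lo = self.parameter_ranges["R"][0]
        if d_lo + r_lo <= 0:
            raise ValueError("ranges admit a surface-singular source "
                             "(d + R = 0 at the lower corners)")


@dataclass(frozen=True)
class TrainingSet:
    X: np.ndarray          # (n, 3) columns Q, d, R
    Y: np.ndarray          # (n, m) profile temps, or (n, 1) peaks
    offsets: np.ndarray
    T_env_C: float
    seed: int


def sample_training_data(config: SurrogateConfig, tissue: TissueParams,
                         offsets=None) -> TrainingSet:
    """Seeded uniform samples of (Q, d, R) with noiseless forward targets."""
    offsets = np.asarray(config.offsets if offsets is None else offsets,
                         dtype=float)
    rng = np.random.default_rng(config.seed)
    lows = np.array([config.parameter_ranges[p][0] for p in PARAM_ORDER])
    highs = np.array([config.parameter_ranges[p][1] for p in PARAM_ORDER])
    X = rng.uniform(lows, highs, size=(config.training_set_size, 3))
    X = np.where(highs > lows, X, lows)  # degenerate ranges collapse to a point
    profiles = np.array([
        surface_temperature(HeatSource(Q=q, d=d, R=r), tissue, offsets)
        for q, d, r in X
    ])
    Y = (profiles if config.target == "profile"
         else profiles.max(axis=1, keepdims=True))
    return TrainingSet(X=X, Y=Y, offsets=offsets, T_env_C=tissue.T_env_C,
                       seed=config.seed)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SurrogateModel:
    """Frozen weights + normalization of a trained 3->hidden->m network.

    ``transform`` names the output-space encoding ("log-elevation" stores
    log(T - T_env) per offset, "identity" raw degC); y_low/y_high are the
    per-output min-max constants in that space.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    x_low: np.ndarray
    x_high: np.ndarray
    y_low: np.ndarray
    y_high: np.ndarray
    offsets: np.ndarray
    T_env_C: float
    transform: str = "identity"
    metadata: dict = field(default_factory=dict)

    def _encode_x(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.x_high > self.x_low, self.x_high - self.x_low, 1.0)
        return (X - self.x_low) / span

    def _decode_y(self, Yn: np.ndarray) -> np.ndarray:
        span = np.where(self.y_high > self.y_low, self.y_high - self.y_low, 1.0)
        Yt = Yn * span + self.y_low
        if self.transform == "log-elevation":
            return np.exp(Yt) + self.T_env_C
        return Yt

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Surface temperatures (degC) for (n, 3) parameter rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        hidden = _sigmoid(self._encode_x(X) @ self.W1 + self.b1)
        return self._decode_y(hidden @ self.W2 + self.b2)

    def predict_profile(self, source: HeatSource) -> np.ndarray:
        return self.predict(np.array([[source.Q, source.d, source.R]]))[0]

    def in_training_range(self, source: HeatSource) -> bool:
        x = np.array([source.Q, source.d, source.R])
        return bool(np.all(x >= self.x_low) and np.all(x <= self.x_high))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "x_low": self.x_low.tolist(), "x_high": self.x_high.tolist(),
            "y_low": self.y_low.tolist(), "y_high": self.y_high.tolist(),
            "offsets": self.offsets.tolist(), "T_env_C": self.T_env_C,
            "transform": self.transform, "metadata": self.metadata,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        p = json.loads(text)
        return cls(
            W1=np.array(p["W1"]), b1=np.array(p["b1"]),
            W2=np.array(p["W2"]), b2=np.array(p["b2"]),
            x_low=np.array(p["x_low"]), x_high=np.array(p["x_high"]),
            y_low=np.array(p["y_low"]), y_high=np.array(p["y_high"]),
            offsets=np.array(p["offsets"]), T_env_C=p["T_env_C"],
            transform=p["transform"], metadata=p["metadata"],
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        return cls.from_json(Path(path).read_text())


def _peak_rmse(pred: np.ndarray, true: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred.max(axis=1) - true.max(axis=1)) ** 2)))


def train_surrogate(data: TrainingSet, config: SurrogateConfig) -> SurrogateModel:
    """Fit the network on 80% of the data; validate on the held-out rest.

    Of ``n_restarts`` seeded initializations the one with the lowest
    held-out peak RMSE is kept (lowest training loss when no validation
    split is possible). Non-convergence within max_epochs is flagged in
    the metadata, never silent. Fully reproducible from the config seed.
    """
    n = data.X.shape[0]
    if n == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(data.seed)
    perm = rng.permutation(n)
    n_val = int(round(n * config.validation_fraction)) if n > 4 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    x_low = np.array([config.parameter_ranges[p][0] for p in PARAM_ORDER])
    x_high = np.array([config.parameter_ranges[p][1] for p in PARAM_ORDER])
    x_span = np.where(x_high > x_low, x_high - x_low, 1.0)

    transform = config.output_transform
    if transform == "log-elevation" and np.any(data.Y <= data.T_env_C):
        transform = "identity"  # elevation not strictly positive: no log
    Yt = np.log(data.Y - data.T_env_C) if transform == "log-elevation" else data.Y
    y_low = Yt.min(axis=0)
    y_high = Yt.max(axis=0)
    y_span = np.where(y_high > y_low, y_high - y_low, 1.0)

    Xn = (data.X - x_low) / x_span
    Yn = (Yt - y_low) / y_span
    if Yn.shape[1] == 1:
        Yn_fit = Yn.ravel()
    else:
        Yn_fit = Yn

    best = None
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        for restart in range(config.n_restarts):
            reg = MLPRegressor(
                hidden_layer_sizes=(config.hidden_units,),
                activation="logistic", solver="lbfgs",
                max_iter=config.max_epochs, tol=config.tolerance,
                alpha=0.0, max_fun=10 * config.max_epochs,
                random_state=int(config.seed * 1000 + restart) % (2**31 - 1),
            )
            reg.fit(Xn[train_idx],
                    Yn_fit[train_idx] if Yn_fit.ndim == 1 else Yn_fit[train_idx])
            if n_val:
                pred_n = np.atleast_2d(reg.predict(Xn[val_idx]))
                if pred_n.shape[0] == 1 and len(val_idx) > 1:
                    pred_n = pred_n.T
                pred_t = pred_n * y_span + y_low
                pred = (np.exp(pred_t) + data.T_env_C
                        if transform == "log-elevation" else pred_t)
                score = _peak_rmse(pred, data.Y[val_idx])
            else:
                score = float(reg.loss_)
            if best is None or score < best[0]:
                best = (score, reg, restart)
    score, reg, restart = best

    converged = reg.n_iter_ < config.max_epochs
    coef2 = reg.coefs_[1]
    int2 = np.atleast_1d(reg.intercepts_[1])
    if coef2.ndim == 1:
        coef2 = coef2[:, None]
    metadata = {
        "seed": data.seed, "final_loss": float(reg.loss_),
        "n_iter": int(reg.n_iter_), "converged": bool(converged),
        "restart_used": restart, "hidden_units": config.hidden_units,
        "target": config.target, "transform": transform,
        "training_set_size": config.training_set_size,
    }
    if n_val:
        metadata["validation_peak_rmse"] = score
        metadata["validation_ok"] = bool(score < config.rmse_threshold)
    return SurrogateModel(
        W1=reg.coefs_[0], b1=reg.intercepts_[0], W2=coef2, b2=int2,
        x_low=x_low, x_high=x_high, y_low=np.atleast_1d(y_low),
        y_high=np.atleast_1d(y_high), offsets=data.offsets,
        T_env_C=data.T_env_C, transform=transform, metadata=metadata,
    )


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of surrogate-based refinement of an initial guess."""

    initial: HeatSource
    optimized: HeatSource
    # |peak of analytic model - peak of surrogate|, both at the optimized
    # parameters (falls back to the observed peak without tissue params)
    peak_discrepancy: float
    converged: bool
    mismatch_initial: float
    mismatch_optimized: float
    warnings: tuple[str, ...] = ()


def refine_parameters(initial: HeatSource, observed: TemperatureProfile,
                      model: SurrogateModel,
                      config: SurrogateConfig | None = None,
                      tissue: TissueParams | None = None,
                      bounds=None) -> RefinementResult:
    """Bounded derivative-free fit of (Q, d, R) to an observed profile.

    Minimizes the sum of squared differences between the surrogate's
    profile and the observed one (interpolated onto the surrogate's
    offsets, centred on the observed peak) with a Nelder-Mead search
    clipped to ``bounds`` (default: the surrogate's training ranges). A
    proximity penalty of weight ``config.regularization`` on the
    range-normalized distance from the initial guess resolves the d/R
    ridge. Guaranteed never to return a point with a worse (unpenalized)
    mismatch than the initial guess.
    """
    if config is None:
        config = SurrogateConfig()
    warnings: list[str] = []
    if not model.in_training_range(initial):
        warnings.append("initial-outside-training-range")
    if bounds is None:
        bounds = list(zip(model.x_low, model.x_high))

    obs_at = np.interp(model.offsets,
                       observed.offsets - observed.peak_offset,
                       observed.temps)
    scale = np.where(model.x_high > model.x_low,
                     model.x_high - model.x_low, 1.0)
    x0 = np.array([initial.Q, initial.d, initial.R])

    def mismatch(x: np.ndarray) -> float:
        pred = model.predict(x[None, :])[0]
        return float(np.sum((pred - obs_at) ** 2))

    lam = config.regularization

    def objective(x: np.ndarray) -> float:
        return mismatch(x) + lam * float(np.sum(((x - x0) / scale) ** 2))

    f0 = mismatch(x0)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x_start = np.clip(x0, lo, hi)  # NM needs an in-bounds start
    res = minimize(objective, x_start, method="Nelder-Mead", bounds=bounds,
                   options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 2000})
    f_res = mismatch(res.x)
    if f_res <= f0:
        x_best, f_best = np.maximum(res.x, 0.0), f_res
    else:  # keep the initial point: refinement must never hurt
        x_best, f_best = x0, f0
    optimized = HeatSource(Q=float(x_best[0]), d=float(x_best[1]),
                           R=float(x_best[2]))
    surrogate_peak = float(np.max(model.predict_profile(optimized)))
    if tissue is not None:
        model_peak = float(np.max(
            surface_temperature(optimized, tissue, model.offsets)))
    else:
        model_peak = float(np.max(observed.temps))
    peak_disc = abs(model_peak - surrogate_peak)
    return RefinementResult(
        initial=initial, optimized=optimized, peak_discrepancy=peak_disc,
        converged=bool(res.success), mismatch_initial=f0,
        mismatch_optimized=f_best, warnings=tuple(warnings),
    )
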