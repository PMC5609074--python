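# Methods

## Forward model

The tissue is treated as a homogeneous, isotropic half-space in steady
state. Blood-perfusion heat exchange and the tumour's metabolic excess are
absorbed into a single equivalent point source of total power Q (W); the
time-dependent term of the bioheat balance vanishes under the static
assumption. Conduction from a point source gives the radial field
T(r) = Q/(4πkr) + T₀ (`point_source_field`), and equating the source power
with convective loss through the skin surface yields the lateral surface
profile

    T(a) = T_e + Q / (4π h₀ [(d + R)² + a²])

(`surface_temperature`). A spherical source of radius R at depth d enters
only through the effective depth d_eff = d + R; the package asserts this
equivalence bit-exactly rather than approximating it.

**Convention note.** Two variants of the surface formula circulate, one
dividing by 4h₀ and one by 4πh₀. The package adopts 4πh₀ throughout: it is
the convention consistent with the intensity inversion formula and the one
that reproduces every cross-checkable reference number handled by the test
suite (the 28.2996 °C peak, the 1.6597 °C span, and the 0.41/0.24/0.3 °C
perturbation shifts). The choice is recorded once per CLI run in the log.

**Units.** Internally SI (m, W, W/(m²·K)); temperatures are handled in °C,
with the tabulated Kelvin defaults (310.15 K arterial, 300.15 K ambient)
exposed through °C accessors. Every model output depends only on
temperature differences, so the °C/K choice is observationally neutral.

## Tissue parameters

`TissueParams` defaults are the standard constants for sound breast
tissue: k = 0.52 W/(m·K), h₀ = 8.77 W/(m²·K), c_b = 4186 J/(kg·K),
ρ_b = 1000 kg/m³, q_m = 700 W/m³, tumour metabolic generation
25 000–90 000 W/m³, ω_b = 5.2·10⁻⁴ s⁻¹, T_arterial = 310.15 K,
T_env = 300.15 K. Tissue density and specific heat are accepted but
unused in steady state. All are overridable programmatically or through a
flat YAML config.

The sensitivity reference case (Q = 0.045 W, d = 1.05 cm, R = 5 mm) is
evaluated against a 26.6 °C ambient. That value is not a tabulated
constant: it is the ambient implied by the reference peak/edge pair
(28.2996, 26.6399 °C) under the adopted convention, and is shipped as a
documented fixture value.

## Inversion

`depth_from_temps` provably returns the effective depth d + R of the
equivalent point source — never the geometric depth — so d_eff is the
primary estimand and the reported geometric depth is the decomposition
d = d_eff − R floored at zero. `radius_from_intensity` implements the
cube-root relation R = (Q/(q_m·A_t))^{1/3} with A_t = 10⁻⁶ by default, the
constant that makes it exactly consistent with the intensity-free radius
relation (`radius_depth_relation`); the relation's units do not cohere
dimensionally, so it is provided exactly as conventionally printed, with
both constants configurable, and no physical plausibility is asserted for
the resulting radii.

`localize_from_thermogram` locates the peak (ties broken by the centroid
of the argmax set, for sub-pixel stability), reads local temperatures at
one or more lateral offsets (on grids: the four axis-aligned pixels at
each whole-pixel radius, averaged), forms one estimate per offset and
combines them by the median — robust to noise, and exactly offset-
invariant on noiseless data. Flat inputs raise a "no source detected"
error; a peak on the image boundary sets a warning flag.

The three-temperature workflow (`estimate_source`) consumes the ambient,
the peak and one local skin temperature. When only a depth band is
plausible, the intensity is additionally reported over a uniform grid of
effective depths in the band together with its mean — a documented
averaging convention for depth uncertainty, not an attempt to reproduce
any particular historical average.

## Neural surrogate and refinement

The surrogate is a feed-forward network with 3 inputs (Q, d, R), one
hidden layer of 10 logistic units and a linear output predicting the
surface profile on a fixed lateral grid (default 21 offsets spanning
±5 cm; a peak-only target is available). Training data are uniform seeded
samples from per-parameter ranges, targets the noiseless forward model.
Fitting uses scikit-learn's MLPRegressor with L-BFGS; all sampling, the
80/20 validation split and weight initialization derive from one seed, so
retraining is bit-reproducible. Non-convergence is flagged in the model
metadata, never silent. Models serialize to a single JSON file and reload
bit-exactly; prediction is a plain numpy forward pass.

Three numerical choices were made where the design was genuinely open:

- **Output encoding.** The network is trained on log(T − T_e) per offset,
  min-max normalized per output. The elevation spans orders of magnitude
  across realistic parameter ranges and a 10-unit network trained on raw
  °C plateaus at several tenths of a degree of peak error; the log
  encoding brings the held-out peak RMSE below the 0.05 °C threshold over
  the default ranges.
- **Restarts.** L-BFGS on this loss surface lands in poor local optima for
  a substantial fraction of initializations, so `n_restarts` (default 5)
  seeded initializations are trained and the best held-out peak RMSE kept.
- **Ridge regularization of refinement.** The forward model depends on d
  and R only through d + R, so the profile mismatch has an exactly flat
  ridge along (d + δ, R − δ) and an unregularized simplex search drifts
  arbitrarily along it. The refinement objective therefore adds a small
  proximity penalty (weight 0.01 on the range-normalized squared distance
  from the initial guess), which deterministically selects the ridge point
  nearest the initial values. The penalty never degrades the fit: the
  result is accepted only if its *unpenalized* mismatch does not exceed
  the initial one.

Default training ranges bracket the low-intensity reference source
(Q ∈ [0.30, 0.42] W, d ∈ [1.5, 2.5] cm, R ∈ [0, 8] mm); the 0.05 °C
accuracy threshold is calibrated for ranges of this width. Much wider
ranges (e.g. Q down to 0.01 W with depths to 4 cm) put the peak
temperature across a ~0.04–180 °C span, which a 10-unit network cannot fit
to hundredths of a degree; widen the ranges only with a correspondingly
relaxed threshold. `peak_discrepancy` compares the analytic model's peak
with the surrogate's peak, both at the optimized parameters — a direct
measure of surrogate fidelity at the solution.

## Sensitivity machinery

`perturb_parameter` changes one of {Q, d, R} by a signed fraction (or to
an explicit value) and reports the peak shift and per-offset deltas; it is
deterministic and exact, and the suite verifies the linearity of the peak
shift in ΔQ at fixed geometry. Over the reference case, a +20% depth error
moves the peak more than −20% intensity or radius errors — depth is the
dominant sensitivity.

`temperature_perturbation_study` applies i.i.d. uniform ±f errors either
to the absolute reading (worst case f·max T ≈ 1.41 °C at 5% on the
reference peak) or scaled by the profile span (worst case f·span ≈
0.083 °C), seeded. Uniform was chosen because the error model is stated
only as "random ±f"; the distribution is a one-line swap if needed.

`relative_error_table` reports 100·|est − true|/true per parameter,
rounded to two decimals, with zero denominators flagged rather than
divided. The divisor convention is configurable ("original" by default,
"optimized" as the documented alternative) because published error tables
mix the two.

Percent noise for synthetic thermograms defaults to the *elevation* above
ambient rather than the absolute temperature (`elevation_percent`),
because the ambient is independently measured in practice; absolute-
percent and additive-Gaussian models are also provided.

## Synthetic data and I/O

`generate_synthetic_thermogram` evaluates the forward model at every
pixel's radial distance from the hotspot centre (default: the exact
central pixel, so noiseless grids invert to machine precision) and applies
the configured noise. Grids carry full provenance — source, ambient, h₀,
shape, pitch, centre, noise kind/magnitude/seed — sufficient to regenerate
the artifact bit-for-bit from its own header. Files are plain CSV with
`# key = value` headers; temperatures serialize at 6 decimals by default
(quantization of 5·10⁻⁷ °C, negligible against every quantity studied),
or at full precision with `decimals=None`. A single-row variant with an
`offsets_m` header carries 1D profiles.

## What the synthetic generator does and does not emulate

It emulates the forward model's hotspot geometry, ambient reference and
three stylized noise models. It does **not** emulate tissue heterogeneity
or layering, curved anatomy, vascular thermal structure, camera
point-spread/focus effects, or spatially correlated sensor noise. Passing
tests therefore demonstrate the correctness and noise-robustness of the
algorithms under the model's own assumptions, not clinical performance;
the method sees only sources shallow enough to imprint on the skin.

## Problem sizes

The shipped experiments use 41×41 grids, 401-point profiles, 500-sample
training sets, 20 training seeds for the recovery studies and 60-seed
Monte-Carlo for the noisy-inversion distribution — sizes at which every
behaviour of interest (exact round-trips, noise propagation, surrogate
accuracy ordering) is already stable and the full suite runs in well under
a minute.

## Known limitations

- Steady state only; no transient response, no layered or heterogeneous
  tissue, no finite-element reference solution.
- Single-source localization; multiple or extended sources violate the
  model's radial symmetry.
- The radius formulas inherit a dimensional inconsistency from their
  conventional form; treat recovered radii as relative indicators unless
  q_m·A_t is recalibrated.
- The d/R decomposition of an estimated effective depth is only as good
  as the radius estimate; the floored decomposition can return d = 0 when
  the radius formula overshoots.
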