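"""Inverse problem: recover source parameters from a synthetic thermogram.

Simulates a 41x41 thermal image above a point source (0.1 W at 14 mm),
with and without 10% elevation noise, and inverts it back to effective
depth and intensity using only the peak temperature, one ring of local
temperatures, and the ambient reference.
"""

from thermoloc import (HeatSource, NoiseSpec, TissueParams,
                       generate_synthetic_thermogram,
                       localize_from_thermogram)

tissue = TissueParams()
truth = HeatSource(Q=0.1, d=0.014, R=0.0)

for label, noise in (("noiseless", NoiseSpec()),
                     ("10% elevation noise", NoiseSpec("elevation_percent",
                                                       0.10, seed=7))):
    grid = generate_synthetic_thermogram(truth, tissue, (41, 41),
                                         pixel_pitch=0.005, noise=noise)
    result = localize_from_thermogram(grid, tissue)
    print(f"{label}:")
    print(f"  effective depth d+R = {result.d_eff * 1000:7.3f} mm "
          f"(true {truth.d_eff * 1000:.3f} mm)")
    print(f"  intensity Q         = {result.Q * 1000:7.3f} mW "
          f"(true {truth.Q * 1000:.3f} mW)")

print("Noiseless images invert to machine precision; multiplicative noise "
      "on the elevation propagates to a few percent error on both "
      "parameters at this noise level.")
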