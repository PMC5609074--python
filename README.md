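# thermoloc

Thermographic localization of embedded heat sources in tissue.

A tumour's elevated metabolism and vascularization make it a localized heat
source, and its signature reaches the skin: infrared thermography of the
breast shows a hotspot whose height and width encode the source's depth,
power and size. `thermoloc` is a toolkit for the inverse problem behind that
observation, aimed at researchers prototyping thermography-based screening
pipelines and at anyone who needs a transparent, fully seeded testbed for
bioheat inverse methods. It provides:

- a **forward model** of the steady-state skin-surface temperature above an
  embedded point or spherical source,
- the **closed-form inversion** of surface temperatures to source depth,
  intensity and radius,
- a small **feed-forward neural surrogate** used to refine parameter
  estimates against an observed profile,
- **sensitivity studies** (parameter perturbations, random temperature
  errors, relative-error tables),
- **synthetic thermogram** generation and CSV I/O, with a thin `thermoloc`
  command-line interface over all of it.

## The model

Starting from the steady-state bioheat balance in homogeneous tissue, an
embedded source of total power Q (W) produces the radial field
T(r) = Q/(4πkr) + T₀. Balancing the source power against surface convection
(heat-exchange coefficient h₀, W/(m²·K)) gives the surface temperature at
lateral offset *a* from the point above the source centre:

    T(a) = T_e + Q / (4π h₀ [(d + R)² + a²])

where T_e is the ambient temperature, d the depth of the source top and R
its radius — a sphere at depth d is exactly a point source at *effective
depth* d + R. Given the peak temperature T_max, one local reading T(a) and
the ambient, the model inverts in closed form:

    d + R = a √[(T(a) − T_e) / (T_max − T(a))]
    Q     = 4π h₀ a² (T(a) − T_e)(T_max − T_e) / (T_max − T(a))
    R³    = (T(a) − T_e)(a² + (d+R)²) · 4π h₀ / (q_m · 10⁻⁶)

with q_m the metabolic heat generation of healthy tissue. The surrogate
stage trains a 3-input, 10-hidden-unit sigmoidal network on seeded forward
samples and refines an initial (Q, d, R) guess by bounded derivative-free
minimization of the surrogate-vs-observed profile mismatch.

## Worked example

Recover a source from a synthetic thermal image
(`python examples/invert_thermogram.py`):

```
noiseless:
  effective depth d+R =  14.000 mm (true 14.000 mm)
  intensity Q         = 100.000 mW (true 100.000 mW)
10% elevation noise:
  effective depth d+R =  15.231 mm (true 14.000 mm)
  intensity Q         = 108.721 mW (true 100.000 mW)
```

A noiseless 41×41 image of a 0.1 W source at 14 mm inverts to machine
precision; with 10% multiplicative noise on the temperature elevation the
same image still localizes the source to within ~9% in depth and
intensity. The other scripts in `examples/` walk through the forward
parameter sweeps, the sensitivity studies (e.g. the reference case's
28.2996 °C peak and 1.6597 °C span, and the 0.34/0.38/0.24 °C peak shifts
from 20% parameter errors), the neural-surrogate refinement, and the
three-temperature clinical workflow.

The same functionality is exposed on the command line:

```bash
thermoloc simulate --Q 0.1 --d 0.014 --R 0 --shape 41x41 --pitch 0.005 -o grid.csv
thermoloc invert -i grid.csv -o report.json
thermoloc estimate --Te 20 --Tmax 35.2 --Tskin 33.4 --depth-range 0.006,0.01
thermoloc sensitivity --base 0.045,0.0105,0.005 --param d --fraction 0.2
thermoloc surrogate-train --n 500 --seed 1 -o model.json
```

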