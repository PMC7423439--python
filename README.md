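# nestgrowth

Arboreal *Nasutitermes* termites build lightweight, intricately folded nests
whose galleries show a single characteristic length and an abundance of
saddle-shaped walls. The construction is stigmergic: where a termite deposits
next depends on the shape of what is already built, with local surface
curvature concentrating the building activity. `nestgrowth` implements a
minimal continuum model of that process and the measurement pipeline used to
compare simulated structures with micro-CT scans of real nests. It is aimed
at researchers in collective animal behaviour and pattern formation who want
a desk-scale, fully reproducible version of the model and its morphometrics.

## The model

The nest is a phase field `f(x, t) ∈ [0, 1]` on a cubic grid (material where
`f > 1/2`, empty where `f < 1/2`, wall surface at the iso-level) evolving
under a single non-dimensional equation with one parameter `d > 0`:

    ∂f/∂t = −f(1−f) · d · Δf − Δ²f

The anti-diffusive first term approximates curvature-driven accretion (Δf
stands in for the mean curvature `∇·n̂` of the local iso-surface), the kernel
`f(1−f)` confines growth to the interface, and the bi-Laplacian smooths away
small-scale detail. Linearizing about `f = 1/2` gives

    σ(k) = f̃ d k² − k⁴,   f̃ = 1/4,

unstable below `k₀ = √(f̃d)` with the fastest-growing wavelength
`λ_max = 2π/√(f̃d/2)`: walls spontaneously appear at a preferred spacing,
then branch and merge while invading the available space. The package
provides:

* `model` / `field` — the explicit-Euler integrator (Numba-compiled),
  periodic or fixed-value (Dirichlet) z-boundaries, white-noise and frozen
  nest-like seed initial conditions, snapshot + TIFF-stack I/O;
* `dispersion` — the closed-form linear-stability toolkit (k₀, k_max, λ_max,
  σ_max, marginal d, discrete-stencil growth rates used as the integrator's
  oracle);
* `morphometrics` — FFT dominant length, directional/radial autocorrelation,
  Lewiner marching-cubes iso-surfaces, per-vertex mean (H) and Gaussian (Γ)
  curvature, area-weighted (H, Γ) kernel densities with decile contours;
* `benchmarks` — gyroid, band-passed noise, and closed-form calibration
  volumes;
* `experiments` / `cli` — manifest-tracked end-to-end runs
  (`nestgrowth simulate | dispersion | analyze | benchmark | experiment ...`).

See `docs/methods.md` for the numerical and estimator choices.

## Worked example

```python
import numpy as np
from nestgrowth import (GrowthConfig, d_for_wavelength, dominant_scale,
                        init_white_noise, run, summarize, extract_isosurface,
                        curvatures, h_g_histograms)
from nestgrowth.morphometrics import autocorrelation

d = d_for_wavelength(12.0)          # drive chosen so lambda_max = 12 cells
s = summarize(d)
print(f"d = {d:.3f}  k_max = {s.k_max:.3f}  lambda_max = {s.lambda_max:.1f}  "
      f"sigma_max = {s.sigma_max:.4f}")

cfg = GrowthConfig(d=d, rng_seed=42)
field = init_white_noise((64, 64, 64), cfg)
final = run(field, cfg, t_end=30 * s.timescale).final

k_dom, l_dom = dominant_scale(final)
corr = autocorrelation(final, rescale_length=l_dom)
print(f"dominant length = {l_dom:.2f} cells  (linear theory: {s.lambda_max:.1f})")
print(f"first autocorrelation maximum at rescaled lag {corr.first_max_location:.2f}")

mesh = curvatures(extract_isosurface(final, 0.5, rescale_length=l_dom))
hist = h_g_histograms(mesh)
print(f"H mode = {hist.H_mode:+.2f}  Gamma<0 fraction = "
      f"{hist.Gamma_negative_fraction:.2f}  ({int(mesh.interior.sum())} vertices)")
```

Output (a couple of minutes on one core):

```
d = 2.193  k_max = 0.524  lambda_max = 12.0  sigma_max = 0.0752
dominant length = 13.14 cells  (linear theory: 12.0)
first autocorrelation maximum at rescaled lag 1.22
H mode = +0.00  Gamma<0 fraction = 0.94  (60017 vertices)
```

Read: starting from white noise, the pattern matures at a wall spacing within
~10% of the linear-analysis prediction; the direction-averaged
autocorrelation, with distances rescaled by the FFT length, peaks again near
lag 1 (the pattern is periodic at its own dominant scale); and the extracted
wall surface is saddle-dominated — mean curvature peaked at zero with 94% of
the surface area at negative Gaussian curvature, the geometric signature
this model shares with real nests.

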