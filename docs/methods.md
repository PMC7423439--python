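# Methods

## Model

The nest is represented by a phase field `f(x, t)` on a cubic grid, with
`f > f0` read as built material and `f < f0` as empty space; the wall surface
is the iso-surface `f = f0`. The field evolves under a single non-dimensional
equation,

    ∂f/∂t = −f^α (1−f)^β · d · Δf − Δ²f,

with one free parameter `d > 0`. The first term is the growth law: the mean
curvature of the local iso-surface, `∇·n̂` with `n̂ = ∇f/|∇f|`, is approximated
by `Δf` under the assumption that `|∇f|` is roughly constant across the
diffuse interface, so `d` is an *effective* drive coefficient that absorbs the
unknown proportionality. (The exact operator `∇·(∇f/|∇f|)`, with a 1e−12
floor on `|∇f|`, is available as a diagnostic — `model.curvature_divergence` —
but is never integrated: the production equation is the simplified one.) The
kernel `f^α(1−f)^β` vanishes at `f = 0, 1` and confines all dynamics to the
interface region: no deposition in empty space, no remodelling deep inside
walls. The bi-Laplacian is the stabilizing hyper-diffusion that cuts off the
instability at short wavelengths. Throughout, `α = β = 1`, which places the
kernel maximum and the wall surface at `f0 = 1/2`.

Linearizing about `f = f0` gives the dispersion relation

    σ(k) = f̃ d k² − k⁴,   f̃ = f0(1−f0) = 1/4,

with neutral wavenumber `k0 = √(f̃d)`, most unstable wavenumber
`k_max = √(f̃d/2) = k0/√2`, most unstable wavelength `λ_max = 2π/k_max`, and
peak growth rate `σ_max = σ(k_max) = f̃²d²/4`. Simulation time is reported in
units of `1/σ_max` ("timescales"); measured single-mode growth rates confirm
this is the rate consistent with the equation. An alternative convention
`f0²d²/4` — larger by `(f0/f̃)²`, i.e. exactly 4× at `f0 = 1/2` — circulates
for this model and is exposed separately as `sigma_max_f0sq` so the two are
never conflated. On a
periodic domain of size `L` the instability threshold is
`d_c = (2π/L)²/f̃`.

## Discretization and integration

Space: 7-point second-order central-difference Laplacian; the bi-Laplacian is
the same stencil applied twice (13-point biharmonic stencil in the interior),
so ghost handling is defined once. Boundary conditions are triply periodic,
or periodic in x, y with fixed-value (Dirichlet) planes at z-min/z-max; in
the Dirichlet case the field is clamped to the boundary constant on a
two-deep ghost halo (the depth the composed bi-Laplacian needs), which makes
the first Laplacian pass exactly zero on the halo.

Time: first-order explicit Euler. The step is chosen from a von Neumann bound
on the linearized operator: the largest stencil eigenvalues on a 3D grid are
`K₂ = 12/h²` for Δ and `K₄ = K₂²` for Δ², giving
`dt = S · 2/(f̃ d K₂ + K₄)` with safety factor `S = 0.25` to absorb the
nonlinear kernel exceeding its uniform-state value during transients.
Configurations with a larger `dt` are rejected at construction; the bound was
additionally validated empirically (5000-step white-noise runs remain finite,
and measured single-mode rates on a 64³ grid match the discrete dispersion
relation `f̃dk̃² − k̃⁴`, `k̃² = (2−2cos kh)/h²`, to better than 0.1%, far
inside the 5% acceptance band).

`f` is *not* clamped to [0, 1] by default: the kernel self-damps near 0 and 1
and matured runs overshoot only to about [−0.08, 1.07]; excursions beyond
[−0.05, 1.05] emit a log warning, and a config flag enables hard clamping.

Initial conditions are (a) i.i.d. uniform white noise `f0 ± a` with default
amplitude `a = 0.1` (the distribution and amplitude are a package choice — a
tenth of the full phase range is large enough to seed every mode, small
enough to stay linear for several e-foldings), or (b) a frozen seed: a
half-sphere resting on the floor (optionally with a roughened surface) or a
volume patch copied from a matured run, with `f = 1` inside, 0 outside, and
all nodes initially above the freeze threshold (default 0.9) excluded from
the update forever. Frozen nodes take precedence over Dirichlet planes they
touch, so a seed can rest on an `f = 0` floor. Grid resolution is chosen so
that `λ_max` spans at least ~12 cells, which resolves the whole unstable band
(`λ0 = λ_max/√2` is then ~8.5 cells).

## Morphometrics

All analyses accept either simulation snapshots or grayscale image stacks
(e.g. micro-CT scans) normalized to [0, 1]; non-periodic volumes must be
Hann-windowed for the spectral steps.

* **Dominant length** — mean-subtracted 3D FFT, `|F|²` averaged over
  spherical shells of width `2π/(Nh)` (N the smallest axis, DC excluded);
  the dominant wavenumber is the power-weighted centroid of `|k|` over the
  peak shell and its two neighbours, which is exact for a single grid mode
  and removes the half-shell quantization (±1 shell corresponds to ±20% in
  length at the 64³ study scale, which would otherwise dominate the
  estimate's seed-to-seed scatter).
* **Autocorrelation** — Wiener–Khinchin for periodic volumes, zero-padded
  convolution with overlap-count normalization otherwise; axis profiles plus
  a spherical-shell average over lag space, all lags divided by the dominant
  length. The first strict local maximum of the radial profile locates the
  pattern wavelength; an axis whose profile has no prominent local maximum
  near rescaled lag 1 (prominence ≥ 0.02 within lag 0.25–1.75) marks an
  anisotropic direction. Note the shell average of a *single* plane wave is
  `sinc(kr)`, whose first maximum is at `kr ≈ 7.725`, not one wavelength —
  only multi-directionally modulated fields peak near 1.
* **Iso-surface** — Lewiner marching cubes at `f = f0`, faces wound so
  normals point from material to empty space, followed by (default) 3 Taubin
  smoothing passes; vertices on the open cut faces of the domain are flagged
  as boundary and excluded from every statistic (rims of CT fragments are
  artifacts). Coordinates are divided by the dominant length so curvatures
  are comparable across objects.
* **Curvature** — per interior vertex, Gaussian curvature Γ as the angle
  deficit over the Meyer mixed (Voronoi-safe) area, and mean curvature H as
  half the projection of the cotangent-weighted mean-curvature normal onto
  the outward unit vertex normal (solid-body exteriors have H > 0; H = 0 is
  a minimal surface). The projection form is used rather than the signed
  norm: on marching-cubes meshes the norm acquires a Rayleigh-type upward
  bias from tangential discretization noise, which visibly shifts the H
  statistics of near-minimal surfaces, while the discarded tangential
  component carries no curvature information. The few Taubin passes remove
  the voxel-scale staircase that otherwise biases even the projected mean
  (gyroid area-weighted mean H: ~0.1 raw vs ~0.01 smoothed, in units of the
  inverse period); more aggressive smoothing starts to distort closed-form
  fixtures, and 3 passes keep the sphere's median H and Γ errors under 3%.
  Degenerate triangles (area < 1e−12) are dropped with a logged count. The
  angle-deficit total is an exact discrete Gauss–Bonnet invariant, so closed
  meshes satisfy `ΣΓ·A = 2πχ` to machine precision.
* **(H, Γ) density** — 2D Gaussian KDE (Scott's rule) over interior vertices
  weighted by mixed area (the per-vertex proxy for a per-surface-element
  sample; whether elements should instead be counted equally is not
  determinable, and area weighting is the convention least sensitive to mesh
  grading). Contour levels are weighted decile quantiles of the sample
  densities, so consecutive contours bracket 10% of the surface mass.
  Samples beyond 10⁴ vertices are down-sampled by a fixed-seed area-weighted
  draw (exact KDE evaluation is quadratic; 10⁴ points pin the decile levels
  to well under a contour width). Degenerate (delta-like) samples are
  regularized with 1e−9-scale jitter. 1D histograms of H and Γ are
  area-weighted with bins aligned so 0 is a bin center (default width 0.05
  in rescaled units); the reported H mode is the center of the heaviest bin.

## Benchmarks

* **Gyroid** `sin qx cos qy + sin qy cos qz + sin qz cos qx`, `q = 2π/λ`,
  mapped affinely to [0, 1] so level 0.5 is exactly the zero set — the
  minimal-surface anchor (mean H = 0, Γ < 0). Its spectral peak sits at
  `|k| = √2·q` (every constituent plane wave has that magnitude), i.e. at
  length `λ/√2`, not at the unit-cell period λ.
* **Band-passed noise** — seeded white noise filtered by a Gaussian annulus
  centered on `2π/ℓ_c` with relative width 0.25 (a package choice: wide
  enough to stay generic, narrow enough for a clean single scale), DC
  removed, remapped to [0, 1]. The "length scale without organization" null:
  its H distribution is systematically wider than the gyroid's.
* **Sphere / plane / cosine mode** — closed-form calibration fixtures. The
  solid-ball field falls linearly across a 4-cell shell at `r = R` so the
  extracted surface lies on the exact sphere rather than a voxel staircase.

## Synthetic study conditions

The matured-pattern object used by the tests and the acceptance script is a
triply periodic 64³ run from white noise (amplitude 0.1 about 0.5) with `d`
set so `λ_max = 12` cells, integrated for 30 timescales — long enough for
full saturation (amplitudes saturate after ~6–8 timescales) but well before
the very slow drift toward sheet-like anisotropy that develops over tens to
hundreds of timescales. These sizes keep a full suite run in minutes on one
core; the drivers accept the much larger domains (e.g. 256³) used for
high-resolution studies, which behave identically per unit volume but are
not exercised by tests. What the synthetic volumes do *not* emulate about
real CT scans: intensity noise and artifacts, anisotropic voxel spacing,
partial-volume effects at thin walls, and cut fragment rims (only the last
is handled explicitly, via boundary-vertex exclusion); passing tests
therefore validate the estimators and the model dynamics, not robustness to
scanner noise.

## Known limitations

* Explicit Euler with the stiff Δ² term forces `dt ∝ h⁴`; the step count to
  a fixed number of timescales scales as `(λ_max/h)⁴` and is independent of
  further grid refinement only through the safety factor. No implicit or
  spectral integrator is provided by design.
* The accretive-locality separation between front and bulk change rates is
  about one order of magnitude (front ≈ 7e−3, bulk ≈ 5–7e−4 per time unit at
  30–50-timescale pattern ages) — the bulk keeps rearranging slowly as the
  secondary (sheet-selecting) instability proceeds, so "frozen bulk" is an
  idealization valid only on scales of a few timescales.
* Periodic iso-surfaces are extracted as open meshes cut at the box faces;
  faces are not stitched across periodic boundaries, so Euler-characteristic
  (topology) checks are limited to closed fixtures like the sphere.
* Pointwise discrete curvatures on marching-cubes meshes remain noisy (IQR
  of H on the gyroid is ~0.9 in rescaled units even after smoothing);
  distribution-level statistics (means, medians, modes, deciles) are the
  reliable outputs, single-vertex values are not.
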