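# Methods

This note documents the models, parameter choices and numerical
decisions behind `cbctscatter`, and what the synthetic tests do and do
not demonstrate about real scanner data.

## Signal model

A detector pixel records primary plus scatter, `I_m = I_p + I_s`.
Scatter is modelled by kernel superposition: the primary image is
partitioned by object thickness into subprojections `I_{p,t}` and each
is convolved with a thickness-specific kernel,

    I_s = Σ_t  I_{p,t} ** K_t,        K_t = A_t · SF_t · PSF_t.

* `PSF_t` — unit-sum, radially symmetric spatial shape of the scatter a
  pencil beam produces behind `t` mm of PMMA. Symmetric kernels are
  adequate for compact, head-sized objects.
* `SF_t = a1·t + a2` — scatter fraction, linear in thickness with
  defaults `a1 = 0.0038 /mm`, `a2 = 0.1`. The linear fit crosses 1 near
  `t ≈ 237 mm`, which is unphysical; values are clamped at 0.99 with a
  warning so the MLEM denominator stays meaningful for thick rays.
* `A_t` — piecewise-constant compensating amplitude: 1.0 on (0, 40] and
  (40, 80], 1.75 on (80, 120] and (120, 160], 2.0 above 160 mm.
  Interval edges are upper-inclusive.

The kernel database holds PSFs at 1 mm thickness steps. Coarse kernels
(parametric, or loaded from HDF5 when computed externally, e.g. by
photon-transport simulation) are interpolated per-pixel to the 1 mm
grid and re-normalized; SF and A are always evaluated from their own
models, never interpolated.

### Parametric PSF family

Published slab-scatter kernels are available only as profile plots, so
the package generates its own two-component radial family: a narrow
Gaussian core plus a dominant broad exponential tail, with widths
affine in thickness (`σ(t) = 4 + 0.05·t` mm, `ρ(t) = 120 + 0.10·t` mm,
tail weight 0.95 by default; all exposed in `PSFShape`). The very broad
tail matters physically: scatter emission across the projection is
strongest under the *thin* rim of an object (high transmitted flux),
and only a kernel whose reach is comparable to the object's shadow
smears that emission into the slowly-varying haze that produces the
classic cupping artifact. Narrow kernels make the scatter track the
primary and produce a qualitatively different (dome-like) artifact.
Any parametric family is an approximation of simulated kernels, not a
claim about a specific measured set — externally computed kernels can
be loaded instead.

Component-wise normalization on the grid means a kernel's mass is
exactly `A_t·SF_t` regardless of truncation; what truncation changes is
the *shape* available inside the grid. Kernel grids should be chosen so
the tail has room (the test fixtures use 201×201 pixels at 1.2 mm
pitch, ±120 mm).

## Thickness mapping and grouping

PMMA-equivalent thickness comes from monoenergetic Beer's law,
`t = log(I0/Ip)/μ_PMMA`, or from a monotone log-signal lookup table
built from calibration slabs. `μ_PMMA` defaults to 0.022 /mm (PMMA at
an effective energy of roughly 60 keV); because the simulator uses the
same effective-energy attenuation table, a simulated slab maps back to
its own thickness, which is the package's self-consistent calibration.
Intensities below `1e-6·I0` are clipped before the log; pixels at or
above the flat field map to 0 mm.

Pixels are partitioned into five 40 mm groups by default, the last
group open-ended, with upper-inclusive edges. Each group is represented
by the kernel at its center thickness (20/60/100/140/180 mm): the
grouped convolution needs one representative `t` per bin and
center-of-bin is the least biased simple choice.

**Minimum scattering thickness.** Pixels with less than 10 mm of
apparent material are treated as non-scattering, identically in the
simulator and the correction. Physically, a ray through (almost) no
material contributes negligible scatter. Numerically the floor is
load-bearing: if the scatter operator switched on at exactly `t = 0`,
the iteration would admit a spurious self-consistent solution in which
near-flat-field pixels drift below `I0`, acquire a tiny apparent
thickness, and generate precisely the scatter that sustains their own
depression. Sustaining such a halo requires an apparent thickness of
about `log(1 + A·SF)/μ ≈ 7 mm` for the first group's kernel mass, so a
10 mm floor removes the solution while leaving real object pixels
untouched.

## MLEM deconvolution

With Poisson counting statistics the primary estimate is updated
multiplicatively,

    I_p^{n+1} = I_p^n · I_m / ( I_p^n + Σ_t I_{p,t}^n ** K_t ),

starting from `I_p^0 = I_m` (the standard choice; it also keeps the
first thickness map well-defined). The thickness map and partition are
re-derived from the current iterate every iteration. Convolutions are
zero-padded frequency-domain products at full detector resolution.
The update is evaluated as `estimate · (measured / denominator)`, which
makes the zero-scatter case (`K ≡ 0`) return the measurement
bit-exactly in one iteration.

Convergence is monitored through the Poisson log-likelihood with
estimate-independent terms dropped, evaluated at the model's predicted
measurement mean `λ = I_p^n + Σ I_{p,t}^n ** K_t`:

    L(n) = Σ_{x,y}  I_m·log λ − λ.

`λ`, not the bare primary, is the mean the data are Poisson-distributed
around; evaluated at the primary alone the monitor would be maximized
by the uncorrected measurement itself and could only fall. Iteration
stops at 5 iterations (empirically sufficient; more risks
overcorrection) or when the relative change of L drops below 1e-4,
whichever comes first — both configurable. Because the kernel term
depends on the current iterate, monotone ascent of L is not a theorem
here (the update is not exactly Richardson-Lucy, and pixels can flip
thickness groups between iterations); it is a monitored property that
holds on the matched-model fixtures, with occasional group-flip dips
on the order of 1e-8 relative well past convergence. Views are
corrected independently; no state is shared between them.

## Synthetic data and the inverse-crime design

The simulator provides ground truth for every stage:

* **Phantom** — a voxelized cylinder (160 mm diameter by default,
  soft-tissue background 0.0210 /mm) with optional rod inserts of bone
  (0.0573), air (0), water (0.0206) or small low-contrast offsets,
  mirroring a cylindrical QA phantom's CT-number and low-contrast
  sections. A slab phantom supports thickness-calibration tests.
* **Projector** — monoenergetic Beer's law with exact radiological
  paths (incremental Siddon/Amanatides-Woo voxel traversal, numba-
  compiled). A dense-sampling integrator serves as an independent
  oracle in the tests. The polychromatic spectrum of a real scanner is
  reduced to one effective energy; beam hardening is out of scope.
* **Scatter** — generated by the same grouped-kernel forward model the
  correction assumes. This inverse crime is deliberate and stated
  openly: it makes the true primary an exact fixed point, so recovery
  error measures the *algorithm* (convergence, grouping, convolution
  handling), not model mismatch. Passing these tests therefore shows
  the deconvolution machinery is correct; it does not show the kernel
  model matches any physical scanner — that is what externally
  measured kernels and real acquisitions would be for.
* **Noise** — Poisson noise on measured counts is available behind a
  seeded switch and off by default, so deterministic fixtures stay
  bit-reproducible.

Geometry defaults: DSO 500 mm, DSD 786 mm (the magnifying assignment of
the reference scanner's printed distances, which are stated in the
physically impossible order), 0.388 mm detector pitch at full scale. The
test fixtures downscale to a 1.2 mm pitch, 256×256-pixel detector and
180 views so that the 160 mm phantom fits the field of view and the
full recovery study runs in about a minute on one CPU; all problem
sizes are stated in the tests themselves.

## Reconstruction

Projections are log-converted (`p = log(I0/I)`, floored at `1e-12·I0`;
negative line integrals are kept — with scatter, intensities above the
flat field are legitimate data). The central slice is reconstructed by
flat-detector fan-beam FBP on the virtual detector through the
isocenter:

    f(x,y) = (π/N) Σ_β (DSO/L)² · Q_β(u),

with cosine-weighted rows ramp-filtered in the frequency domain (DFT of
the band-limited spatial ramp kernel — keeping its small positive DC
term, which is what makes reconstructed values quantitatively accurate)
and the double coverage of a full 2π scan folded into the constant. A
uniform cylinder reconstructs to its true attenuation within a fraction
of a percent. Shepp-Logan (sinc) and Hamming windows truncate at
`cutoff × Nyquist`; the cutoff convention (fraction of Nyquist) is this
package's documented choice. An FDK variant with the standard
`DSO/√(DSO²+u²+v²)` row weighting reconstructs full volumes and is
exercised on small grids; short-scan weighting is not implemented
(full rotations only).

## Evaluation metrics

CT numbers are calibrated as `CT# = 1000·(m_x − m_ref)/m_ref` against a
water-surrogate reference mean — in practice the soft-tissue background
of a low-scatter reference reconstruction, standing in for water when
the spectrum cannot separate the two. Contrast is the signed ROI mean
difference; CNR divides by the root-sum-square of the two ROI standard
deviations. Percent cupping averages four peripheral circular ROIs in
the uniform region (placed at 60% of the cylinder radius in the
fixtures) and compares with the central ROI:

    % cupping = (CT#_edge − CT#_center) · 100 / (CT#_edge + 1000).

ROI shapes, radii and positions are configurable throughout; published
phantom studies rarely state them exactly, so defaults are documented
rather than claimed.

## Known limitations

* Monoenergetic model: no beam hardening, so the residual ~10% cupping
  a real low-scatter reference scan exhibits is absent here.
* The parametric PSF family approximates the qualitative shape of
  simulated slab kernels; absolute scatter magnitudes on a physical
  scanner require measured or Monte-Carlo kernels (loadable via HDF5).
* Detector lag/glare, gain/offset calibration, motion, and anatomical
  phantom geometries are out of scope.
* Likelihood ascent and residual-decrease are empirical properties of
  the matched-model setting, not theorems.
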