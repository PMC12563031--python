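# Methods

This note documents the models implemented in scaffoldkit, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying physics or
conventions left genuine latitude.

## Contact mechanics

### Hertz model with bottom-effect correction

The elastic force–indentation relation for a rigid sphere (radius `R`) on a
layer of thickness `h` bonded to a rigid support is

    F(δ) = 4√R / (3(1−ν²)) · f_BEC(δ) · E · δ^{3/2}

Soft hydrated scaffolds are treated as incompressible (ν = 0.5,
time-independent). The bottom-effect correction `f_BEC` is the standard
fourth-order polynomial in χ = √(Rδ)/h for an incompressible layer:

| variant              | a₁    | a₂    | a₃    | a₄     |
|----------------------|-------|-------|-------|--------|
| bonded (default)     | 1.133 | 1.283 | 0.769 | 0.0975 |
| free (not adhered)   | 0.884 | 0.781 | 0.386 | 0.0048 |

`f_BEC → 1` as `h → ∞` or `δ → 0`; it grows monotonically as the layer
thins. The correction matters whenever the indentation depth is comparable
to the sample thickness (χ ≈ 0.39 and f_BEC ≈ 1.68 for R = 500 µm,
δ = 300 µm, h = 1 mm).

### Lee–Radok hereditary integral

For a monotonically loading depth history δ(t) the viscoelastic force is

    F(t) = 4√R/(3(1−ν²)) ∫₀ᵗ f_BEC(δ(ξ)) · E(t−ξ) · d(δ^{3/2})/dξ dξ

with the SLS relaxation modulus E(t) = E∞ + (E0−E∞)e^{−t/τ}. Two details
are genuinely open and are handled as follows:

* **Placement of f_BEC.** As written above, the correction multiplies the
  depth-rate term at the instantaneous depth. In the elastic degenerate
  case (E0 = E∞) this reduces to the corrected Hertz force only when f_BEC
  is constant (semi-infinite sample); for a finite-thickness layer the two
  differ because ∫f_BEC du ≠ f_BEC·u. The default follows the form above;
  `bec_with_derivative=True` instead integrates d[f_BEC·δ^{3/2}]/dξ, which
  restores exact elastic-limit consistency on thin layers. The two forms
  coincide for semi-infinite samples and differ by ≲2 % at χ ≈ 0.4.
* **Discretization.** Per time interval the corrected δ^{3/2}-rate is taken
  piecewise constant (its exact interval average) and the exponential
  kernel is integrated exactly, giving an O(n) recursion (an IIR filter on
  uniform grids, evaluated by `scipy.signal.lfilter`; a stable scalar
  recursion otherwise). The scheme is exact for elastic materials, free of
  overflow for any τ, and second-order accurate; agreement with a 10×-finer
  brute-force quadrature is ≈3×10⁻⁴ relative at 50 Hz sampling.
* **Step protocols** are represented as a one-sample ramp; the relaxation
  response converges to δ₀^{3/2}·E(t) as the sampling interval shrinks.

## Curve fitting

* **Contact detection**: baseline and noise SD from the first 2 % of the
  recording (assumed pre-contact); contact = first crossing of baseline +
  threshold (default 5× noise SD), walked back to the last baseline
  crossing. If the initial window itself rises beyond the threshold the
  recording is taken to start at contact. Time, depth and force are
  re-zeroed at contact.
* **Segmentation**: hold = samples within 0.5 % of maximal depth whose mean
  depth rate is well below the ramp rate (so a pure monotone ramp yields no
  hold even though its last samples are near-maximal).
* **Elastic fit**: F = E·g(δ) is linear in E, so the least-squares optimum
  is closed-form. Minimum 10 loading samples.
* **SLS fit**: bounded trust-region least squares on x = (E∞, ΔE, τ) with
  ΔE = E0 − E∞ ≥ 0, which enforces E0 ≥ E∞ > 0 structurally.
  Initialization: E0 from an elastic fit to the first 20 % of loading, E∞
  from the final hold force through the Hertz inverse, τ from the time to
  half relaxation. Tolerances are set to 10⁻¹² so noiseless synthetic
  curves recover truth to ≲10⁻⁵ relative rather than stalling at the
  optimizer's default cost plateau. The fit window is loading + hold
  jointly by default (`loading`/`hold` windows available). Diagnostics flag
  τ as unidentifiable when the fitted relaxation amplitude ΔE/E0 < 1 %, and
  warn when the hold is shorter than 2τ. The fit is fully deterministic.

## Micro-CT porosity

* **Threshold**: Riddler–Calvard/ISODATA on the integer intensity lattice —
  start at the rounded global mean, iterate T ← round((mean below + mean
  above)/2) with ties rounding half up, stop when the threshold repeats.
  This matches an exhaustive fixed-point search over all integer thresholds
  (verified on random 8-bit volumes); a constant volume raises a degenerate-
  histogram error. Solid = intensity ≥ T (the attenuating phase is bright).
* **Despeckle**: removes 26-connected foreground components below a minimum
  voxel count (default 8 in the pipeline); small non-solid specks inside
  struts are filled symmetrically.
* **Shrink-wrap ROI**: complement of the background flood-filled from the
  volume border (6-connectivity for the background so the wrap cannot leak
  through voxel corners). External air is excluded; internal cavities and
  pores are retained. Stretch/convex-hull wrap variants are not offered.
* **Reports**: porosity % = 100·pore/ROI voxels, volumes in mm³ via the
  voxel size cubed, per-pore volumes from 26-connected labeling, and all
  quantities normalized to a 1 mm³ reference ROI so differently sized scans
  are comparable. Doubling the voxel size multiplies volumes by 8 and
  leaves porosity unchanged.

## Angiogenesis and histomorphometry

All metrics are deterministic ratio/mean arithmetic on counted inputs:
vascular index = count₇₂ₕ/count₀ₕ ("fold difference" is read as a ratio,
consistent with expressing baselines as 100 %); length/area fold changes as
percent of baseline; perfusion change = 100·(v₇₂ₕ−v₀ₕ)/v₀ₕ; vessel density
= mean over ten fields of count/area; lamina thickness = mean of five
probes 400 µm apart; relative membrane area = 100·red area/field area.
Zero baselines are rejected. Vessel segmentation/counting itself is out of
scope — the package consumes counted tables. Group comparisons invoke
standard routines (Kruskal–Wallis with Holm-adjusted pairwise Mann–Whitney
post hocs, or one-way ANOVA with Welch pairwise tests); the field-of-view
area at a given magnification is instrument-specific and must be supplied
by the user.

## Synthetic-data generators

* **Indentation curves**: exact Lee–Radok forward model plus multiplicative
  Gaussian force noise (instrument-like, default protocol 30 µm/s to
  300 µm, 30 s hold, 100 Hz) with optional pre-contact approach travel and
  an additive noise floor. They do **not** emulate drift, adhesion,
  cantilever ringing, or depth-channel noise — recovery results bound what
  the fitter can do under the stated noise model only.
* **Porous volumes**: overlapping spherical pores (radii uniform in 4–12
  voxels ≈ 48–144 µm diameter at 6 µm voxels, the lower end of the 50–500
  µm pore-size range so 128³ test volumes hold many pores) carved from a
  solid block until the block's void fraction is within ±0.5 percentage
  points of target. Pore centres keep clearance from the block surface so
  the pore network stays enclosed by a solid shell — otherwise an open pore
  network would be flood-filled away as exterior background by any tight
  shrink-wrap, which is a physical property of real open-cell scaffolds
  that this generator deliberately does not reproduce. Grayscale rendering
  is two intensity classes (60/180) with additive Gaussian noise (SD 15).
  Real micro-CT texture (partial-volume effects, beam hardening, ring
  artifacts) is not modelled, so the ±1-percentage-point recovery shown on
  these volumes is a best case.
* **CAM tables**: per-group log-normal fold changes (mean calibrated to the
  group effect, log-SD "dispersion" = 0.25) applied to Poisson baseline
  counts and log-normal lengths/areas; default design 9/7/6/6 embryos
  (control + three scaffold groups) with mean fold changes 2.0/1.3/1.7/1.9
  — a control CAM roughly doubles its vessel count over 72 h while dense or
  slowly degrading scaffolds blunt the response.

All generators are seed-deterministic and return their ground truth beside
the data.

## Problem sizes and validation scope

The validation suite uses a 3×3×3 truth grid spanning 1–200 kPa and
0.5–20 s (noiseless recovery < 0.5 % relative), 20-seed Monte Carlo at 1–2 %
noise (median recovery error ≪ 5 %, R² > 0.97), 100 random volumes ≤ 32³
for threshold exactness, and 5 seeds × 128³ voxels at void fractions
0.332/0.643/0.785 for porosity recovery. These sizes give stable statistics
at interactive runtimes; the algorithms themselves are O(n) (curve fitting)
or O(voxels) (volume pipeline) and scale to full-size scans.

## Known limitations

* The BEC polynomial is a published approximation valid for χ ≲ 1; very
  thin samples or very deep indentation leave its fitted range.
* Single-exponential SLS only: power-law or multi-term Prony kernels,
  adhesion (JKR/DMT) and non-spherical tips are out of scope.
* The Lee–Radok form assumes monotone (non-retracting) loading; unloading
  segments are not modelled.
* Porosity accuracy on real scans depends on acquisition artifacts the
  synthetic volumes do not contain; the threshold/ROI pipeline is exact
  only with respect to its own segmentation rule.
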