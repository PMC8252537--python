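# Methods

This note documents the measurement models implemented in `sysphantom`, the
assumptions behind the digital-reference-object (DRO) simulator, the
numerical choices that affect results, and the limits of what the test suite
demonstrates.

## Phantom geometry model

The layout is a queryable, serializable model in phantom coordinates
(+Z superior, +X left, +Y down; origin at the central fiducial sphere; mm).

* **Fiducial array** — 57 spheres of 10.0 mm inner diameter on a 40 mm cubic
  lattice: the central 3×3×3 block (27 spheres) plus 5 spheres at each of
  the six outward faces. The published description does not enumerate the 5
  face positions; we use the face center (±80 mm on one axis) plus the four
  40 mm-adjacent lattice points (a cross), which keeps every center strictly
  inside the 200 mm shell and every nearest-neighbor distance at exactly
  40 mm. Numbering sorts by (z, y, x) ascending — plate 1 (most inferior)
  first, then right to left — which places the central sphere at index 29.
* **Parameter arrays** — 14 spheres of 15 mm inner diameter per array: 10
  equally spaced (36°) on a 50 mm-radius ring plus 4 interior spheres on a
  40 mm grid, in a coronal plane. The plane offsets (NiCl₂ at y = −60 mm,
  MnCl₂ at −20 mm, PD at +20 mm) are a layout choice on the plate grid that
  avoids collisions with fiducial planes; only in-plane geometry enters any
  analysis, and the JSON layout can be replaced with coordinates from the
  published 3D model files if exact plate offsets matter.
* **Resolution insets** — five hole sizes (fine: 0.4–0.8 mm, coarse:
  0.6–1.0 mm), each a 4×4 block with center-to-center pitch = 2 × diameter
  (the ACR convention) plus a copy rotated 10° about a shared corner hole.
  The rotated copy extends into the opposite quadrant from the shared
  corner, so the two arrays touch only at that hole; 31 distinct holes per
  size, 155 per inset.
* **Wedges** — two opposed 10° wedges of 10 mm height, analyzed through
  4 mm × 50 mm rectangles.

## DRO simulator

Signal models per region (PD fraction, T1, T2 in ms):

* IR (magnitude): S(TI) = |A(1 − (1+δ)e^(−TI/T1))|, A ∝ PD. The inversion
  efficiency defaults to δ = 0.85, a typical scanner value (ideal 1.0).
  The ideal-TR model is rendered; finite-TR saturation is not.
* Spoiled GRE / VFA: S = S₉₀ sin α (1−E₁)/(1−E₁ cos α) · e^(−TE/T2),
  E₁ = e^(−TR/T1).
* SE: S = S₀ e^(−TE/T2) · (1 − e^(−TR/T1)).

Rendering paints each sphere into the voxel grid with anti-aliased partial
volume (3× supersampling per axis, box-averaged; total painted volume within
1 % of (4/3)πr³ at 1 mm voxels). Sphere centers are displaced by a
distortion field — a similarity part (rotation, translation, isotropic
scale) plus a low-order 3D polynomial displacement in r/100 mm — then the
image is multiplied by a smooth polynomial receive-bias field, and Rician
noise (Gaussian on two quadrature channels, then magnitude) is applied last;
a pure-Gaussian option is kept for statistical oracle tests. Output is
byte-deterministic given configuration and seed.

The background fill renders as long-T1 water (T1 = 3000 ms, T2 = 1800 ms,
PD = 1), mimicking deionized-water contrast; the level is configurable since
protocols do not pin it down.

What the simulator deliberately omits: Gibbs ringing (except in the
resolution module's analytic finite-k-space synthesis), B0/B1 field maps and
flip-angle errors, eddy currents, chemical shift, slice-to-slice excitation
imperfections, drift between repeats, and plastic shells around the liquid
spheres. Passing tests therefore demonstrate correctness of the estimators
under the stated models and noise — not robustness to every scanner
artifact; on real data the known extra effects (imperfect flip angles for
VFA, CPMG-vs-SE differences for T2, ringing near sphere walls) dominate the
error budget.

### Reference table

The bundled reference relaxation table is **synthetic** (see
`data/reference_synthetic_3T.json`): √2 geometric progressions anchored to
the one published archival value pair (Ni-12: T1 = 44.53 ms,
T2 = 31.86 ms at 3 T, 20 °C), spanning ~20–2000 ms as the concentration
series intends. It mirrors the *structure* of the NIST calibration tables
and must be replaced with the certificate values of a physical phantom for
real QA work. Concentrations are back-computed from the same relaxivity
lines used in the relaxivity fits (NiCl₂ r₁ = 0.64 mM⁻¹s⁻¹,
MnCl₂ r₂ = 71 mM⁻¹s⁻¹, water rates 0.33/0.55 s⁻¹).

## Fiducial analysis

Localization correlates each search window (± half the 40 mm lattice
spacing, preventing neighbor capture) with a noiseless rendered sphere
kernel (zero-mean). The integer peak is refined by a 3D quadratic fit to the
3×3×3 neighborhood, then polished by maximizing the normalized correlation
against kernels rendered at continuous sub-voxel positions (Nelder-Mead,
10⁻⁴ mm tolerance; refinements that wander more than one voxel are
rejected). On simulated 10 mm spheres at 1 mm voxels and SNR 50 the mean 3D
center error is ~0.001–0.02 mm, comfortably below the 0.1 mm construction
accuracy of the physical phantom.

Defect (bubble) rejection is numeric: flag when the correlation peak is
below 0.6 × the median peak, when the integrated intensity deviates more
than 40 % from the group median, or when the peak lies on the search-window
edge; thresholds are configurable. The similarity fit is the closed-form
weighted Procrustes/Umeyama solution (SVD, reflections disallowed);
"generalized" iterative re-fitting happens only when residual-based
re-flagging changes the point set (residual > 5 × median and > 1 mm).

Uniformity normalizes integrated 10 mm-ROI intensities to the **maximum**
unflagged sphere (the reference sphere choice is not specified in the
standard description; max makes the top value exactly 1). Local volume
distortion is the clipped fractional intensity support of a sphere relative
to its nominal volume; ×1.1 local scaling reads ≈ 1.33.

## Relaxometry

All fits are nonlinear least squares (`scipy.optimize.curve_fit`) with
standard errors from the Jacobian-based covariance.

* **IR**: the absolute-value model is fitted directly — no polarity
  restoration — because magnitude images are the common denominator across
  scanners. The objective is non-smooth near the signal null, so the
  optimizer restarts from 8 log-spaced T1 seeds and keeps the best SSE.
  δ is bounded to [0, 1.2]. `voxel_map` mode fits every ROI voxel and
  averages the T1 map (stderr = SD/√n of the voxel estimates); it agrees
  with the ROI-mean fit within combined standard errors on simulated data.
  Spheres with T1 below the shortest TI are still fitted but carry visibly
  enlarged standard errors — by design, not failure.
* **VFA**: initialized from the DESPOT1 linearization (S/sin α vs S/tan α);
  warns when all flips sit on one side of the Ernst angle.
* **SE**: optional exclusions, recorded per point with reasons: echoes below
  a noise floor (default floor: background mean + 2 SD; the multiplier is a
  declared choice, as the published analysis does not define its floor
  line), and an optional first-echo drop (stimulated-echo/B1 artifacts).
  Floor exclusion demonstrably reduces Rician bias in paired simulations.
* **Coverage convention**: interval checks in the test suite use Student-t
  critical values at the fit's residual degrees of freedom (the covariance
  is residual-scaled, so z-based intervals undercover for 10-point fits).
* **Relaxivity**: R(C) = r·C + R_water with the intercept fixed to the
  measured water rate by default (free-intercept option available); rates in
  s⁻¹ are 1000/T(ms).

## PD and SNR

The four local-background samples sit at ±x and ±z (in-plate directions)
3 mm outside the sphere wall, as 3-voxel-radius spherical samples; their
size/direction is a declared choice. A sample deviating > 50 % from the
median of the four is re-sampled at 45°-rotated offsets and the sphere
flagged. Under a smooth ×6 edge-to-center bias the recovered PD is linear in
prescribed PD (slope 1 ± 0.02) with sub-percentage-point errors on noiseless
renders. The difference-method SNR assumes drift-free replicates; a large
background-ROI method is intentionally not primary (more drift-sensitive).

## Resolution

The analytic synthesis evaluates each hole's disk spectrum
(πR²·2J₁(kR)/(kR), phase-shifted to its center) on the acquisition's
Nyquist k-space cell, multiplies by the Gaussian PSF transform
(width 2σ; unit DC, so the image integral is exactly the total hole area),
and inverse-FFTs. PSF estimation is a 1D grid search (0.005 mm steps, 0 to
0.3 mm) over the width minimizing the L2 difference after least-squares
amplitude+offset matching; the residual curve and any boundary-minimum
warning are reported. Reported resolution stays separated into the
sampling-limited part (voxel size) and the Gaussian broadening.

The automated ACR-style rule reads *displayed pixels* (nearest-pixel
lookup): a size group is resolved when, in every row and column of both the
0° and 10° blocks, each hole-center pixel exceeds the adjacent
midpoint pixels by a contrast margin. The margin defaults to 25 % of the
block's local dynamic range, calibrated so the automated call reproduces the
published visual assessment on its published instance (fine inset at
0.35 mm voxels → 0.5 mm resolved, 0.4 mm not); it is configurable, and the
call is inherently threshold-sensitive for groups near the sampling limit.

Note that the finite-k-space synthesis intentionally contains truncation
(Gibbs) ringing; a box-average rasterization of the same disks does not, so
the two renderings differ by ~15 % in L2 in the near-Nyquist band while
agreeing to < 2 % once both are smoothed past it. This is a property of the
two definitions, not an implementation error.

## Slice profile

The ERF is the ROI column average; its derivative (central differences,
optional odd-width boxcar smoothing — reported, because smoothing biases the
FWHM) is the projected slice profile. FWHM uses linear interpolation at the
half-maximum crossings. With projected widths w₁, w₂ of the two wedges, the
slice-plane tilt is θ = ½·asin[(w₂−w₁)·sin 20°/(w₂+w₁)] (verified against
exact wedge-projection geometry to < 0.01° for |θ| ≤ 3°), and:

* NEMA method: t = mean of wᵢ·tan(10° ± θ) — exact for boxcar profiles at
  any tilt in range.
* Automated method: continuous flat–ramp–flat least-squares fit of each ERF
  (coarse breakpoint grid + Nelder-Mead refinement; levels solved linearly),
  then t = ½(w₁+w₂)·tan 10° with an uncertainty propagated from the fit
  residual. Averaging the two orientations cancels the O(θ) error; the
  residual error is sin²θ/(sin²10° − sin²θ) ≈ 1 % at θ = 1°, growing
  slightly faster than θ² (the 2°:1° error ratio is 4.12, not 4.00, because
  of the quartic term).

Thicknesses implying t > 10 mm (the wedge height) are rejected as outside
the measurable range. The simulated wedge image is rendered directly in the
slice frame — effective angles 10° ± θ — with boxcar or Gaussian
slice-sensitivity profiles; real profiles are sequence-dependent, which is
why the profile shape is selectable.

## Problem sizes and determinism

Simulation-based checks are sized for interactive runs: whole-phantom
distortion renders use a 220³ grid at 1 mm; localization studies use ~24
spheres; statistical checks use 100–200 repetitions with fixed seeds. All
randomness flows through `numpy.random.default_rng` seeded explicitly;
identical configuration + seed reproduces images byte-for-byte and reports
byte-for-byte (timestamps excluded).

## Known limitations

* The IR renderer uses the ideal TR ≫ T1 model, so finite-TR bias in real
  protocols is not emulated.
* VFA accuracy on real scanners is limited by flip-angle (B1) errors, which
  are out of scope here (no B1 mapping).
* The T2 module fits single-echo SE series; CPMG echo-train effects are not
  modeled.
* The ACR resolvability margin is a calibrated surrogate for a human visual
  rule; calls for groups within ~10 % of the sampling limit should be
  reviewed visually.
* DICOM support targets classic single-frame MR files written by this
  package (16-bit magnitude with rescale); enhanced multi-frame DICOM and
  PACS networking are out of scope.
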