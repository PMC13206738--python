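# Methods

## Scope and shape of the model

The package measures 2-D photographs of bisected eyes and simulates 2-D
phantoms to validate those measurements.  The simulated domain is therefore
a disc — the coronal cross-section a bisection exposes — not a 3-D globe.
No radial symmetry is assumed: the grid is Cartesian with a masked disc, so
occluders and off-center boluses are handled naturally.

Transport is isotropic Fickian diffusion, `∂C/∂t = D ∇²C`, with no-flux
(reflecting) boundaries at the eye wall and at occluder edges.  This is the
minimal physics consistent with a size-dependent barrier narrative:
convection (agitation, aqueous flow), dye degradation, clearance and
binding are deliberately excluded.

## Diffusivity model

    D_eff = k_B T / (6 π η r_s) · exp(−(r_s/ξ)²)

- `r_s` — Stokes radius of the tracer (nm).  Catalog: 2 MDa 27 nm,
  500 kDa 14.7 nm, 70 kDa 5.8 nm, 40 kDa 4.5 nm.  The 3 kDa radius is not
  tabulated; it is extrapolated to 1.3 nm (it must fall well below 4.5 nm)
  and flagged `extrapolated` in the catalog.
- `T` — absolute temperature.  Ex-vivo presets use 277.15 K (incubation at
  4 °C), in-vivo 310.15 K.
- `η` — effective medium viscosity, default 2.0 mPa·s.  No measured
  vitreous viscosity is available for these models; a single tunable
  effective value is exposed rather than hidden.
- `ξ` — gel mesh size entering the Ogston-type hindrance factor
  `exp(−(r_s/ξ)²)`.  `SimulationConfig` defaults to the literature bovine
  estimate of 550 nm.  At that value the hindrance is negligible for every
  tracer in the panel (even 27/550 gives a 0.2% reduction), while
  intact-globe distribution data argue the pig/human mesh is much smaller;
  the scenario presets therefore use an effective 20 nm, at which the
  factor is meaningfully size-selective (40 kDa ≈ 0.95, 2 MDa ≈ 0.16).
  The plasmin preset multiplies ξ by 3 (partial enzymatic loosening); this
  raises the 2 MDa diffusivity fivefold in relative terms but leaves it an
  order of magnitude below the 40 kDa value, so the large tracer stays
  effectively pinned — the qualitative plasmin observation.  The
  multiplier is a scenario knob, not a fitted dose–response model.

Diffusivities are converted to mm²/h.  Typical values at 4 °C, η = 2 mPa·s,
ξ = 20 nm: 3 kDa 0.28, 40 kDa 0.077, 70 kDa 0.058, 500 kDa 0.0145,
2 MDa 0.0022 mm²/h.

## Injection geometry

The limbus analog is the superior pole of the disc.  The needle entry point
lies on the disc boundary at an arc length `injection_offset` (default
4 mm; 3.5 mm for the miniature-pig preset) from that pole, on the nasal
(image left) or temporal (image right) side.  The bolus center sits on the
entry-to-center segment at fraction `needle_depth` of the way to the center
(default 0.25 — "advanced toward the center" without a stated depth; a
value of 1.0 places the bolus at the center, used by the calibration
series).  The bolus is an isotropic Gaussian of width σ₀ = 1.0 mm,
truncated to the domain and renormalized to the injected mass.  σ₀ is
deliberately smaller than the ~2.3 mm radius of a 50-µL sphere so the
rendered time-0 spot is compact.

## Numerics

- Explicit FTCS stepping in flux form: fluxes are exchanged only across
  cell faces interior to the domain, which realizes the no-flux boundary
  and conserves mass to floating-point roundoff (assertions use 10⁻⁶
  relative).  Stability: dt = 0.9·dx²/(4D), shrunk so output times are hit
  exactly.
- Grid spacing 0.1 mm by default (≥ 200 cells across an adult eye);
  structural tests use coarser grids (0.15–0.35 mm) to stay fast, which
  changes nothing but resolution.
- Verified against the free-space Gaussian solution: with the boundary
  ≥ 5σ away, σ²(t) = σ₀² + 2Dt is recovered from second moments within 2%
  and the cell-wise profile matches within 2% over the region holding 99%
  of the mass.

## Rendering

`green = clip(background + gain·C + vignette + noise, 0, 255)`, red/blue
carry half the background plus noise.  Noise is Gaussian and seeded;
identical configurations render identical bytes.  The default gain is set
so that at day-scale observation times the brightest cell stays inside the
8-bit range (exposure chosen to avoid clipping, as in practice); the
compact time-0 bolus may saturate, which the measurement chain never sees.

## Measurement conventions

- Threshold comparison is `>= τ` (the stated sweep levels are inclusive);
  rounding during normalization is half-away-from-zero.  Both choices are
  stated because half-cases move segmentation masks.
- Components are 8-connected; region-boundary pixels are detected with
  4-connectivity.  When no seed point is given the largest component is
  kept (ties: centroid closest to the first boundary-polygon vertex, then
  lowest row-major index); the excluded-signal fraction is always reported
  so the policy is auditable.
- Coordinates are 0-based pixel centers; distances are between pixel
  centers.  The Feret radius is computed on the convex hull, which equals
  the all-pairs maximum (asserted against an O(n²) oracle).
- Radii are not capped at the eye radius.
- The eye-area denominator defaults to the circle approximation from the
  averaged orthogonal diameters; the polygon-mask area is available by
  flag.  A constant image normalizes to all zeros (no signal), not 255.
- The min/max for normalization are taken over the whole image by default,
  with an option to restrict range estimation to the eye interior.
  Background subtraction acts on the green (analysis) channel; the mean of
  the background region is the default statistic, median by flag.

## Diffusivity self-calibration

`vitreoquant.calibrate.recover_diffusivity` closes the loop: a centered
bolus is simulated, rendered at 6 time points (4–40 h), measured, and D is
re-fit from the radius growth.  For a Gaussian spot normalized so its peak
maps to 255, the threshold-τ contour obeys
`r² = 2 ln(255/τ)(σ₀² + 2Dt)`, so a least-squares line through (t, r²) has
slope `4 ln(255/τ) D`.  Each frame is exposed individually
(gain = 200/Cmax): the estimator is invariant to gain — normalization
cancels it — so per-frame exposure only protects the late, dim frames from
having camera noise amplified by the rescaling.  With the default noise
(σ = 2 counts) the recovered D is within ~7% of truth; at a fixed low
exposure the noise-inflated max-distance radius would bias D upward by
~25%, which is a real failure mode of max-based radius metrics on dim
images and is why the audit reports the excluded fraction and the tests
pin the exposure policy.

## What the generator does and does not emulate

Emulated: disc-shaped cross-sections with per-model globe-diameter ranges,
size-dependent hindered spread over 24/48 h, nasal/temporal injection
laterality, an impermeable bursa compartment (human preset), camera
background, noise and optional vignetting, and fully seeded determinism.

Not emulated: convective transport (the incubation agitation that helps
small dyes fill the cavity), 3-D geometry, lens/retina optics, dye
bleaching or clearance, plasmin reaction–diffusion kinetics, and the
anterior/posterior dual-face bookkeeping of real bisection (one image per
eye).  Consequently the small-tracer spread is conservative: the 3 kDa
preset reaches ~15% fluorescent area at 24 h rather than near-complete
coverage, because pure diffusion at physical D cannot fill a 22 mm globe
in a day.  Passing tests therefore demonstrate correct measurement of a
known transport field and correct relative ordering across tracer sizes —
not absolute agreement with in-tissue percentages.

## Statistics

Student's t (pooled variance) is the default two-group test, matching the
naming convention of the field; Welch is behind a flag.  ANOVA + Tukey HSD
uses the studentized-range distribution with pooled within-group variance
(scipy backend; cross-checked in the tests against statsmodels and a
permutation max-t oracle).  Both SD and SEM are always emitted because "±"
conventions are ambiguous; inputs are raw per-eye values, never summaries.
No multiplicity control beyond Tukey is applied.  The null calibration of
the familywise error rate uses the equivalent max-studentized-range
rejection rule, vectorized over replicates (2,000 replicates, 5 groups of
8 by default); its equivalence to the per-pair adjusted p-values is itself
asserted in the tests.

## Problem sizes used by the test suite

Cohort checks use 8 eyes per dye-by-time group (the per-group sample size
of the ex-vivo study design) at 0.1 mm grid spacing for the single-time
cohort and 0.15 mm for the two-time cohort; physics unit tests use 10–16 mm
phantom eyes at 0.2 mm spacing.  All seeds are fixed in the test
configuration and logged.

## Known limitations

- The hindrance model is a single Ogston factor; real vitreous is
  heterogeneous and multilayered, and the effective mesh size is a bulk
  surrogate.
- A 2-D disc conserves mass in-plane, whereas real bisection integrates a
  3-D distribution onto the cut face; area percentages are comparable
  across simulated conditions but not directly to tissue values.
- The centroid-based radius is a maximum statistic and inherits a positive
  noise bias on dim images (see the calibration section).
- Tie-breaking in component selection is documented but arbitrary; the
  excluded-signal fraction should be inspected whenever it is non-trivial.
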