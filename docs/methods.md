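# Methods

## Scope and physical model

`phasetomo` models a monochromatic 25 keV parallel-beam inline
phase-contrast micro-CT measurement under the projection (thin-object)
approximation.  A sample is described by per-voxel maps of the refractive
index `n = 1 − δ + iβ`; a projection at angle θ is the pair of line
integrals `D = ∫δ ds`, `B = ∫β ds` (metres of path-integrated index), and
the detected intensity for one detector row is

    ψ₀(u) = exp(−(2π/λ)B(u)) · exp(−i(2π/λ)D(u))
    I(u)  = |F⁻¹[ F[ψ₀] · exp(−iπλz f²) ]|²

— the 1-D angular-spectrum propagator over the sample-to-detector distance
z.  At z = 0 this reduces exactly to Beer–Lambert, `I = exp(−4πB/λ)`,
which is the oracle used throughout the tests.  Full 2-D propagation is
deliberately not implemented: the primary simulation unit is a 2-D slice
(one sinogram), and a 3-D phantom is a stack of correlated slices
propagated row-wise.  Partial coherence, source size, scintillator PSF and
polychromaticity are out of scope; their absence makes simulated fringes
somewhat crisper than beamline reality.

Line integrals are computed with scikit-image's Radon transform and
reconstructions with its filtered back projection (`iradon`, ramp or Hann
window, linear interpolation); both share the rotation-axis convention
(centre column index `n//2`), so the pair is self-consistent.  Sinogram
values in metres with the voxel size passed as `pixel_spacing` reconstruct
attenuation in 1/m; a noiseless absorption scan of the cord phantom
reconstructs its `4πβ/λ` map with ≈ 1.6% relative RMSE.

## Phantoms and materials

Two families, both rasterised with 1-pixel feathered (area-weighted) edges
so sub-pixel diameters are meaningful, with every inserted structure
recorded in a `truth` list:

* **Cord phantom** — embedding cylinder (radius 0.485·grid) around a cord
  disc (radius 0.293·grid, i.e. ~300 px diameter on the default 512 grid
  with 1.625 μm voxels) containing a white-matter annulus, a
  mirror-symmetric grey-matter butterfly (polar profile
  `R(θ) = R_cord(0.30 + 0.36 sin²θ + 0.10 cos θ)`), vessels of 2–8 px
  diameter (lower β than parenchyma, i.e. dark) and ~15 px somata confined
  to the grey matter.  `stain_contrast` multiplies grey-matter β by
  `1 + c` (default 0.3; 0 reproduces an unstained sample).  The default
  somata count (12) is sized for the 512 grid; smaller grids need fewer
  (placement is rejection-sampled with non-overlap constraints and fails
  loudly when asked to over-pack).
* **Wire phantom** — a solid insulation disc holding seven drawn copper
  strands inside the embedding cylinder; the standard sample for the
  projection-number study.

Material (δ, β) values at 25 keV are plausible defaults, not measured
ground truth: β of wax is fixed so a 3 mm path transmits ~70%, agar
absorbs ~10% more, soft tissue sits slightly above agar, and copper is
computed from its electron density/attenuation at 25 keV.  The required
ordering (air < wax ≤ epoxy < agar; copper ≫ insulation ≫ media) is
asserted by tests; all values are overridable per call.  Other energies
are served by approximate `δ ∝ E⁻²`, `β ∝ E⁻³` scalings.

## Detector and artefact models

Counts are `dark + I · flat_profile · 2¹⁶ · exposure_fraction` with
per-pixel Poisson noise and full-well clipping; the default exposure
fraction 0.85 reproduces the ~85%-saturation flat-field operating point.
Per-frame random streams are spawned from a single master seed, so any
subset of frames is independently reproducible and whole scans are
byte-identical across runs.

* **Zingers**: 1-px-wide linear streaks of 1–4 px, amplitude 5–30 kcounts
  added on top of the frame; ~20 per frame when enabled.
* **Ring seeds**: a seeded fraction of pixels receives a fixed gain error
  applied to the *scan* frames but not to the recorded flats — emulating
  scintillator defects that drift between flat acquisition and scan, which
  is what survives flat-field correction and reconstructs into rings.
* **Radial distortion**: the distorted frame samples the ideal frame at
  radius `r(1 + k₁r² + k₂r⁴)` about a centre; displacement grows toward
  the corners.  Undistortion inverts that mapping by fixed-point iteration
  (tolerance 10⁻³ px).

## Correction chain

Fixed order, recorded in an audit report: zinger removal (pixels exceeding
the 3×3 median by 8 robust σ, σ = 1.4826·MAD of the median residual,
replaced by the median) → dark/flat normalisation to transmission (floored
at 10⁻⁶) → undistortion → ring suppression on sinograms.  Ring suppression
subtracts the sharp part of the angle-averaged column profile (raw minus a
31-px moving average), preserving the global mean — a mean-column scheme
chosen for transparency over wavelet approaches; it fulfils the same
contract (remove angle-invariant column bias) and reduces radial
fixed-pattern power by two orders of magnitude in the tests.

**Distortion-centre estimation** screens candidate centres
(coarse-to-fine grid, 30 px radius) by undistorting the 0° and 180° check
projections with the known coefficients, mirroring the latter, aligning by
sub-pixel cross-correlation and scoring the mean squared difference; both
frames are Gaussian-smoothed (σ = 2 px) first because photon noise is
uncorrelated between the two frames and otherwise floors the score.  Ties
(and the zero-distortion case) resolve to the frame centre.  A structural
property of this method, confirmed both analytically and in simulation:
the x-coordinate of the centre is sharply identified (≲ 2 px), but the
y-coordinate only enters at second order through the centre's offset from
the flip axis — a y-centre error displaces both frames identically and
cancels in the mirrored difference, leaving a residual of ~0.02 px per
10 px of y-error at this scale.  The y-coordinate is therefore effectively
unidentifiable; symmetrically, a y-error of that size has sub-pixel impact
on the corrected data, which is why downstream round-trip and
corrected-chain quality checks are unaffected.

## Retrieval and reconstruction

The Paganin filter operates on transmission frames (2-D FFT, edge-padded
2×): division by `1 + (λ·z·(δ/β)/4π)(k_x² + k_y²)` with angular
frequencies from the retrieval pixel size, then −ln.  δ/β = 0 bypasses the
FFT and returns −ln(T) exactly.  The output is left proportional to
thickness × attenuation; absolute thickness is never needed for the
studies.  Two effective pixel sizes coexist deliberately: 1.625 μm for
geometry and 1.6125 μm as the retrieval default, mirroring the
instrument-style configuration where both appear; either can be set
explicitly.  The 180° check projection is acquired when requested but
never reconstructed.  Evenly spaced projection subsets require the subset
size to divide the full count so angles stay equally spaced; the error
message names the nearest valid sizes.

## Quality metrics and studies

* **PSNR** is implemented verbatim with the *summed* squared error in the
  denominator, `10 log₁₀[max(t)²/SSE]` — reproducing the convention of the
  procedure this package models rather than the textbook MSE form (which
  is available behind `normalised=True`).  Values are therefore negative
  for large noisy images; only differences and trends matter.
* **RMS contrast** is the sample standard deviation (n−1) over an ROI of
  an individually min–max normalised slice.  Min–max normalisation was
  chosen because "individually normalised" admits several readings; it is
  recorded in provenance.
* **Projection-number study**: the full-set reconstruction is the
  reference t(x,y); each evenly spaced subset gives n(x,y); PSNR is
  computed on the ROI crop (keeping background from dominating) and RMS
  contrast on the normalised ROI.  Run on the wire standard (512 px, 1440
  projections, subsets 720…45, PD 20 mm): PSNR rises monotonically with
  subset size and RMS contrast saturates early (last step < 1% of range).
  At this scale the RMS curve approaches its plateau from above — photon
  noise still shrinking — rather than from below as in beamline data where
  streak extremes dominate the normalisation at severe subsampling; the
  substantive behaviour (early saturation vs continued PSNR growth) is
  reproduced and is what the acceptance tests assert.
* **δ/β screen** (cord scan at PD 160 mm, ratios 1…3000): RMS contrast on
  an ROI *inside* the cord (0.35·grid) — including the cord/embedding
  boundary lets that never-blurring step dominate and masks the loss of
  interior features.  The curve peaks at an interior ratio (≈ 10 at
  default conditions): light filtering removes noise and fringes faster
  than structure, heavy filtering blurs the structure itself.
* **PD screen** (cord, 20–320 mm, noise-free by default so the trends
  reflect physics): RMS contrast is taken on the *raw* ROI because all
  slices share physical units (1/m) and min–max normalisation would let
  the growing fringe extremes mask the contrast gain; the fringe-overshoot
  score is the mean excursion of reconstructed attenuation beyond the
  phantom's true material range inside the reconstruction circle.  Both
  rise monotonically with PD — the enhancement/obscuration trade-off.
* **Histogram peaks**: 256-bin histogram, moving-average smoothing
  (window n_bins/32), two most prominent maxima with a prominence floor of
  max(5% of the tallest peak, 3·√peak) — the latter rejects
  Poisson-counting wiggles on flat histograms; ties resolve to the lower
  grey level, and a histogram without two clear modes is flagged rather
  than guessed at.
* **Saturation fraction** of a curve is measured against its observed
  dynamic range (baseline at the smallest parameter, ceiling at the
  largest finite one), because "percent saturation" is otherwise undefined
  when the metric diverges at the reference itself.

## Numerical choices

FFTs pad to the next power of two with edge replication (propagation and
Paganin) to suppress wrap-around; transmission is floored at 10⁻⁶ before
logarithms; FBP relies on scikit-image's finite-ramp handling; distortion
inversion tolerance is 10⁻³ px; zinger detection uses a global robust
scale per frame (stable even on frames that are mostly structure).
Degenerate inputs fail loudly: constant frames for centre estimation,
single-pixel ROIs, constant slices for normalisation, non-divisor subset
sizes, unimodal histograms.

## Problem sizes

The package's study defaults are desk-scale: 512-px phantoms,
1440-projection scans, 720-projection screens — proportioned like the
beamline setting (a ~3.5 mm sample in a ~4.2 mm field of view at 1.625 μm)
at one-fifth the linear size.  These sizes are the package's chosen
operating point for interactive use; everything scales with `grid_px` and
`n_angles`.

## What passing tests do and do not show

The synthetic phantoms reproduce geometry, contrast orderings and artefact
statistics, not tissue microstructure: no laminar texture, no stain
diffusion or penetration gradients, no shrinkage, no sample drift, no wax
small-angle scattering blur.  Passing the study reproductions therefore
shows that the *procedures* (iterative downsampling, PD screening, δ/β
screening, the correction chain) behave as described on data with known
ground truth — not that any particular δ/β or PD value is optimal for a
given real sample, which remains an empirical, sample-dependent choice.
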