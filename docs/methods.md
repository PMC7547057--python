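# Methods

## Overview

`petac` couples a parametric digital torso phantom to a deliberately
simplified CT/PET simulator so that the full AC-dose analysis — one PET
emission dataset reconstructed once per CT-derived attenuation map over a
24-acquisition × 2-algorithm grid — runs in minutes on one CPU. The
analysis layer (ROI statistics, ΔCOV paired testing, voxel-wise QSD
exceedance, significance-mask localization) is independent of the
simulator and applies unchanged to real co-registered volumes.

## Phantom

The phantom is a union of parametric solids in world millimetres
(elliptic-cylinder torso, ellipsoidal lungs/heart/liver, a spherical lung
lesion, a dense spine cylinder, two soft-tissue "arm" cylinders lateral to
the torso acting as attenuators only). Activities are prescribed in SUV —
soft tissue 1.0, heart 4.0, liver 2.5, lung lesion 4.0 (17 mm diameter);
lungs, spine and arms carry none — and CT numbers in HU (soft tissue ~40,
lungs −750, spine 700). Rasterization is voxel-center inclusion with
later compartments overriding earlier ones, so rasterized compartments
are disjoint; the same geometry can be sampled at any grid. Grid defaults
are 128×128×40 PET voxels at 4 mm isotropic, with the CT grid refining
the PET grid 2× per axis; indices are 0-based with world coordinates at
voxel centers and the origin at the grid center.

## CT simulation surrogate

Vendor CT reconstruction chains are not modelled; the simulator works in
the image domain with three behavioral terms whose *statistical
signatures* matter for AC:

1. **Quantum noise.** Zero-mean noise with a ramp-shaped power spectrum
   (the FBP noise texture), per-slice, with standard deviation
   `sigma0 / sqrt(CTDI)`; `sigma0 = 25 HU·sqrt(mGy)`, giving ~46 HU at the
   lowest grid dose (0.3 mGy) and ~14 HU at the reference dose (3.3 mGy)
   on the fine CT grid — clinically plausible low-dose noise levels.
2. **Beam hardening.** The polychromatic under-measurement grows roughly
   quadratically with water-equivalent path length, so an artifact image
   is reconstructed (ramp-filtered backprojection) from the *squared*
   density sinogram and subtracted, scaled by
   `bh_hu × (120 / kVp)^3` with `bh_hu = 12 HU`. The artifact is darkest
   where many dense chords cross — the lateral corridor through spine and
   arms — and is ~3.4× deeper at 80 kVp than at 120 kVp. It affects FBP
   and IR alike, being acquisition physics.
3. **IR surrogate.** Iterative CT reconstruction is represented by
   edge-preserving total-variation denoising (weight proportional to the
   noise level, so smoothing strengthens as dose falls) plus a
   dose-dependent negative HU bias,
   `−ir_bias_hu × exp(−CTDI / 0.35 mGy) × ((HU + 1000)/1000)²` applied to
   tissue voxels, with `ir_bias_hu = 60 HU`. This is the mechanism by
   which the surrogate reproduces the clinically observed signature that
   very low-dose iterative CT *underestimates* attenuation (and hence PET
   activity), with the effect vanishing by ~1 mGy and denser voxels
   biased more. The constants were calibrated once so that, at the
   pattern-analysis grid, the QSD is ~4–5% of the liver mean, lowest-dose
   IR exceedance is a few percent of body voxels, FBP stays within one
   QSD at all doses, and all protocols converge to the reference above
   1 mGy — the signature set the pipeline is designed to probe. FBP adds
   no systematic algorithmic HU bias.

HU volumes are clipped to [−1024, 3071]. CT datasets are block-averaged
to the PET grid, converted to 511-keV linear attenuation with the
standard bilinear map (`mu = 0.096 × (1 + HU/1000) cm⁻¹` below water; a
shallower bone segment of 4.0×10⁻⁵ cm⁻¹/HU above), and smoothed with a
6 mm FWHM Gaussian the way a scanner prepares AC maps for PET resolution.
The *true* attenuation used in emission simulation is the unsmoothed
conversion of the noiseless phantom, so even a perfect CT yields the
small, shared AC-preparation error that cancels in TR−RR comparisons.

## CTDI model

The scanner-reported dose is modelled as `CTDI = c(kVp) × mAs` with
per-voltage coefficients fitted by least squares through the origin to
the calibration table (c ≈ 0.019, 0.040, 0.065 mGy/mAs at 80, 100,
120 kVp); the table is pitch-independent at the scanner's 0.1 mGy
reporting precision, so pitch enters the pipeline only through protocol
bookkeeping. All 24 grid protocols are reproduced within ±0.1 mGy.
Voltages between calibrated values interpolate linearly in c; outside the
range, an explicit extrapolation flag is required.

## PET simulation and reconstruction

The simulator is 2-D-slice-stacked parallel-beam. The projector is a
sparse matrix built pixel-driven (each pixel center splat linearly onto
the two nearest detector bins per view; detector pitch = pixel pitch;
views uniform over [0, π), count ≈ 0.94 × image side rounded to a
multiple of 15 so that 3 or 5 subsets divide it). Because the adjoint is
the exact matrix transpose, the OSEM update is internally consistent.

One emission dataset per study: the activity is forward projected, each
line of response attenuated by `exp(−∫ mu dl)` through the true
attenuation map, scaled to a target expected total (default 2×10⁵ counts
per slice), and Poisson sampled. Reconstruction is standard OSEM
(multiplicative update, interleaved angle subsets, attenuation factors in
the system model; nonnegativity is preserved and an all-zero sinogram
yields an all-zero image) with the clinical operating point of 3
iterations × 3 subsets as default. SUV calibration is study-level: the
reconstruction using the *true* attenuation map is scaled so its
whole-phantom (body) mean equals the ground-truth body mean, and that
single factor is applied to every reconstruction, mimicking scanner
cross-calibration.

At 3 it × 3 ss the reconstruction is deliberately partially converged
(like its clinical counterpart): large-compartment means sit a few
percent low and the 17 mm lesion recovers only partially (it is assessed
through its ROI *maximum*, the conventional lesional statistic). Engine
accuracy is verified separately at a converged operating point (20 it ×
6 ss, ≥5×10⁶ counts/slice), where soft tissue, liver and heart means are
recovered within ~2%.

Randomness: one master seed feeds `numpy.random.SeedSequence`; child 0
drives the PET Poisson sample and child *i*+1 the CT simulation of
protocol *i* in grid order. A bundle is bit-identical given (seed,
protocol list).

## Analysis conventions

* ROIs are 2-D circles on a named axial slice; membership is
  voxel-center inclusion with a tie at exactly the radius counting as
  inside. Sample SD (n−1) throughout. Default radii: liver 15 mm, soft
  tissue 10 mm, beam-hardening soft tissue 8 mm, lesion 8.5 mm; default
  placements derive from the phantom geometry and are configurable via
  YAML. The lesion's statistic of record is the maximum, others the mean.
* ΔCOV = COV_FBP − COV_IR over matched acquisitions (all 24 pairs by
  default); zero difference variance is a flagged degenerate result, not
  an exception.
* QSD = sample SD of the RR liver ROI and must be positive.
* Voxel differences are signed RR − TR (positive = TR underestimates).
  Exceedance uses the absolute difference with a *strict* inequality at
  the QSD boundary. Max/mean voxel differences are percentages of the RR
  voxel value, restricted to RR > 0.1 SUV (configurable floor) to keep
  the ratio defined in zero-activity lung and air.
* The support for voxel tests defaults to the phantom body (air
  excluded), because air voxels are exactly zero in a noiseless-air
  simulator and would degenerate the paired t test; whole-volume mode is
  available by flag for real data. No multiple-testing correction is
  applied across the 47 TR-vs-RR tests.
* Localization regions: high-activity compartments (SUV ≥ 2);
  attenuation-interface shells (within 2 voxels of an internal CT-density
  step > 150 HU, restricted to tissue voxels — the external body–air
  outline and the air-like side of a step are excluded since no emission
  originates there, so no SUV difference is observable there); the
  beam-hardening corridor (lateral band through the spine); background.
  Regions may overlap; enrichment is region exceedance rate over the
  global rate.

## Problem sizes

Pattern-level analyses (the multi-seed ensemble in the test suite and the
acceptance script) run the full 48-reconstruction grid at 64×64×16 PET
voxels of 8×8×10 mm — the same phantom geometry at coarser sampling —
where the default 2×10⁵ counts/slice yields a liver COV of ~4–5%,
matching the per-voxel statistics regime the analysis targets; finer
grids need proportionally more counts per slice for the same per-voxel
noise (at the full 128²×40 default, ~1×10⁶ counts/slice gives a
comparable QSD fraction). Parameter recovery runs at the full default
grid.

## Known limitations

* The CT surrogate reproduces statistical signatures, not vendor
  algorithms: absolute exceedance percentages are not comparable to any
  particular scanner, only their ordering across dose and algorithm.
* FBP AC maps show a small *positive* SUV bias at very low dose (noise
  rectification through the exponential attenuation correction), where
  physical scanners with segmented AC pipelines show a small
  underestimation; both stay within one QSD.
* The beam-hardening corridor shows depressed HU but, at soft-tissue
  activity (SUV 1), its voxel differences stay below the QSD, so
  corridor enrichment is near zero in the synthetic bundle — weaker
  localization than a physical scanner exhibits there.
* No scatter, randoms, decay or point-spread modelling; no TOF; no
  helical geometry (pitch acts only through dose bookkeeping); 2-D
  slice-stacked projection rather than fully 3-D.
* Emission simulation and reconstruction share one projector (an
  "inverse crime"), which is appropriate here because every comparison
  is differential across AC maps, not a claim about absolute resolution.
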