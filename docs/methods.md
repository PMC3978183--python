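# Methods

`specres` characterizes the spatial resolution of 99mTc SPECT as a function
of position in the field of view, voxel size, reconstruction algorithm and
iteration count, by simulating the classic point-source experiment: small
(< 1 voxel) sources placed coplanar at several radii from the isocenter,
imaged in air, in a cold (non-radioactive water) background, and in a warm
(low-activity water) background, reconstructed with FBP and with OSEM, and
measured by fitting radial and tangential profiles with a Gaussian plus a
constant.

## Geometry and phantoms

All modelling is 2-D transaxial: the sources sit in a single transverse
plane, which is where the measurement is defined. Coordinates are physical
millimetres with the origin at the isocenter; voxel centers lie at
`(i + 0.5 - n/2) * voxel_mm`. The acquisition grid is 256 x 256 at 0.9 mm
(230.4 mm field of view); projections are rebinned by block sums of 2 and 4
to emulate 128 (1.8 mm) and 64 (3.6 mm) matrices from the *same* data.

Point sources are deposited by bilinear weighting onto the four nearest
voxel centers, which preserves both total activity and the activity-weighted
centroid exactly. Azimuths follow golden-angle staggering with a
deterministic adjustment pass enforcing a minimum pairwise separation of the
realized centers. The default separation is 40 mm: the layout's design
requirement is that reconstructed signals not overlap, and early-iteration
OSEM and FBP blobs in this simulator reach ~19-24 mm FWHM, for which 25-30 mm
spacing demonstrably contaminates neighbouring profile fits. 40 mm is the
largest value jointly feasible for all three layouts (air uses radii
2-11 cm; the 22 cm cylinder restricts warm/cold to 2-10 cm, and the analysis
uses 2-9 cm).

The warm background adds uniform activity inside the 22 cm cylinder at
`min(source peak voxel) / sbr` with `sbr = 500` by default. The experiment
this emulates specifies only a per-voxel source-to-background ratio above
50; a sub-microlitre droplet of concentrated pertechnetate over a
low-concentration fill is realistically 10^2-10^4, and ratios near the lower
bound make the warm sources unmeasurable at coarse voxels and low update
counts, contrary to the reference measurements. Attenuation maps are
analytic: mu = 0.015/mm (water at 140 keV) inside the cylinder, zero
outside, zero everywhere in air.

## Acquisition model

The camera is a parallel-hole system on a circular 360-degree step-and-shoot
orbit (default 250 mm radius, 360 views at full scale). The system
resolution follows the standard distance law

    FWHM(d) = sqrt(intrinsic^2 + (offset + slope * d)^2)

with defaults intrinsic 3.8 mm, offset 1.0 mm, slope 0.07 — representative
of a low-energy high-resolution collimator class, not calibrated to any
vendor.

The projector is rotation-based. Per view the image is rotated into the
detector frame by a mass-conserving bilinear splat (each voxel scattered
onto the four nearest rotated-grid centers), multiplied by per-voxel
attenuation survival factors (half-voxel self-attenuation plus the
cumulative path to the detector), convolved per depth row with the Gaussian
of that row's distance, and summed along the rays. The depth blur is applied
in the frequency domain using the DFT of a *sampled, unit-sum Gaussian
kernel*: the kernel is nonnegative (no ringing at coarse bin pitches),
circularly symmetric (real transfer, hence self-adjoint), and exactly
mass-conserving. Because every stage has an exact transpose
(splat <-> gather, diagonal attenuation, symmetric convolution,
sum <-> broadcast), the backprojector is the exact adjoint of the projector
to float rounding — the property the EM algorithm assumes.

Scatter is modelled phenomenologically: the scatter component is the primary
convolved along the bin axis with a broad Gaussian (60 mm FWHM), scaled so
that scatter/(scatter+primary) equals the scatter fraction globally (0.30 in
water, 0 in air). The lower energy window records
`lower_window_scatter_gain` (default 2.0) scatter counts per photopeak
scatter count and no primary. Poisson noise scales the photopeak so the mean
per-view total matches the target (250,000 at full scale) and draws all
counts from one seeded generator recorded in the sinogram metadata.

## Reconstruction

**FBP**: frequency-domain ramp filter, optionally Hann-apodized (the
default, cutoff at Nyquist, configurable in cycles/mm), zero-padded to at
least twice the bin count, then pixel-driven backprojection with linear
interpolation and a pi/n_views scale. No attenuation or scatter
compensation; its use case is sources in air.

**OSEM**: multiplicative EM over ordered subsets. Views are assigned
round-robin by view index modulo SUB, subsets visited in bit-reversed order
(fixed for determinism); SUB = 1 reduces exactly to MLEM. Resolution
recovery includes the distance-dependent PSF in the system operator (the
recovery model may deliberately differ from the simulation's collimator to
probe mismatch). Attenuation correction uses attenuated
forward/backprojection with the analytic mu map standing in for CT. Scatter
correction adds the dual-energy-window estimate
`dew_k * lower * (photopeak width / lower width)` (dew_k default 0.5, which
together with the default lower-window gain of 2 makes the estimate
calibrated) *inside the forward model* rather than pre-subtracting it,
keeping the Poisson statistics of the measured counts valid. The EM ratio is
guarded by `max(denominator, 1e-12)` so exact data are untouched; voxels
with zero sensitivity are frozen at zero.

## Measurement

Each source is localized as the intensity-weighted centroid of voxels above
half the background-subtracted local maximum inside a search window. The
window background is its lower quartile and the detection threshold is five
noise-sigmas, with noise estimated from median absolute adjacent-voxel
differences — a deliberate choice so that smooth background structure (or a
blob filling much of the window) does not mask a genuine peak, while a flat
image still fails detection.

Radial profiles run along the line from the isocenter through the source,
tangential profiles along the in-plane perpendicular, sampled by bilinear
interpolation at voxel/3 steps. Default half-lengths: 25 mm (air/cold OSEM),
40 mm (warm and FBP) — chosen to cover the expected blob at roughly twice
its FWHM while staying clear of neighbouring sources. The model
`c + A exp(-(x-mu)^2 / 2 sigma^2)` is fit by bounded nonlinear least squares
(moment-based start; amplitude nonnegative, center inside the window, width
at most the window span); the constant absorbs the warm background, so no
pre-subtraction is applied. FWHM = 2 sqrt(2 ln 2) sigma, with its
uncertainty from the residual-scaled covariance. Fits that fail to converge,
pin the width at the window bound, or collapse below half the sample step
are flagged and excluded from trends.

## Trend statistics

FWHM vs radius uses ordinary least squares (mm per cm, t-based confidence
intervals; the two-point case returns the interpolating line with infinite
intervals). FWHM vs IT x SUB uses the two-parameter power law
`a * n^(-b)` fit as OLS in log-log space (positive b = improving
resolution); an additive floor is available but off by default since the
converged width is not identified on short ladders. The constancy check is
the chi-square statistic about the inverse-variance-weighted mean with n-1
degrees of freedom, using the per-point sigma from the profile-fit
covariance. Anisotropy is summarized as signed RR - TR per radius with a
majority-sign verdict. Image noise is the coefficient of variation over a
warm-background mask at least 20 mm from every source.

## Study sizes used by the tests and the acceptance script

The full-scale study (360 views, 250k counts/view, the complete
IT x SUB ladder at three matrices) is supported by `run_experiment` but the
shipped checks run desk-scale versions chosen as representative: the in-air
experiment at 180 views, noise-free, analyzed at the 128 matrix with FBP and
OSEM 10x18; and the warm experiment at 120 views with Poisson noise at the
64 matrix, 6 subsets with snapshots at 3/30/60/90 iterations (IT x SUB of
18/180/360/540). These sizes reproduce all the qualitative endpoints while
keeping a single-CPU run in seconds.

## What the simulator does and does not emulate

It emulates: distance-dependent collimator blur, water attenuation, a broad
scatter component split across two energy windows, Poisson counting at the
stated per-view level, sub-voxel source placement, projection rebinning, and
the full reconstruction/compensation matrix. It does not emulate: septal
penetration, energy-spectrum physics, detector dead time,
center-of-rotation errors, 3-D (axial) blur, or any vendor's proprietary
weighting — so passing tests demonstrate the behaviour of the *method* under
the stated physics, not agreement with a specific scanner's printed FWHM
values, which are treated only as a benchmark table for the trend
statistics.

## Known limitations

* With the default collimator law, the per-view blur seen by a source at
  radius r spans FWHM(R-r) to FWHM(R+r); after ramp-filtered angular
  averaging this makes the noise-free FBP point-spread function genuinely
  (if mildly) nonstationary and anisotropic at the periphery — tangential
  FWHM ~11% narrower than radial at 9 cm. Real FBP measurements read as
  stationary and isotropic because measurement noise dominates these
  differences; a noise-free chi-square test against fit-covariance
  uncertainties resolves ~0.1 mm trends and therefore rejects constancy.
  The corresponding acceptance test records this honestly and fails its
  stated gate; all qualitative orderings (FBP far flatter and far wider
  than OSEM) hold.
* The scatter model is a single stationary broad kernel; no object-dependent
  scatter.
* Trend uncertainties for noise-free inputs reflect model mismatch, not
  counting statistics, and should not be interpreted as measurement error.
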