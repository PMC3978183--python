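# specres

Characterization of 99mTc SPECT spatial resolution across the field of view,
voxel size and iterative-reconstruction parameters — as a fully simulated,
tested pipeline.

Quantitative SPECT (dosimetry for radionuclide therapy, uptake
quantification) needs to know the point-spread function everywhere in the
image, because partial-volume corrections inherit every property of the
reconstruction. Resolution measured the classical way — point sources in
air, FBP — is stationary and isotropic, but clinical images are made with
OSEM, resolution recovery, attenuation and scatter corrections, over
scattering media with background activity, where resolution becomes
nonstationary (improving with radius r from the isocenter), anisotropic
(radial RR differs from tangential TR FWHM), and convergence-dependent
(improving with the iteration-subset product IT x SUB).

`specres` builds the whole experiment in software:

* **phantoms** — coplanar sub-voxel point sources at radii 2-9(11) cm,
  staggered azimuths, inside a 22 cm water cylinder (warm or cold) or in air;
* **acquisition** — 360-degree parallel-hole orbit with distance-dependent
  collimator blur `FWHM(d) = sqrt(intrinsic^2 + (offset + slope d)^2)`,
  attenuation, a dual-energy-window scatter model, Poisson noise at a target
  counts-per-view, and exact projection rebinning 256 -> 128 -> 64;
* **reconstruction** — FBP (ramp/Hann) and OSEM with switchable resolution
  recovery (RR), attenuation correction (AC) and dual-energy-window scatter
  correction (SC), over an exactly adjoint projector/backprojector pair;
* **measurement** — radial/tangential profiles through each source fit to a
  Gaussian plus a constant; FWHM = 2 sqrt(2 ln 2) sigma;
* **trends** — linear FWHM(r) fits, power-law FWHM(IT x SUB) fits
  `a n^(-b)`, a chi-square constancy test, anisotropy bookkeeping and a
  background-noise (CV) metric.

## Worked example

```python
import numpy as np
from specres import (BackgroundSpec, ReconConfig, fbp, rebin, reconstruct,
                     resolution_record, fit_linear)
from specres.runner import ExperimentConfig, simulate_experiment

# sources in air at 2-9 cm, noise-free, 180 views at the 256-bin matrix
cfg = ExperimentConfig(experiment="B", n_views=180, counts_per_view=None,
                       radii_cm=tuple(float(r) for r in range(2, 10)))
sino, layout = simulate_experiment(cfg)
s128 = rebin(sino, 2)                      # 1.8 mm voxels

vol_fbp = fbp(s128)
vol_osem = reconstruct(s128, ReconConfig(iterations=10, subsets=18),
                       background=BackgroundSpec.air())

for vol, half, name in ((vol_fbp, 40.0, "FBP"), (vol_osem, 25.0, "OSEM 10x18")):
    recs = [resolution_record(vol, s.center_mm, s.radius_cm, half_length_mm=half)
            for s in layout]
    mean = np.mean([r.mean_mm for r in recs])
    print(name, f"mean FWHM {mean:.2f} mm;",
          fit_linear(recs, 'mean').summary())
```

prints (to the last digit, this being a deterministic noise-free run):

```
FBP mean FWHM 17.88 mm; FWHM(r) = 18.20 -0.058 r mm (slope 95% CI [-0.231, 0.115], n=8)
OSEM 10x18 mean FWHM 6.73 mm; FWHM(r) = 7.86 -0.206 r mm (slope 95% CI [-0.251, -0.161], n=8)
```

Read: FBP is ~2.7x wider than OSEM with resolution recovery at the same
data, and its FWHM-vs-radius slope is compatible with zero, while the OSEM
resolution clearly *improves* (narrows) away from the isocenter — the
nonstationarity that partial-volume corrections must account for. A warm
background makes OSEM dramatically worse at equal IT x SUB and introduces
the opposite anisotropy (tangential narrower than radial); resolution then
converges as a power law in IT x SUB while background noise rises
monotonically — all measurable with `run_experiment` /
`specres.trends`.

A command-line interface mirrors the library
(`specres simulate|reconstruct|analyze|experiment|report`); volumes and
sinograms are NIfTI with JSON sidecars, tables are CSV, configurations YAML.

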