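# mrsipvc

Postprocessing for 7 T FID-MRSI metabolite maps: acquisition point-spread
modelling, PSF-adjusted gray/white/CSF partial-volume correction with
pure-tissue regression, steady-state T1 correction, quality-assurance
filtering, regridding, and atlas-space group averaging with data-density
masking — plus a digital brain phantom so every stage can be validated
against known ground truth without scanner data.

## Who this is for

Spectroscopic-imaging groups who fit their spectra elsewhere (e.g.
LCModel) and need the downstream map-level corrections: MRSI voxels are
large (5 × 5 × 10 mm³) and k-space truncation bleeds signal between them,
so raw metabolite maps mix gray matter (GM), white matter (WM) and CSF
contributions. This package separates them at 1 mm resolution and builds
group-average maps in a common reference space.

## The model

A voxel's metabolite ratio (over total creatine, tCr) is a weighted sum of
pure-tissue levels, with CSF contributing no metabolite signal:

    M(v) = f_GM(v) · S_GM + f_WM(v) · S_WM

where the tissue fractions are **PSF-adjusted**: 1 mm segmentations are
convolved with the acquisition PSF — the magnitude of the inverse Fourier
transform of the elliptical k-space shutter times the Gaussian
spatial-response apodization, which for the standard 44 × 44 / 220 mm
protocol has an 8.75 mm in-plane FWHM. Writing g = f_GM/(f_GM+f_WM)
(the normalized GM fraction) gives a line

    M / (f_GM + f_WM) = S_WM + (S_GM − S_WM) · g

fitted by ordinary least squares over QA-surviving voxels (kept iff
SNR > 3, FWHM < 0.15 ppm, Lip13ab/tCr < 2, CRLB < 50 %SD, and the voxel's
tCr CRLB passes). Extrapolation to g = 1 and g = 0 gives the pure-GM and
pure-WM levels. Each voxel's value is then redistributed over its 250
1 mm cells in proportion to the locally predicted signal (conserving the
voxel mean exactly), corrected for steady-state T1 saturation

    E(T1) = sin α (1 − e^(−TR/T1)) / (1 − cos α e^(−TR/T1)),
    factor = E(T1_tCr) / E(T1_met)

(α = 35°, TR = 300 ms), carried to a reference space through a
rigid + affine + nonlinear transform chain composed into a single
resampling, and averaged across subjects with a per-cell data-density
count; cells with fewer than 3 contributing subjects are masked.

## Worked example

```python
import numpy as np
from mrsipvc import (AcquisitionGeometry, build_elliptical_shutter, build_psf,
                     default_phantom_spec, generate_study, build_qa_mask,
                     propagate_tcr_filter, QAThresholds, run_pvc,
                     default_t1_table)

geo = AcquisitionGeometry()                      # 44x44, 220 mm FOV, 2 slices
psf = build_psf(geo, build_elliptical_shutter(geo))
print(f"PSF FWHM: {psf.fwhm_mm:.4f} mm")

study = generate_study(default_phantom_spec(seed=7, noise_sd=0.05))
th = QAThresholds()                              # SNR>3, FWHM<0.15, ...
masks = {m: build_qa_mask(study.qa, th, m) for m in study.native}
masks = propagate_tcr_filter(masks, study.qa, th)
print(f"QA kept {masks['Glu'].n_kept}/{masks['Glu'].keep.size} voxels for Glu")

res = run_pvc(study.native["Glu"], study.fractions_psf, geo,
              mask=masks["Glu"], t1s=default_t1_table())
e = res.estimate
print(f"Glu/tCr pure-tissue fit: s_gm={e.s_gm:.3f}  s_wm={e.s_wm:.3f}  "
      f"(n={e.n_voxels}, r2={e.r2:.3f})")
```

prints

```
PSF FWHM: 8.7272 mm
QA kept 3380/3872 voxels for Glu
Glu/tCr pure-tissue fit: s_gm=1.190  s_wm=0.699  (n=1592, r2=0.662)
```

The PSF width is the composite in-plane response of the elliptical
shutter plus reconstruction apodization. The QA stage discarded the
phantom's overcrushed low-SNR rim and broadened-linewidth frontal zone
(492 of 3872 voxels). The regression recovers the phantom's true pure
tissue levels (S_GM = 1.2, S_WM = 0.7) to within its standard error from
noisy data, and `res.corrected` holds the partial-volume- and
T1-corrected 1 mm map.

A `mrsipvc` command-line tool exposes the same stages
(`simulate`, `psf`, `qa`, `pvc`, `normalize`, `average`, `roi`, `run`).

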