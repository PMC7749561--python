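# Methods

## Acquisition PSF model

The in-plane spatial response of a phase-encoded MRSI acquisition is the
inverse Fourier transform of its k-space sampling window. We model it as

    PSF = | F⁻¹ [ shutter(k) · W(k) ] |,

zero-padded to the 1 mm anatomical grid and normalized to unit sum.
The shutter is the inscribed ellipse of the acquisition matrix
(centre at index (N/2, M/2), the DFT convention for even matrices; the
mask is point-symmetric under index negation modulo the matrix size, and
the resulting magnitude kernel is exactly point-symmetric about its
peak). W(k) is the Gaussian apodization applied when reconstruction
down-samples the overdiscretized grid to the acquired matrix; it is
parametrized by the FWHM of its *spatial* response.

**Default response width.** The reconstruction's Gaussian target response
is a free parameter of the protocol. The package defaults to 7.5 mm —
1.5× the nominal in-plane voxel, a standard widening factor for Gaussian
target response functions — which yields a composite PSF FWHM of 8.73 mm
for the 44 × 44 / 220 mm elliptical-shutter protocol, matching the
protocol's quoted 8.75 mm width to 0.3 %. A 5 mm response (the nominal
voxel size) would give 7.71 mm and is *not* consistent with that quoted
composite width. The parameter is exposed in the config
(`geometry.response_fwhm_mm`).

The through-slice response is treated as an ideal 10 mm boxcar: the
shutter and apodization act in-plane only, so the PSF is strictly 2-D and
applied per 1 mm sub-slice.

**FWHM measurement** walks outward from the kernel peak along each
in-plane axis to the first half-maximum crossing with linear
interpolation between grid samples, and averages the two axis widths.
Sub-grid precision without model assumptions; degenerate single-cell
kernels report widths ≤ 2 grid steps; flat kernels raise.

**Boundary handling.** Segmentations are convolved with the PSF using
reflective padding by default, so tissue at the slab edge is not
artificially destroyed. Because the truncated-k-space kernel has
long ringing tails, reflection conserves total tissue volume only
approximately (worst case a few percent when structures touch the slab
edge); the periodic mode (`boundary="wrap"`) conserves it exactly and is
used wherever an exact-conservation check is wanted. Convolved fractions
are clipped to [0, 1] only against numerical overshoot (< 1e−6); larger
excursions raise.

## Voxel sampling and the pure-tissue regression

Voxel sampling is modelled as a boxcar average of the PSF-blurred field
over each 5 × 5 × 10 mm voxel (the boxcar is the voxel's intrinsic
aperture; the PSF captures truncation and apodization). The same block
average aggregates the PSF-adjusted 1 mm fractions to the native grid, so
the model's forward and inverse paths are consistent by construction.

The regression uses the tissue-normalized form: y = M/(f_GM+f_WM) against
g = f_GM/(f_GM+f_WM), unweighted OLS (weighting by tissue fraction is
available as an option). Voxels enter the fit only if they survive QA,
carry a value, and have f_GM+f_WM ≥ `min_tissue` (default 0.5):
CSF-dominated voxels have unstable normalized values. One global
(S_GM, S_WM) pair is fitted per metabolite per subject. Negative
extrapolated values are retained with a warning, never clipped — silent
clipping would bias group statistics. Fits with no variation in g, or
with fewer than `min_voxels` (default 10) points, raise.

## Redistribution and its exactness

Within each native voxel, cell values are
`measured · p(r) / mean(p)` with `p(r) = f_GM(r)·S_GM + f_WM(r)·S_WM`
evaluated on the PSF-adjusted 1 mm fractions. The voxel mean is conserved
to machine precision by construction and pure-CSF cells receive zero;
voxels whose predicted signal vanishes everywhere are flagged missing.

Because redistribution allocates by the *adjusted* composition, the field
the correction reconstructs is the PSF-consistent signal
`f_GM_psf·S_GM + f_WM_psf·S_WM`, not the raw-composition signal: at
tissue boundaries the acquisition has genuinely mixed the signal and no
within-voxel reallocation can unmix beyond the PSF's support. The
phantom therefore carries both truth fields (`truth_raw`, `truth_psf`),
and the package's central oracle — noiseless forward simulation followed
by the full correction — recovers `truth_psf` to better than 1e−6
wherever the tissue fraction is at least 0.5. Against `truth_raw` the
corrected map is closer than the uncorrected one in ROI means (contrast
restoration), but residual blur remains at structure borders.

A related consequence: for a noiseless phantom whose deep-GM nucleus is
comparable in size to the PSF, the within-ROI standard deviation of the
corrected map can *decrease* slightly relative to the blocky regridded
native map, even as the ROI mean moves toward the pure-GM level and the
GM–WM contrast strictly increases. Broader value distributions after
correction are a property of noisy, cohort-averaged data, not of the
noiseless limit; the tests assert the mean-shift and contrast properties.

## Steady-state T1 correction

Ratio maps are multiplied by E(T1_tCr)/E(T1_met) with
E(T1) = sin α (1−e^(−TR/T1)) / (1−cos α e^(−TR/T1)), per tissue, mixed at
each 1 mm cell as (f_GM·F_GM + f_WM·F_WM)/(f_GM+f_WM). The mixing rule is
a first-order choice — exact in single-tissue cells, an approximation in
mixed ones. T1 values ship as an editable table whose defaults are
approximate 7 T GM/WM literature values at the right order of magnitude;
studies should substitute their preferred values via the config. The
round-trip oracle uses a neutral table (metabolite T1 = tCr T1, factor
exactly 1) so the redistribution identity is tested independently of the
mixing approximation.

## QA filtering

Keep-criteria are strict inequalities (SNR > 3, FWHM < 0.15 ppm,
Lip13ab/tCr < 2, CRLB < 50 %SD): a voxel exactly at a threshold is
discarded. Because all maps are ratios over tCr, voxels whose tCr CRLB
exceeds the threshold are removed from every metabolite's mask
(idempotent intersection). Masks carry per-criterion provenance: every
discarded voxel records which criteria failed. CRLB values are relative
(%SD); the FWHM field is whatever the fitting stage reports per voxel.
Missing values are quiet NaN in volumes and empty cells in tables.

## Spatial normalization and averaging

Native maps are subdivided onto the 1 mm grid by nearest-neighbour
replication (one voxel → 250 cells; half-open extents, lower index wins
at boundaries). The slice→anatomy rigid, anatomy→reference affine and
optional dense displacement field are composed and applied in a *single*
resampling — sequential stage-by-stage resampling is provided only for
comparison and accumulates more interpolation error. The displacement
field lives on the reference grid in millimetre offsets and is added to
each reference sample location before the inverse affines (the usual
pull-back convention for nonlinear registration outputs). Trilinear
interpolation is missing-aware: weights renormalize over present
neighbours, and a cell is missing only if all contributing inputs are.
Defaults: trilinear for continuous metabolite maps, nearest for masks and
QA maps. The reference grid is configurable; tests use small synthetic
references so no atlas download is needed.

Group averages count per-cell data density (subjects contributing after
QA and normalization); cells below `min_density` (default 3) are masked.
The SD uses the n−1 denominator and is missing for density < 2.
Per-cell accumulation runs in value-sorted order, making the result
bit-identical under permutation of the input list. ROI statistics report
mean ± SD over non-missing cells per region; regions with no coverage
are reported absent, not zero.

## The phantom

The synthetic study emulates a two-slice axial slab at the level of the
subcortical nuclei: a WM elliptical brain, a 6 mm cortical GM ribbon,
paired CSF ventricles, and four deep-GM nuclei, rendered at 1 mm with
8× per-axis in-plane supersampling so boundary cells carry true partial
fractions (within 0.02 of dense coverage). Default pure values
(ratio/tCr): Glu (1.2 GM, 0.7 WM), tNAA (1.6, 1.45), tCho (0.22, 0.32) —
GM/WM contrasts in the direction reported for these metabolites. Noise
is additive Gaussian on native-grid *fitted-map* values (σ default 0.05),
not on spectra: the pipeline under test starts at fitted maps. QA maps
carry a jittered baseline (SNR 20, FWHM 0.06 ppm, Lip/tCr 0.5) with CRLB
tied inversely to SNR (400/SNR), plus defect zones: an overcrushed
cortical rim forced to SNR 1 and a frontal box with 0.25 ppm linewidth.
Everything is bit-reproducible from (spec, seed).

What the phantom does *not* emulate: spectral fitting itself, lipid
contamination structure, B0/B1 inhomogeneity beyond the QA defect zones,
inter-subject anatomical variability (cohort subjects share the anatomy
and differ in noise and QA jitter), or subject motion. Passing tests
therefore validate the map-level corrections and bookkeeping, not the
upstream spectroscopy.

The macromolecular baseline generator sums nine Gaussians at 0.94, 1.29,
1.42, 1.79, 2.04, 2.31, 2.75, 3.02 and 3.25 ppm with the customary
amplitude groupings (MM12_14, MM17_20, MM30_32 share one scale each).
Linewidths (default 0.09 ppm FWHM) and relative amplitudes are free
parameters with documented defaults chosen so all nine components remain
resolvable as local maxima.

## Problem sizes and numerical choices

The full-scale phantom (220 × 220 × 20 slab, 44 × 44 × 2 native grid)
runs each pipeline stage in seconds; unit tests use a proportionally
scaled 60 × 60 × 10 slab. Recovery checks use 100 seeded replicates of
500-voxel regressions at σ = 0.05. Key tolerances: PSF kernel
normalization 1e−9; redistribution conservation 1e−12 per voxel;
round-trip recovery 1e−6; fraction-sum closure 1e−6 after convolution.
Block pooling uses sequential single-axis means so replicated blocks
pool back bit-exactly. Nearest-lookup ties at cell boundaries go to the
lower index (half-open cells). Seeds derive from a single SeedSequence
per study, spawned per consumer (native noise, QA jitter).

## Known limitations

- No absolute (water-referenced) quantification; ratios over tCr only.
- No B1/flip-angle correction; the steady-state factor assumes the
  nominal flip angle everywhere.
- One global pure-tissue pair per metabolite per subject; regional
  regression is out of scope.
- Transforms are inputs; the package never estimates registrations.
- The default T1 table is an approximate placeholder, to be replaced
  with study-specific literature values.
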