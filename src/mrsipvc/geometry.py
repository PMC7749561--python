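"""Acquisition geometry and point-spread-function modelling.

The in-plane spatial response of a phase-encoded MRSI acquisition is set by
the sampled k-space region. Truncating k-space to a 44 x 44 matrix (and to
the inscribed ellipse under an elliptical shutter) spreads each voxel's
signal into its neighbours ("voxel bleeding"). Reconstruction additionally
applies a Gaussian target spatial-response apodization when down-sampling
the overdiscretized grid back to the acquired matrix. The composite response
is modelled here as the magnitude of the inverse DFT of

    shutter(k) * gaussian_apodization(k)

zero-padded to the 1 mm anatomical grid. Through-slice response is treated
as an ideal slice-thickness boxcar, so the PSF is strictly 2-D in-plane.

Tissue segmentations are convolved with this PSF before partial-volume
correction so that the tissue fractions seen by the model match the blurred
composition the spectroscopic voxel actually samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .errors import (
    DoubleAdjustmentError,
    InvalidGeometryError,
    NoPeakError,
    ShapeError,
)
from .maps import MetaboliteMap

GAUSSIAN_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: Default FWHM (mm) of the Gaussian target spatial response applied during
#: reconstruction down-sampling: 1.5x the nominal in-plane voxel size, a
#: standard widening factor for Gaussian response functions. Together with
#: the elliptical shutter this yields a composite PSF of 8.75 mm FWHM.
DEFAULT_RESPONSE_FWHM_MM = 7.5


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of the FID-MRSI acquisition and its anatomical slab.

    Defaults follow a 7 T FID-MRSI protocol: 220 x 220 mm field of view,
    44 x 44 acquisition matrix (5 x 5 mm in-plane voxels), two adjacent
    10 mm slices, 4x overdiscretized reconstruction, elliptical k-space
    shutter, and a 1 mm isotropic anatomical grid covering the slab.
    """

    fov_mm: tuple[float, float] = (220.0, 220.0)
    acq_matrix: tuple[int, int] = (44, 44)
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 10.0)
    n_slices: int = 2
    overdiscretization_factor: int = 4
    shutter: str = "elliptical"
    anat_res_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.acq_matrix) <= 0:
            raise InvalidGeometryError(f"non-positive matrix {self.acq_matrix}")
        if self.overdiscretization_factor < 1:
            raise InvalidGeometryError("overdiscretization_factor must be >= 1")
        if self.shutter not in ("elliptical", "full"):
            raise InvalidGeometryError(f"unknown shutter {self.shutter!r}")
        for ax in (0, 1):
            expected = self.acq_matrix[ax] * self.voxel_size_mm[ax]
            if abs(self.fov_mm[ax] - expected) > 1e-6:
                raise InvalidGeometryError(
                    f"FOV {self.fov_mm[ax]} mm != matrix x voxel "
                    f"{expected} mm on axis {ax}"
                )
        for ax in (0, 1, 2):
            ratio = self.voxel_size_mm[ax] / self.anat_res_mm
            if abs(ratio - round(ratio)) > 1e-9:
                raise InvalidGeometryError(
                    f"anat_res {self.anat_res_mm} mm does not divide voxel "
                    f"size {self.voxel_size_mm[ax]} mm on axis {ax}"
                )

    @property
    def cells_per_voxel(self) -> tuple[int, int, int]:
        """1 mm-grid cells per native voxel along each axis (e.g. 5, 5, 10)."""
        return tuple(int(round(v / self.anat_res_mm)) for v in self.voxel_size_mm)

    @property
    def anat_inplane_shape(self) -> tuple[int, int]:
        return tuple(int(round(f / self.anat_res_mm)) for f in self.fov_mm)

    @property
    def slab_shape(self) -> tuple[int, int, int]:
        """Anatomical-grid shape of the slab, e.g. (220, 220, 20)."""
        nx, ny = self.anat_inplane_shape
        nz = self.n_slices * self.cells_per_voxel[2]
        return (nx, ny, nz)

    @property
    def native_shape(self) -> tuple[int, int, int]:
        return (self.acq_matrix[0], self.acq_matrix[1], self.n_slices)


@dataclass(frozen=True)
class KSpaceShutter:
    """Binary k-space sampling mask on the acquisition matrix."""

    mask: np.ndarray

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PointSpreadFunction:
    """Normalized in-plane PSF kernel on the anatomical grid.

    ``kernel`` is non-negative, sums to one and is point-symmetric about its
    peak; ``fwhm_mm`` is the measured full width at half maximum and
    ``response_fwhm_mm`` the FWHM of the Gaussian target spatial response
    folded into it (0 means no apodization).
    """

    kernel: np.ndarray
    fwhm_mm: float
    response_fwhm_mm: float
    grid_res_mm: float = 1.0

    def __post_init__(self) -> None:
        if abs(float(self.kernel.sum()) - 1.0) > 1e-9:
            raise ShapeError("PSF kernel must sum to 1 within 1e-9")
        if self.fwhm_mm <= 0:
            raise ShapeError("PSF FWHM must be positive")


@dataclass
class TissueFractions:
    """GM/WM/CSF fractional volumes per anatomical-grid cell.

    ``adjusted`` distinguishes raw segmentations from PSF-convolved ones.
    Fractions lie in [0, 1] and sum to at most 1 (cells outside the head
    sum to 0).
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    adjusted: bool = False
    res_mm: float = 1.0

    def __post_init__(self) -> None:
        shapes = {self.gm.shape, self.wm.shape, self.csf.shape}
        if len(shapes) != 1:
            raise ShapeError(f"tissue fields differ in shape: {shapes}")
        for name in ("gm", "wm", "csf"):
            f = getattr(self, name)
            if np.nanmin(f) < -1e-9 or np.nanmax(f) > 1.0 + 1e-9:
                raise ShapeError(f"{name} fraction outside [0, 1]")
        total = self.gm + self.wm + self.csf
        if np.nanmax(total) > 1.0 + 1e-6:
            raise ShapeError("gm + wm + csf exceeds 1")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape

    @property
    def tissue(self) -> np.ndarray:
        """Combined GM + WM fraction (the signal-bearing compartment)."""
        return self.gm + self.wm


def build_elliptical_shutter(geometry: AcquisitionGeometry) -> KSpaceShutter:
    """Binary k-space shutter for the given geometry.

    For the elliptical shutter, sample ``(i, j)`` is acquired iff it lies
    inside the inscribed ellipse ``((i-c_x)/r_x)^2 + ((j-c_y)/r_y)^2 <= 1``
    with the centre at index ``(N/2, M/2)`` (DFT convention for even
    matrices) and radii of half the matrix size. A full shutter samples
    every point.
    """
    nx, ny = geometry.acq_matrix
    if nx < 2 or ny < 2:
        raise InvalidGeometryError("acquisition matrix must be at least 2 x 2")
    if geometry.shutter == "full":
        return KSpaceShutter(np.ones((nx, ny), dtype=bool))
    cx, cy = nx / 2.0, ny / 2.0
    rx, ry = nx / 2.0, ny / 2.0
    i, j = np.indices((nx, ny))
    mask = ((i - cx) / rx) ** 2 + ((j - cy) / ry) ** 2 <= 1.0
    return KSpaceShutter(mask)


def build_psf(
    geometry: AcquisitionGeometry,
    shutter: KSpaceShutter,
    response_fwhm_mm: float = DEFAULT_RESPONSE_FWHM_MM,
) -> PointSpreadFunction:
    """Compose the acquisition PSF on the 1 mm anatomical grid.

    The shutter mask is multiplied by a Gaussian apodization whose spatial
    response has FWHM ``response_fwhm_mm`` (0 disables apodization),
    zero-padded to the anatomical in-plane grid, inverse-Fourier
    transformed, and the magnitude normalized to unit sum.
    """
    if response_fwhm_mm < 0:
        raise InvalidGeometryError("response FWHM must be >= 0")
    nx, ny = geometry.acq_matrix
    if shutter.mask.shape != (nx, ny):
        raise ShapeError(
            f"shutter shape {shutter.mask.shape} != matrix {(nx, ny)}"
        )
    px, py = geometry.anat_inplane_shape
    if px < nx or py < ny:
        raise InvalidGeometryError(
            "anatomical grid is smaller than the acquisition matrix"
        )

    weighted = shutter.mask.astype(float)
    if response_fwhm_mm > 0:
        sigma = response_fwhm_mm / GAUSSIAN_FWHM_PER_SIGMA
        for ax, (n, fov) in enumerate(zip((nx, ny), geometry.fov_mm)):
            k = (np.arange(n) - n / 2.0) / fov  # cycles / mm
            w = np.exp(-2.0 * np.pi**2 * sigma**2 * k**2)
            weighted *= w[:, None] if ax == 0 else w[None, :]

    padded = np.zeros((px, py))
    sx, sy = (px - nx) // 2, (py - ny) // 2
    padded[sx:sx + nx, sy:sy + ny] = weighted
    kernel = np.abs(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(padded))))
    kernel /= kernel.sum()

    psf = PointSpreadFunction(
        kernel=kernel,
        fwhm_mm=1.0,  # placeholder until measured
        response_fwhm_mm=response_fwhm_mm,
        grid_res_mm=geometry.anat_res_mm,
    )
    return replace(psf, fwhm_mm=measure_fwhm(psf))


def measure_fwhm(psf: PointSpreadFunction) -> float:
    """In-plane FWHM of the kernel, averaged over the two axes.

    Walks outward from the peak along each in-plane axis to the first
    half-maximum crossing and interpolates linearly between grid points.
    """
    kernel = psf.kernel
    peak_val = kernel.max()
    if np.ptp(kernel) == 0 or (kernel == peak_val).sum() > 1:
        raise NoPeakError("kernel has no unique maximum")
    px, py = np.unravel_index(int(kernel.argmax()), kernel.shape)

    def axis_width(profile: np.ndarray, p: int) -> float:
        half = profile[p] / 2.0
        # walk left
        i = p
        while i > 0 and profile[i - 1] >= half:
            i -= 1
        if i == 0:
            left = 0.0
        else:
            left = (i - 1) + (half - profile[i - 1]) / (profile[i] - profile[i - 1])
        # walk right
        j = p
        n = len(profile)
        while j < n - 1 and profile[j + 1] >= half:
            j += 1
        if j == n - 1:
            right = float(n - 1)
        else:
            right = j + (profile[j] - half) / (profile[j] - profile[j + 1])
        return right - left

    wx = axis_width(kernel[:, py], px)
    wy = axis_width(kernel[px, :], py)
    return 0.5 * (wx + wy) * psf.grid_res_mm


def _convolve_inplane(field: np.ndarray, kernel: np.ndarray,
                      boundary: str) -> np.ndarray:
    """Convolve each z sub-slice of a 3-D field with a 2-D kernel."""
    out = np.empty_like(field, dtype=float)
    if boundary == "wrap":
        kern_hat = np.fft.fft2(np.fft.ifftshift(_embed(kernel, field.shape[:2])))
        for z in range(field.shape[2]):
            out[:, :, z] = np.real(np.fft.ifft2(np.fft.fft2(field[:, :, z]) * kern_hat))
    elif boundary == "reflect":
        hx, hy = kernel.shape[0] // 2, kernel.shape[1] // 2
        for z in range(field.shape[2]):
            padded = np.pad(field[:, :, z], ((hx, hx), (hy, hy)), mode="reflect")
            conv = fftconvolve(padded, kernel, mode="same")
            out[:, :, z] = conv[hx:hx + field.shape[0], hy:hy + field.shape[1]]
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    return out


def _embed(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Centre-embed a kernel into a (possibly larger) 2-D shape."""
    if kernel.shape == shape:
        return kernel
    if kernel.shape[0] > shape[0] or kernel.shape[1] > shape[1]:
        raise ShapeError("kernel larger than field")
    out = np.zeros(shape)
    sx = (shape[0] - kernel.shape[0]) // 2
    sy = (shape[1] - kernel.shape[1]) // 2
    out[sx:sx + kernel.shape[0], sy:sy + kernel.shape[1]] = kernel
    return out


def convolve_fractions(
    fractions: TissueFractions,
    psf: PointSpreadFunction,
    boundary: str = "reflect",
) -> TissueFractions:
    """PSF-adjust raw tissue segmentations.

    Each tissue field is convolved in-plane (per 1 mm sub-slice) with the
    PSF kernel, mimicking the voxel-bleeding the acquisition imposes on the
    metabolite signal. Reflective boundary handling is the default to avoid
    artificial tissue loss at slab edges; ``"wrap"`` (periodic) is available
    and conserves total volume exactly.
    """
    if fractions.adjusted:
        raise DoubleAdjustmentError("fractions are already PSF-adjusted")
    fields = {}
    for name in ("gm", "wm", "csf"):
        conv = _convolve_inplane(getattr(fractions, name), psf.kernel, boundary)
        if conv.min() < -1e-6 or conv.max() > 1.0 + 1e-6:
            raise ShapeError(
                f"convolution overshoot beyond tolerance on {name}: "
                f"[{conv.min():.3g}, {conv.max():.3g}]"
            )
        fields[name] = np.clip(conv, 0.0, 1.0)
    return TissueFractions(adjusted=True, res_mm=fractions.res_mm, **fields)


def pool_to_native(field: np.ndarray, geometry: AcquisitionGeometry) -> np.ndarray:
    """Block-average a slab-shaped 1 mm field onto the native MRSI grid.

    Models voxel sampling as a boxcar average over each 5 x 5 x 10 mm
    voxel; used both to aggregate PSF-adjusted fractions for the pure-tissue
    regression and by the phantom's forward model, so the two stay
    consistent by construction.
    """
    cx, cy, cz = geometry.cells_per_voxel
    nx, ny, nz = geometry.native_shape
    if field.shape != geometry.slab_shape:
        raise ShapeError(
            f"field shape {field.shape} != slab {geometry.slab_shape}"
        )
    blocks = field.reshape(nx, cx, ny, cy, nz, cz)
    # sequential single-axis means keep replicated blocks bit-exact
    return blocks.mean(axis=5).mean(axis=3).mean(axis=1)


def upsample_native_grid(map_native: MetaboliteMap, factor: int) -> MetaboliteMap:
    """Replicate each native cell into ``factor x factor`` in-plane cells.

    Pure replication: values are unchanged and in-plane mean-pooling by the
    same factor recovers the input exactly.
    """
    if factor < 1:
        raise ShapeError("up-sampling factor must be >= 1")
    if factor == 1:
        return map_native.copy()
    values = np.repeat(np.repeat(map_native.values, factor, axis=0), factor, axis=1)
    vx, vy, vz = map_native.voxel_size_mm
    return map_native.with_values(
        values,
        grid=f"{map_native.grid}_x{factor}",
        voxel_size_mm=(vx / factor, vy / factor, vz),
    )


def mean_pool_inplane(values: np.ndarray, factor: int) -> np.ndarray:
    """Inverse of :func:`upsample_native_grid` for replicated fields."""
    nx, ny, nz = values.shape
    blocks = values.reshape(nx // factor, factor, ny // factor, factor, nz)
    return blocks.mean(axis=3).mean(axis=1)
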