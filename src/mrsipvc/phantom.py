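"""Digital phantoms with known ground truth for pipeline validation.

A phantom is a stack of 2-D geometric structures (WM background, cortical
GM ribbon, CSF ventricles, deep-GM nuclei) extruded through the slab, each
carrying a GM/WM/CSF composition. Edges are antialiased by in-plane
supersampling so boundary cells carry genuine partial fractions — exactly
what partial-volume correction consumes. From the composition and a set of
pure-tissue metabolite levels the forward model produces native-grid MRSI
maps: the 1 mm signal ``f_gm s_gm + f_wm s_wm`` (CSF contributes nothing)
is blurred with the acquisition PSF, boxcar-averaged per voxel, and
Gaussian noise is added on the fitted-map scale. QA maps carry plausible
baseline metrics plus configurable defect zones (an overcrushed low-SNR
cortical rim, a frontal broadened-linewidth zone). Everything is
deterministic given the spec and seed.

The module also synthesizes macromolecular baseline profiles as a sum of
nine Gaussians with grouped amplitudes, for enriching spectral fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .errors import PhantomSpecError
from .geometry import (
    AcquisitionGeometry,
    PointSpreadFunction,
    TissueFractions,
    _convolve_inplane,
    build_elliptical_shutter,
    build_psf,
    convolve_fractions,
    pool_to_native,
)
from .maps import MetaboliteMap
from .qa import QABundle

SUPERSAMPLE = 8  # in-plane antialiasing factor per axis (1/64 coverage steps)


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Structure:
    """One geometric region with a fixed tissue composition.

    ``shape`` is ``"ellipse"`` (params: center, semi_axes), ``"shell"``
    (an elliptical annulus; params: center, semi_axes, thickness) or
    ``"box"`` (params: x0, x1, y0, y1, half-open). Coordinates are in
    1 mm cells; structures are extruded over ``z_range`` (half-open).
    """

    name: str
    shape: str
    composition: dict[str, float]
    params: dict[str, tuple | float]
    z_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        total = sum(self.composition.get(t, 0.0) for t in ("gm", "wm", "csf"))
        if abs(total - 1.0) > 1e-9:
            raise PhantomSpecError(
                f"structure {self.name!r}: composition sums to {total}, not 1"
            )
        if set(self.composition) - {"gm", "wm", "csf"}:
            raise PhantomSpecError(f"structure {self.name!r}: unknown tissue")
        if self.shape not in ("ellipse", "shell", "box"):
            raise PhantomSpecError(f"unknown structure shape {self.shape!r}")

    def inside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Indicator evaluated at continuous in-plane coordinates (mm)."""
        if self.shape == "ellipse":
            cx, cy = self.params["center"]
            a, b = self.params["semi_axes"]
            return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
        if self.shape == "shell":
            cx, cy = self.params["center"]
            a, b = self.params["semi_axes"]
            t = float(self.params["thickness"])
            outer = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
            inner = ((x - cx) / (a - t)) ** 2 + ((y - cy) / (b - t)) ** 2 <= 1.0
            return outer & ~inner
        x0, x1 = self.params["x0"], self.params["x1"]
        y0, y1 = self.params["y0"], self.params["y1"]
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)


@dataclass(frozen=True)
class QADefect:
    """A QA artifact zone overriding metric levels inside its footprint.

    ``region`` is ``"annulus"`` (params in native-voxel units: center,
    semi_axes, width) or ``"box"`` (x0, x1, y0, y1, half-open native voxel
    indices). ``overrides`` maps metric names (``"snr"``, ``"fwhm_ppm"``,
    ``"lip_over_tcr"``) to the value imposed inside the zone.
    """

    name: str
    region: str
    params: dict[str, tuple | float]
    overrides: dict[str, float]

    def mask(self, native_shape: tuple[int, int, int]) -> np.ndarray:
        nx, ny, nz = native_shape
        i, j = np.indices((nx, ny)).astype(float)
        if self.region == "annulus":
            cx, cy = self.params["center"]
            a, b = self.params["semi_axes"]
            w = float(self.params["width"])
            outer = ((i - cx) / a) ** 2 + ((j - cy) / b) ** 2 <= 1.0
            inner = ((i - cx) / (a - w)) ** 2 + ((j - cy) / (b - w)) ** 2 <= 1.0
            inplane = outer & ~inner
        elif self.region == "box":
            inplane = (
                (i >= self.params["x0"]) & (i < self.params["x1"])
                & (j >= self.params["y0"]) & (j < self.params["y1"])
            )
        else:
            raise PhantomSpecError(f"unknown defect region {self.region!r}")
        return np.repeat(inplane[:, :, None], nz, axis=2)


@dataclass(frozen=True)
class QABaseline:
    """Defect-free metric levels and their voxel-to-voxel jitter."""

    snr: float = 20.0
    fwhm_ppm: float = 0.06
    lip_over_tcr: float = 0.5
    snr_jitter: float = 1.5
    fwhm_jitter: float = 0.008
    lip_jitter: float = 0.15
    crlb_scale: float = 400.0  # CRLB %SD = crlb_scale / SNR (monotone link)


@dataclass
class PhantomSpec:
    """Complete description of a synthetic study."""

    slab_shape: tuple[int, int, int] = (220, 220, 20)
    structures: list[Structure] = dataclass_field(default_factory=list)
    pure_values: dict[str, tuple[float, float]] = dataclass_field(
        default_factory=dict
    )  # metabolite -> (s_gm, s_wm)
    noise_sd: float = 0.05
    qa_defects: list[QADefect] = dataclass_field(default_factory=list)
    qa_baseline: QABaseline = dataclass_field(default_factory=QABaseline)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")


def default_phantom_spec(
    seed: int = 0,
    noise_sd: float = 0.05,
    with_defects: bool = True,
    slab_shape: tuple[int, int, int] = (220, 220, 20),
) -> PhantomSpec:
    """The default two-slice slab phantom.

    A WM elliptical 'brain' with a 6 mm cortical GM ribbon at the rim, two
    CSF ventricles flanking the midline, and four deep-GM nuclei adjacent
    to the ventricles — echoing an axial slab through the level of the
    subcortical nuclei. Defects: an overcrushed low-SNR rim at the cortex
    and a frontal zone of broadened linewidth. ``slab_shape`` rescales the
    in-plane layout proportionally for reduced-size studies.
    """
    structures = [
        Structure("brain", "ellipse", {"wm": 1.0},
                  {"center": (110.0, 110.0), "semi_axes": (85.0, 100.0)}),
        Structure("cortex", "shell", {"gm": 1.0},
                  {"center": (110.0, 110.0), "semi_axes": (85.0, 100.0),
                   "thickness": 6.0}),
        Structure("ventricle_left", "ellipse", {"csf": 1.0},
                  {"center": (94.0, 110.0), "semi_axes": (9.0, 26.0)}),
        Structure("ventricle_right", "ellipse", {"csf": 1.0},
                  {"center": (126.0, 110.0), "semi_axes": (9.0, 26.0)}),
        Structure("nucleus_left", "ellipse", {"gm": 1.0},
                  {"center": (64.0, 110.0), "semi_axes": (13.0, 19.0)}),
        Structure("nucleus_right", "ellipse", {"gm": 1.0},
                  {"center": (156.0, 110.0), "semi_axes": (13.0, 19.0)}),
        Structure("thalamus_left", "ellipse", {"gm": 1.0},
                  {"center": (94.0, 146.0), "semi_axes": (12.0, 14.0)}),
        Structure("thalamus_right", "ellipse", {"gm": 1.0},
                  {"center": (126.0, 146.0), "semi_axes": (12.0, 14.0)}),
    ]
    fx = slab_shape[0] / 220.0
    fy = slab_shape[1] / 220.0
    if (fx, fy) != (1.0, 1.0):
        scaled = []
        for s in structures:
            params = dict(s.params)
            params["center"] = (params["center"][0] * fx,
                                params["center"][1] * fy)
            params["semi_axes"] = (params["semi_axes"][0] * fx,
                                   params["semi_axes"][1] * fy)
            if "thickness" in params:
                params["thickness"] = params["thickness"] * 0.5 * (fx + fy)
            scaled.append(
                Structure(s.name, s.shape, s.composition, params, s.z_range)
            )
        structures = scaled
    defects = []
    if with_defects:
        defects = [
            QADefect("overcrushed_rim", "annulus",
                     {"center": (21.5 * fx, 21.5 * fy),
                      "semi_axes": (17.0 * fx, 20.0 * fy),
                      "width": 1.6 * 0.5 * (fx + fy)},
                     {"snr": 1.0}),
            QADefect("frontal_linewidth", "box",
                     {"x0": int(15 * fx), "x1": int(29 * fx),
                      "y0": int(36 * fy), "y1": int(41 * fy)},
                     {"fwhm_ppm": 0.25}),
        ]
    return PhantomSpec(
        slab_shape=slab_shape,
        structures=structures,
        pure_values={"Glu": (1.2, 0.7), "tNAA": (1.6, 1.45),
                     "tCho": (0.22, 0.32)},
        noise_sd=noise_sd,
        qa_defects=defects,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def generate_segmentations(spec: PhantomSpec) -> TissueFractions:
    """Render the structures into raw GM/WM/CSF fraction fields.

    Structures are painted in list order; later structures override
    earlier ones within their (antialiased) coverage, so boundary cells
    carry partial fractions from 4x4 in-plane supersampling.
    """
    nx, ny, nz = spec.slab_shape
    ss = SUPERSAMPLE
    # supersampled in-plane coordinates (mm), cell centres at i + 0.5
    xs = (np.arange(nx * ss) + 0.5) / ss
    ys = (np.arange(ny * ss) + 0.5) / ss
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    gm = np.zeros(spec.slab_shape)
    wm = np.zeros(spec.slab_shape)
    csf = np.zeros(spec.slab_shape)
    for struct in spec.structures:
        inside = struct.inside(X, Y)
        alpha = inside.reshape(nx, ss, ny, ss).mean(axis=(1, 3))
        if alpha.max() == 0:
            raise PhantomSpecError(
                f"structure {struct.name!r} lies outside the slab"
            )
        z0, z1 = struct.z_range if struct.z_range is not None else (0, nz)
        if not (0 <= z0 < z1 <= nz):
            raise PhantomSpecError(
                f"structure {struct.name!r} z-range outside the slab"
            )
        a = alpha[:, :, None]
        comp = struct.composition
        for fld, tissue in ((gm, "gm"), (wm, "wm"), (csf, "csf")):
            fld[:, :, z0:z1] = (
                a * comp.get(tissue, 0.0) + (1.0 - a) * fld[:, :, z0:z1]
            )
    return TissueFractions(gm=gm, wm=wm, csf=csf, adjusted=False)


def tissue_signal(
    fractions: TissueFractions, s_gm: float, s_wm: float
) -> np.ndarray:
    """Composition-weighted metabolite signal; CSF contributes nothing."""
    return fractions.gm * s_gm + fractions.wm * s_wm


def simulate_native_maps(
    truth: dict[str, np.ndarray],
    fractions: TissueFractions,
    geometry: AcquisitionGeometry,
    psf: PointSpreadFunction,
    noise_sd: float,
    seed,
    boundary: str = "reflect",
) -> dict[str, MetaboliteMap]:
    """Forward-model native MRSI maps from 1 mm truth signal fields.

    Each truth field is convolved in-plane with the acquisition PSF,
    boxcar-averaged onto the native grid (the same sampling the correction
    assumes), and perturbed with i.i.d. Gaussian noise on the fitted-map
    scale. Deterministic for a given seed.
    """
    if noise_sd < 0:
        raise PhantomSpecError("noise_sd must be >= 0")
    if fractions.shape != geometry.slab_shape:
        raise PhantomSpecError(
            f"fractions shape {fractions.shape} != slab {geometry.slab_shape}"
        )
    rng = np.random.default_rng(seed)
    out: dict[str, MetaboliteMap] = {}
    for met, signal in truth.items():
        blurred = _convolve_inplane(signal, psf.kernel, boundary)
        native = pool_to_native(blurred, geometry)
        if noise_sd > 0:
            native = native + rng.normal(0.0, noise_sd, native.shape)
        out[met] = MetaboliteMap(
            values=native, metabolite=met, grid="native",
            voxel_size_mm=geometry.voxel_size_mm,
        )
    return out


def simulate_qa(
    spec: PhantomSpec, geometry: AcquisitionGeometry, seed
) -> QABundle:
    """QA metric maps: jittered baseline plus defect-zone overrides.

    CRLB fields are tied to SNR by the monotone link
    ``crlb = crlb_scale / snr`` and therefore inherit SNR defects.
    """
    rng = np.random.default_rng(seed)
    shape = geometry.native_shape
    base = spec.qa_baseline
    snr = base.snr + rng.normal(0.0, base.snr_jitter, shape)
    fwhm = base.fwhm_ppm + rng.normal(0.0, base.fwhm_jitter, shape)
    lip = np.abs(base.lip_over_tcr + rng.normal(0.0, base.lip_jitter, shape))
    snr = np.clip(snr, 0.1, None)
    fwhm = np.clip(fwhm, 1e-3, None)

    for defect in spec.qa_defects:
        zone = defect.mask(shape)
        for metric, value in defect.overrides.items():
            if metric == "snr":
                snr[zone] = value
            elif metric == "fwhm_ppm":
                fwhm[zone] = value
            elif metric == "lip_over_tcr":
                lip[zone] = value
            else:
                raise PhantomSpecError(
                    f"defect {defect.name!r}: unknown metric {metric!r}"
                )

    metabolites = list(spec.pure_values) + ["tCr"]
    crlb = {met: base.crlb_scale / snr for met in metabolites}
    return QABundle(snr=snr, fwhm_ppm=fwhm, crlb=crlb, lip_over_tcr=lip)


@dataclass
class SimulatedStudy:
    """One synthetic subject with full ground truth.

    ``truth_raw`` holds the 1 mm composition signal from the raw
    segmentations; ``truth_psf`` the PSF-consistent signal (adjusted
    fractions), which is the field the partial-volume correction
    reconstructs exactly in the noiseless limit.
    """

    spec: PhantomSpec
    geometry: AcquisitionGeometry
    psf: PointSpreadFunction
    fractions_raw: TissueFractions
    fractions_psf: TissueFractions
    truth_raw: dict[str, np.ndarray]
    truth_psf: dict[str, np.ndarray]
    native: dict[str, MetaboliteMap]
    qa: QABundle
    provenance: dict = dataclass_field(default_factory=dict)


def generate_study(
    spec: PhantomSpec,
    geometry: AcquisitionGeometry | None = None,
    response_fwhm_mm: float | None = None,
    boundary: str = "reflect",
) -> SimulatedStudy:
    """Render a complete synthetic study from a spec.

    Bit-identical for identical spec and seed.
    """
    from .geometry import DEFAULT_RESPONSE_FWHM_MM

    if geometry is None:
        # derive a matching geometry assuming default 5 x 5 x 10 mm voxels
        nx, ny, nz = spec.slab_shape
        geometry = AcquisitionGeometry(
            fov_mm=(float(nx), float(ny)),
            acq_matrix=(nx // 5, ny // 5),
            n_slices=nz // 10,
        )
    if geometry.slab_shape != tuple(spec.slab_shape):
        raise PhantomSpecError(
            f"geometry slab {geometry.slab_shape} != spec slab "
            f"{tuple(spec.slab_shape)}"
        )
    if response_fwhm_mm is None:
        response_fwhm_mm = DEFAULT_RESPONSE_FWHM_MM

    fractions_raw = generate_segmentations(spec)
    shutter = build_elliptical_shutter(geometry)
    psf = build_psf(geometry, shutter, response_fwhm_mm)
    fractions_psf = convolve_fractions(fractions_raw, psf, boundary=boundary)

    truth_raw = {
        met: tissue_signal(fractions_raw, s_gm, s_wm)
        for met, (s_gm, s_wm) in spec.pure_values.items()
    }
    truth_psf = {
        met: tissue_signal(fractions_psf, s_gm, s_wm)
        for met, (s_gm, s_wm) in spec.pure_values.items()
    }

    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    native = simulate_native_maps(
        truth_raw, fractions_raw, geometry, psf, spec.noise_sd,
        np.random.default_rng(seeds[0]), boundary=boundary,
    )
    qa = simulate_qa(spec, geometry, np.random.default_rng(seeds[1]))

    provenance = {
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "n_structures": len(spec.structures),
        "metabolites": list(spec.pure_values),
        "psf_fwhm_mm": psf.fwhm_mm,
        "response_fwhm_mm": response_fwhm_mm,
        "boundary": boundary,
    }
    return SimulatedStudy(
        spec=spec, geometry=geometry, psf=psf,
        fractions_raw=fractions_raw, fractions_psf=fractions_psf,
        truth_raw=truth_raw, truth_psf=truth_psf,
        native=native, qa=qa, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Macromolecular baseline synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMComponent:
    """One Gaussian macromolecular resonance.

    Components sharing a ``group`` keep a fixed amplitude ratio: only the
    group's common scale may vary.
    """

    name: str
    center_ppm: float
    linewidth_ppm: float  # FWHM
    amplitude: float
    group: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_ppm <= 4.3:
            raise PhantomSpecError(
                f"MM component {self.name!r}: centre outside 0-4.3 ppm"
            )
        if self.linewidth_ppm <= 0:
            raise PhantomSpecError(
                f"MM component {self.name!r}: non-positive linewidth"
            )


def default_mm_components() -> list[MMComponent]:
    """Nine components at the standard chemical shifts.

    Centres follow the conventional MM nomenclature (MM09 at 0.94 ppm
    through MM32 at 3.25 ppm) with the customary groupings MM12_14,
    MM17_20 and MM30_32. Linewidths and relative amplitudes are free
    parameters with plausible documented defaults.
    """
    lw = 0.09
    return [
        MMComponent("MM09", 0.94, lw, 1.00, "MM09"),
        MMComponent("MM12", 1.29, lw, 0.80, "MM12_14"),
        MMComponent("MM14", 1.42, lw, 0.65, "MM12_14"),
        MMComponent("MM17", 1.79, lw, 0.55, "MM17_20"),
        MMComponent("MM20", 2.04, lw, 0.90, "MM17_20"),
        MMComponent("MM23", 2.31, lw, 0.60, "MM23"),
        MMComponent("MM27", 2.75, lw, 0.25, "MM27"),
        MMComponent("MM30", 3.02, lw, 0.45, "MM30_32"),
        MMComponent("MM32", 3.25, lw, 0.35, "MM30_32"),
    ]


def synthesize_mm_profile(
    components: list[MMComponent],
    axis: np.ndarray,
    group_scales: dict[str, float] | None = None,
    global_amplitude: float = 1.0,
) -> np.ndarray:
    """Sum-of-Gaussians macromolecular baseline on a ppm axis.

    ``group_scales`` multiplies entire amplitude groups by a shared factor
    (the grouping constraint); the ``global_amplitude`` scales the whole
    profile linearly. Components centred outside the axis raise a warning
    and still contribute their tails.
    """
    axis = np.asarray(axis, dtype=float)
    group_scales = group_scales or {}
    spectrum = np.zeros_like(axis)
    sigma_factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    for comp in components:
        if not axis.min() <= comp.center_ppm <= axis.max():
            warnings.warn(
                f"MM component {comp.name!r} at {comp.center_ppm} ppm lies "
                "outside the spectral axis",
                stacklevel=2,
            )
        sigma = comp.linewidth_ppm / sigma_factor
        scale = group_scales.get(comp.group, 1.0)
        spectrum += (
            scale * comp.amplitude
            * np.exp(-((axis - comp.center_ppm) ** 2) / (2.0 * sigma**2))
        )
    return global_amplitude * spectrum
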