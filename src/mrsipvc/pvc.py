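"""PSF-adjusted gray/white-matter partial-volume correction.

Model
-----
A spectroscopic voxel's metabolite ratio is treated as a weighted sum of
pure-tissue contributions, with CSF contributing no metabolite signal:

    M(v) = f_gm(v) * S_gm + f_wm(v) * S_wm

where the fractions are PSF-adjusted (segmentations convolved with the
acquisition PSF, then boxcar-averaged over the voxel). Dividing by the
tissue fraction ``f_gm + f_wm`` and writing ``g = f_gm / (f_gm + f_wm)``
(the normalized GM fraction) gives a line in ``g``:

    M / (f_gm + f_wm) = S_wm + (S_gm - S_wm) * g

so ordinary least squares over QA-surviving voxels, extrapolated to
``g = 1`` and ``g = 0``, yields the pure-GM and pure-WM levels. Each
voxel's measured value is then redistributed over its 1 mm cells in
proportion to the locally predicted signal ``p(r) = f_gm(r) S_gm +
f_wm(r) S_wm``, scaled so the voxel mean is conserved exactly, and finally
corrected for steady-state T1 saturation with tissue-specific T1 values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, MissingT1Error, ShapeError
from .geometry import AcquisitionGeometry, TissueFractions, pool_to_native
from .maps import MISSING, MetaboliteMap
from .qa import TCR, QAMask, apply_mask


@dataclass(frozen=True)
class PureTissueEstimate:
    """Pure-tissue metabolite levels from the normalized-GM-fraction fit.

    ``s_wm`` is the regression intercept (value at g = 0) and ``s_gm`` the
    extrapolation to g = 1 (intercept + slope). Standard errors are the
    usual OLS ones.
    """

    s_gm: float
    s_wm: float
    slope: float
    intercept: float
    n_voxels: int
    r2: float
    se_s_gm: float = float("nan")
    se_s_wm: float = float("nan")


@dataclass(frozen=True)
class SequenceParams:
    """Excitation parameters governing steady-state saturation."""

    flip_angle_deg: float = 35.0
    tr_ms: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_angle_deg <= 90.0:
            raise ValueError("flip angle must be in (0, 90] degrees")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")


@dataclass
class T1Table:
    """Per-(metabolite, tissue) longitudinal relaxation times in ms."""

    entries: dict[tuple[str, str], float]
    source: str = "user"

    def __post_init__(self) -> None:
        for key, t1 in self.entries.items():
            if t1 <= 0:
                raise ValueError(f"non-positive T1 for {key}")

    def t1_ms(self, metabolite: str, tissue: str) -> float:
        try:
            return self.entries[(metabolite, tissue)]
        except KeyError:
            raise MissingT1Error(metabolite, tissue) from None


def default_t1_table() -> T1Table:
    """Editable defaults, transcribed approximately from 7 T GM/WM reports.

    These are placeholders at the right order of magnitude for 7 T; studies
    should substitute their preferred literature values via the config.
    """
    ms = {
        ("tCr", "GM"): 1550.0, ("tCr", "WM"): 1400.0,
        ("tNAA", "GM"): 1730.0, ("tNAA", "WM"): 1630.0,
        ("Glu", "GM"): 1660.0, ("Glu", "WM"): 1580.0,
        ("Glx", "GM"): 1660.0, ("Glx", "WM"): 1580.0,
        ("tCho", "GM"): 1270.0, ("tCho", "WM"): 1180.0,
        ("mI", "GM"): 1160.0, ("mI", "WM"): 1010.0,
        ("GSH", "GM"): 1320.0, ("GSH", "WM"): 1250.0,
    }
    return T1Table(entries=ms, source="approximate 7 T GM/WM literature values")


def neutral_t1_table(metabolites: list[str],
                     t1_gm_ms: float = 1500.0,
                     t1_wm_ms: float = 1400.0) -> T1Table:
    """Table in which every metabolite shares tCr's T1s (factor exactly 1)."""
    entries: dict[tuple[str, str], float] = {
        (TCR, "GM"): t1_gm_ms, (TCR, "WM"): t1_wm_ms,
    }
    for met in metabolites:
        entries[(met, "GM")] = t1_gm_ms
        entries[(met, "WM")] = t1_wm_ms
    return T1Table(entries=entries, source="neutral (metabolite T1 = tCr T1)")


def normalized_gm_fraction(f_gm, f_wm):
    """g = f_gm / (f_gm + f_wm); NaN where the voxel holds no GM or WM.

    Accepts scalars or arrays. Voxels with ``f_gm + f_wm = 0`` have no
    defined tissue composition and are excluded from the regression by the
    NaN marker.
    """
    f_gm = np.asarray(f_gm, dtype=float)
    f_wm = np.asarray(f_wm, dtype=float)
    if np.any(f_gm < 0) or np.any(f_wm < 0):
        raise ValueError("tissue fractions must be non-negative")
    total = f_gm + f_wm
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(total > 0, f_gm / np.where(total > 0, total, 1.0), MISSING)
    return float(g) if g.ndim == 0 else g


def aggregate_fractions(
    fractions: TissueFractions, geometry: AcquisitionGeometry
) -> TissueFractions:
    """Boxcar-average PSF-adjusted 1 mm fractions onto the native grid."""
    if not fractions.adjusted:
        raise ShapeError("aggregate PSF-adjusted fractions, not raw ones")
    return TissueFractions(
        gm=pool_to_native(fractions.gm, geometry),
        wm=pool_to_native(fractions.wm, geometry),
        csf=pool_to_native(fractions.csf, geometry),
        adjusted=True,
        res_mm=fractions.res_mm,
    )


def fit_pure_tissue(
    metabolite_map: MetaboliteMap,
    fractions: TissueFractions,
    mask: QAMask | None = None,
    min_tissue: float = 0.5,
    min_voxels: int = 10,
    weighted: bool = False,
) -> PureTissueEstimate:
    """Estimate pure-GM/WM levels by OLS against the normalized GM fraction.

    ``fractions`` must be PSF-adjusted and on the map's grid. Voxels are
    included when they survive QA, carry a value, and have a combined
    GM + WM fraction of at least ``min_tissue`` (CSF-dominated voxels have
    unstable tissue-normalized values). ``weighted=True`` weights the fit
    by the tissue fraction.
    """
    if not fractions.adjusted:
        raise ShapeError("regression requires PSF-adjusted fractions")
    if fractions.shape != metabolite_map.shape:
        raise ShapeError(
            f"fractions shape {fractions.shape} != map {metabolite_map.shape}"
        )
    values = metabolite_map.values
    keep = ~np.isnan(values)
    if mask is not None:
        if mask.keep.shape != metabolite_map.shape:
            raise ShapeError("QA mask grid does not match map grid")
        keep &= mask.keep
    tissue = fractions.tissue
    keep &= tissue >= min_tissue

    n = int(keep.sum())
    if n < max(min_voxels, 2):
        raise InsufficientDataError(
            f"only {n} voxels available for the pure-tissue fit "
            f"(minimum {max(min_voxels, 2)})"
        )

    y = values[keep] / tissue[keep]
    g = fractions.gm[keep] / tissue[keep]
    if np.ptp(g) == 0:
        raise InsufficientDataError(
            "no variation in normalized GM fraction; pure-tissue levels are "
            "not identifiable"
        )

    w = tissue[keep] if weighted else np.ones_like(y)
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    intercept, slope = float(beta[0]), float(beta[1])

    resid = y - (intercept + slope * g)
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    se_int = se_gm = float("nan")
    if n > 2:
        sigma2 = ss_res / (n - 2)
        xtx_inv = np.linalg.inv((X * w[:, None]).T @ X)
        cov = sigma2 * xtx_inv
        se_int = float(np.sqrt(cov[0, 0]))
        # var(intercept + slope) = var(a) + var(b) + 2 cov(a, b)
        se_gm = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]))

    s_wm = intercept
    s_gm = intercept + slope
    if s_wm < 0 or s_gm < 0:
        warnings.warn(
            f"negative extrapolated pure-tissue value for "
            f"{metabolite_map.metabolite}: s_gm={s_gm:.4g}, s_wm={s_wm:.4g} "
            "(retained, not clipped)",
            stacklevel=2,
        )
    return PureTissueEstimate(
        s_gm=s_gm, s_wm=s_wm, slope=slope, intercept=intercept,
        n_voxels=n, r2=r2, se_s_gm=se_gm, se_s_wm=se_int,
    )


def redistribute_voxel(
    measured: float,
    cell_fractions: TissueFractions,
    est: PureTissueEstimate,
) -> np.ndarray:
    """Redistribute one voxel's value over its 1 mm cells.

    Cells receive ``measured * p(r) / mean(p)`` with
    ``p(r) = f_gm(r) s_gm + f_wm(r) s_wm``, so the voxel mean equals the
    measured value exactly and pure-CSF cells receive zero. A voxel whose
    predicted signal vanishes everywhere (entirely CSF) yields all-missing
    cells.
    """
    p = cell_fractions.gm * est.s_gm + cell_fractions.wm * est.s_wm
    mean_p = p.mean()
    if mean_p == 0:
        return np.full(p.shape, MISSING)
    return measured * (p / mean_p)


def t1_correction_factor(
    metabolite: str,
    tissue: str,
    t1s: T1Table,
    seq: SequenceParams,
) -> float:
    """Steady-state saturation correction for a ratio-over-tCr map.

    The steady-state transverse signal of a spoiled acquisition at flip
    angle alpha and repetition time TR is proportional to

        E(T1) = sin(a) (1 - exp(-TR/T1)) / (1 - cos(a) exp(-TR/T1)).

    Both numerator and denominator of a ratio map are attenuated, so the
    multiplicative correction is ``E(T1_tCr) / E(T1_met)`` for the given
    tissue. Monotone increasing in the metabolite T1.
    """
    def saturation(t1_ms: float) -> float:
        a = np.radians(seq.flip_angle_deg)
        e = np.exp(-seq.tr_ms / t1_ms)
        return float(np.sin(a) * (1.0 - e) / (1.0 - np.cos(a) * e))

    return saturation(t1s.t1_ms(TCR, tissue)) / saturation(
        t1s.t1_ms(metabolite, tissue)
    )


@dataclass
class PvcResult:
    """Corrected 1 mm map plus a provenance report of the run."""

    corrected: MetaboliteMap
    estimate: PureTissueEstimate
    report: dict = field(default_factory=dict)


def run_pvc(
    metabolite_map: MetaboliteMap,
    fractions: TissueFractions,
    geometry: AcquisitionGeometry,
    mask: QAMask | None = None,
    t1s: T1Table | None = None,
    seq: SequenceParams | None = None,
    min_tissue: float = 0.5,
    min_voxels: int = 10,
    weighted: bool = False,
) -> PvcResult:
    """Full partial-volume correction of one native metabolite map.

    Stages: QA masking, pure-tissue regression on native-grid aggregated
    fractions, within-voxel redistribution onto the 1 mm grid, and
    steady-state T1 correction with the per-cell tissue-mixed factor
    ``(f_gm F_GM + f_wm F_WM) / (f_gm + f_wm)``. ``fractions`` are the
    PSF-adjusted 1 mm fields; pass ``t1s=None`` to skip T1 correction.
    """
    if not fractions.adjusted:
        raise ShapeError("run_pvc requires PSF-adjusted fractions")
    if fractions.shape != geometry.slab_shape:
        raise ShapeError(
            f"fractions shape {fractions.shape} != slab {geometry.slab_shape}"
        )
    if metabolite_map.shape != geometry.native_shape:
        raise ShapeError(
            f"map shape {metabolite_map.shape} != native "
            f"{geometry.native_shape}"
        )

    masked = apply_mask(metabolite_map, mask) if mask is not None else metabolite_map
    if np.all(np.isnan(masked.values)):
        empty = MetaboliteMap(
            values=np.full(geometry.slab_shape, MISSING),
            metabolite=masked.metabolite,
            grid="anat",
            voxel_size_mm=(geometry.anat_res_mm,) * 3,
        )
        report = {
            "metabolite": masked.metabolite,
            "estimate": None,
            "settings": {"min_tissue": min_tissue, "min_voxels": min_voxels},
            "counts": {"voxels_with_value": 0, "cells_output": 0},
        }
        est = PureTissueEstimate(
            s_gm=float("nan"), s_wm=float("nan"), slope=float("nan"),
            intercept=float("nan"), n_voxels=0, r2=float("nan"),
        )
        return PvcResult(corrected=empty, estimate=est, report=report)
    native_fracs = aggregate_fractions(fractions, geometry)
    est = fit_pure_tissue(
        masked, native_fracs, mask=None, min_tissue=min_tissue,
        min_voxels=min_voxels, weighted=weighted,
    )

    # Vectorized redistribution: per-cell predicted signal, per-voxel mean.
    p = fractions.gm * est.s_gm + fractions.wm * est.s_wm
    mean_p = pool_to_native(p, geometry)
    cx, cy, cz = geometry.cells_per_voxel

    def up(native_field: np.ndarray) -> np.ndarray:
        return np.repeat(
            np.repeat(np.repeat(native_field, cx, axis=0), cy, axis=1),
            cz, axis=2,
        )

    up_measured = up(masked.values)
    up_mean_p = up(mean_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = up_measured * (p / up_mean_p)
    corrected[up_mean_p == 0] = MISSING

    n_all_csf = int(np.sum((mean_p == 0) & ~np.isnan(masked.values)))

    if t1s is not None:
        seq = seq or SequenceParams()
        f_gm_factor = t1_correction_factor(masked.metabolite, "GM", t1s, seq)
        f_wm_factor = t1_correction_factor(masked.metabolite, "WM", t1s, seq)
        tissue = fractions.tissue
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = np.where(
                tissue > 0,
                (fractions.gm * f_gm_factor + fractions.wm * f_wm_factor)
                / np.where(tissue > 0, tissue, 1.0),
                1.0,
            )
        corrected = corrected * eff

    corrected_map = MetaboliteMap(
        values=corrected,
        metabolite=masked.metabolite,
        grid="anat",
        voxel_size_mm=(geometry.anat_res_mm,) * 3,
    )
    report = {
        "metabolite": masked.metabolite,
        "estimate": {
            "s_gm": est.s_gm, "s_wm": est.s_wm,
            "slope": est.slope, "intercept": est.intercept,
            "r2": est.r2, "n_voxels": est.n_voxels,
        },
        "settings": {
            "min_tissue": min_tissue, "min_voxels": min_voxels,
            "weighted": weighted,
            "t1_correction": t1s is not None,
            "t1_source": t1s.source if t1s is not None else None,
        },
        "counts": {
            "native_voxels": int(np.prod(geometry.native_shape)),
            "voxels_with_value": int(np.sum(~np.isnan(masked.values))),
            "voxels_in_fit": est.n_voxels,
            "voxels_all_csf": n_all_csf,
            "cells_output": int(np.sum(~np.isnan(corrected))),
        },
    }
    return PvcResult(corrected=corrected_map, estimate=est, report=report)
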