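"""Spectral quality-assurance filtering of metabolite maps.

Voxel-wise fit-quality metrics (SNR, linewidth, Cramér–Rao lower bounds,
lipid contamination) are thresholded into binary keep/discard masks. A
voxel is kept only if SNR > 3, FWHM < 0.15 ppm, Lip13ab/tCr < 2 and the
metabolite's CRLB < 50 %SD; thresholds are configurable. Because metabolite
maps are ratios over total creatine, a voxel whose tCr CRLB exceeds the
threshold is additionally removed from every metabolite's mask.

Comparisons are strict, so a voxel sitting exactly at a threshold is
discarded. CRLB values are relative (%SD); absolute-CRLB filtering is not
performed here (the metric fields are whatever the spectral-fitting stage
produced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingReferenceError, ShapeError, UnknownMetaboliteError
from .maps import MISSING, MetaboliteMap

#: Internal-reference metabolite whose CRLB failure poisons all ratio maps.
TCR = "tCr"


@dataclass
class QABundle:
    """Per-voxel QA metric fields on the native MRSI grid."""

    snr: np.ndarray
    fwhm_ppm: np.ndarray
    crlb: dict[str, np.ndarray]
    lip_over_tcr: np.ndarray

    def __post_init__(self) -> None:
        shape = self.snr.shape
        fields = {"fwhm_ppm": self.fwhm_ppm, "lip_over_tcr": self.lip_over_tcr}
        fields.update({f"crlb[{m}]": f for m, f in self.crlb.items()})
        for name, f in fields.items():
            if f.shape != shape:
                raise ShapeError(f"QA field {name} shape {f.shape} != {shape}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.snr.shape

    @property
    def metabolites(self) -> list[str]:
        return list(self.crlb)


@dataclass(frozen=True)
class QAThresholds:
    """Keep-criteria thresholds; defaults follow the standard protocol."""

    snr_min: float = 3.0
    fwhm_max: float = 0.15  # ppm
    lip_tcr_max: float = 2.0
    crlb_max: float = 50.0  # %SD

    def __post_init__(self) -> None:
        for name in ("snr_min", "fwhm_max", "lip_tcr_max", "crlb_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")


@dataclass
class QAMask:
    """Binary keep mask for one metabolite with per-criterion provenance.

    ``provenance`` maps criterion names (``"snr"``, ``"fwhm"``, ``"lipid"``,
    ``"crlb"``, ``"crlb_tcr"``) to boolean fields that are True where that
    criterion failed; every discarded voxel fails at least one recorded
    criterion.
    """

    keep: np.ndarray
    metabolite: str
    provenance: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        failed_any = np.zeros_like(self.keep)
        for fail in self.provenance.values():
            failed_any |= fail
        if np.any(~self.keep & ~failed_any):
            raise ShapeError("discarded voxel without recorded failing criterion")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def failing_criteria(self, index: tuple[int, ...]) -> list[str]:
        """Names of the criteria that discarded the voxel at ``index``."""
        return [name for name, fail in self.provenance.items() if fail[index]]


def build_qa_mask(
    qa: QABundle, thresholds: QAThresholds, metabolite: str
) -> QAMask:
    """Binary keep mask for one metabolite.

    A voxel is kept iff ``snr > snr_min`` and ``fwhm < fwhm_max`` and
    ``lip/tCr < lip_tcr_max`` and ``crlb[metabolite] < crlb_max`` (all
    strict; boundary values are discarded).
    """
    if metabolite not in qa.crlb:
        raise UnknownMetaboliteError(
            f"no CRLB field for metabolite {metabolite!r}"
        )
    provenance = {
        "snr": ~(qa.snr > thresholds.snr_min),
        "fwhm": ~(qa.fwhm_ppm < thresholds.fwhm_max),
        "lipid": ~(qa.lip_over_tcr < thresholds.lip_tcr_max),
        "crlb": ~(qa.crlb[metabolite] < thresholds.crlb_max),
    }
    keep = np.ones(qa.shape, dtype=bool)
    for fail in provenance.values():
        keep &= ~fail
    return QAMask(keep=keep, metabolite=metabolite, provenance=provenance)


def propagate_tcr_filter(
    masks: dict[str, QAMask], qa: QABundle, thresholds: QAThresholds
) -> dict[str, QAMask]:
    """Remove voxels with failing tCr CRLB from every metabolite mask.

    All maps are ratios over tCr, so an unreliable tCr fit invalidates them
    all: each mask's keep set is intersected with
    ``{crlb[tCr] <= crlb_max}``. Idempotent.
    """
    if TCR not in qa.crlb:
        raise MissingReferenceError("QA bundle has no tCr CRLB field")
    tcr_fail = qa.crlb[TCR] > thresholds.crlb_max
    out: dict[str, QAMask] = {}
    for name, mask in masks.items():
        provenance = dict(mask.provenance)
        provenance["crlb_tcr"] = tcr_fail
        out[name] = QAMask(
            keep=mask.keep & ~tcr_fail,
            metabolite=mask.metabolite,
            provenance=provenance,
        )
    return out


def apply_mask(metabolite_map: MetaboliteMap, mask: QAMask) -> MetaboliteMap:
    """Set discarded voxels to missing; kept voxels pass through unchanged."""
    if mask.keep.shape != metabolite_map.shape:
        raise ShapeError(
            f"mask shape {mask.keep.shape} != map shape {metabolite_map.shape}"
        )
    values = metabolite_map.values.copy()
    values[~mask.keep] = MISSING
    return metabolite_map.with_values(values)
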