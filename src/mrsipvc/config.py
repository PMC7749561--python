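"""Structured pipeline configuration with strict validation.

The pipeline is driven by one mapping (typically a YAML file) with four
blocks — ``geometry``, ``thresholds``, ``pvc`` and ``normalization`` —
whose defaults reproduce the standard 7 T FID-MRSI protocol: 44 x 44
matrix over a 220 x 220 mm FOV, 5 x 5 x 10 mm voxels, SNR > 3,
FWHM < 0.15 ppm, Lip/tCr < 2, CRLB < 50 %SD, minimum data density 3,
35 degree flip angle and TR 300 ms. Unknown keys are rejected: with this
many interacting thresholds, a silently ignored typo is the main failure
mode.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .geometry import DEFAULT_RESPONSE_FWHM_MM, AcquisitionGeometry
from .pvc import SequenceParams, T1Table, default_t1_table
from .qa import QAThresholds


@dataclass
class GeometryConfig:
    fov_mm: tuple[float, float] = (220.0, 220.0)
    acq_matrix: tuple[int, int] = (44, 44)
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 10.0)
    n_slices: int = 2
    overdiscretization_factor: int = 4
    shutter: str = "elliptical"
    anat_res_mm: float = 1.0
    response_fwhm_mm: float = DEFAULT_RESPONSE_FWHM_MM
    boundary: str = "reflect"

    def build(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            fov_mm=tuple(self.fov_mm),
            acq_matrix=tuple(self.acq_matrix),
            voxel_size_mm=tuple(self.voxel_size_mm),
            n_slices=self.n_slices,
            overdiscretization_factor=self.overdiscretization_factor,
            shutter=self.shutter,
            anat_res_mm=self.anat_res_mm,
        )


@dataclass
class ThresholdConfig:
    snr_min: float = 3.0
    fwhm_max: float = 0.15
    lip_tcr_max: float = 2.0
    crlb_max: float = 50.0

    def build(self) -> QAThresholds:
        if self.crlb_max < 1.0:
            warnings.warn(
                f"crlb_max = {self.crlb_max}: CRLB thresholds are %SD "
                "(e.g. 50), not fractions — check the unit scale",
                stacklevel=2,
            )
        return QAThresholds(
            snr_min=self.snr_min, fwhm_max=self.fwhm_max,
            lip_tcr_max=self.lip_tcr_max, crlb_max=self.crlb_max,
        )


@dataclass
class PvcConfig:
    min_tissue: float = 0.5
    min_voxels: int = 10
    weighted: bool = False
    flip_angle_deg: float = 35.0
    tr_ms: float = 300.0
    t1_correction: bool = True
    t1_table: dict | None = None  # {"Glu": {"GM": 1660, "WM": 1580}, ...}

    def build_sequence(self) -> SequenceParams:
        return SequenceParams(flip_angle_deg=self.flip_angle_deg,
                              tr_ms=self.tr_ms)

    def build_t1_table(self) -> T1Table | None:
        if not self.t1_correction:
            return None
        if self.t1_table is None:
            return default_t1_table()
        entries = {
            (met, tissue): float(t1)
            for met, tissues in self.t1_table.items()
            for tissue, t1 in tissues.items()
        }
        return T1Table(entries=entries, source="config")


@dataclass
class NormalizationConfig:
    min_density: int = 3
    interpolation: str = "trilinear"
    reference_shape: tuple[int, int, int] | None = None  # None: slab grid


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    pvc: PvcConfig = field(default_factory=PvcConfig)
    normalization: NormalizationConfig = field(
        default_factory=NormalizationConfig
    )
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCKS = {
    "geometry": GeometryConfig,
    "thresholds": ThresholdConfig,
    "pvc": PvcConfig,
    "normalization": NormalizationConfig,
}


def _build_block(cls, data: dict, block: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in config block {block!r}"
        )
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    unknown = set(data) - set(_BLOCKS) - {"paths"}
    if unknown:
        raise ValidationError(f"unknown top-level config key(s) {sorted(unknown)}")
    blocks = {
        name: _build_block(cls, data.get(name, {}) or {}, name)
        for name, cls in _BLOCKS.items()
    }
    cfg = PipelineConfig(paths=dict(data.get("paths", {}) or {}), **blocks)
    # trigger unit-scale guards eagerly so a bad file fails at load time
    cfg.thresholds.build()
    return cfg


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{Path(path).name}: config must be a mapping")
    return config_from_dict(data)
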