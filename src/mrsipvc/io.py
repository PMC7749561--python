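"""Volume, table, transform and provenance I/O.

Volumes are NIfTI-1 with float64 payload (quiet NaN marks missing voxels);
affines follow the nibabel convention. Fitted metabolite values and QA
metrics can also enter as a long-format CSV with one row per
(voxel, metabolite).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .geometry import AcquisitionGeometry
from .maps import MISSING, MetaboliteMap
from .qa import QABundle

TABLE_COLUMNS = [
    "row", "col", "slice", "metabolite", "value",
    "snr", "fwhm_ppm", "crlb", "lip_over_tcr",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(data, affine)`` as float64."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        affine = np.asarray(img.affine, dtype=np.float64)
    except Exception as exc:  # malformed header, truncated file, ...
        raise FormatError(f"cannot read volume {path.name}: {exc}") from exc
    return data, affine


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a float64 NIfTI volume (bitwise round-trip safe)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_affine_text(path) -> np.ndarray:
    """Plain-text 4 x 4 affine matrix."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise FormatError(f"{Path(path).name}: expected a 4 x 4 matrix")
    return mat


def write_affine_text(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%.12g")


def read_displacement_field(path) -> np.ndarray:
    """Displacement field: 4-D NIfTI shaped ``ref_shape + (3,)`` in mm."""
    data, _ = read_volume(path)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"{Path(path).name}: displacement field must be (x, y, z, 3)"
        )
    return data


def read_metabolite_table(
    path, geometry: AcquisitionGeometry
) -> tuple[dict[str, MetaboliteMap], QABundle]:
    """Parse a long-format fitting-stage CSV into dense native-grid maps.

    Expected columns: ``row, col, slice, metabolite, value, snr, fwhm_ppm,
    crlb, lip_over_tcr``. Voxels absent from the table are missing.
    Duplicate (voxel, metabolite) rows and out-of-range indices are
    rejected with the offending row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(
            f"{Path(path).name}: missing columns {missing_cols}"
        )
    shape = geometry.native_shape

    dup = df.duplicated(subset=["row", "col", "slice", "metabolite"])
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0])
        r = df.iloc[first]
        raise ValidationError(
            f"duplicate entry at CSV row {first + 2}: voxel "
            f"({int(r['row'])}, {int(r['col'])}, {int(r['slice'])}) "
            f"metabolite {r['metabolite']!r}"
        )
    for ax, col in enumerate(["row", "col", "slice"]):
        bad = (df[col] < 0) | (df[col] >= shape[ax])
        if bad.any():
            first = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"index out of range at CSV row {first + 2}: "
                f"{col}={int(df.iloc[first][col])} (grid extent {shape[ax]})"
            )

    idx = (
        df["row"].to_numpy(int),
        df["col"].to_numpy(int),
        df["slice"].to_numpy(int),
    )
    maps: dict[str, MetaboliteMap] = {}
    crlb: dict[str, np.ndarray] = {}
    for met, sub in df.groupby("metabolite", sort=True):
        values = np.full(shape, MISSING)
        cfield = np.full(shape, MISSING)
        sidx = (
            sub["row"].to_numpy(int),
            sub["col"].to_numpy(int),
            sub["slice"].to_numpy(int),
        )
        values[sidx] = sub["value"].to_numpy(float)
        cfield[sidx] = sub["crlb"].to_numpy(float)
        maps[str(met)] = MetaboliteMap(
            values=values, metabolite=str(met), grid="native",
            voxel_size_mm=geometry.voxel_size_mm,
        )
        crlb[str(met)] = cfield

    snr = np.full(shape, MISSING)
    fwhm = np.full(shape, MISSING)
    lip = np.full(shape, MISSING)
    snr[idx] = df["snr"].to_numpy(float)
    fwhm[idx] = df["fwhm_ppm"].to_numpy(float)
    lip[idx] = df["lip_over_tcr"].to_numpy(float)
    return maps, QABundle(snr=snr, fwhm_ppm=fwhm, crlb=crlb, lip_over_tcr=lip)


def write_provenance(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))


def read_provenance(path) -> dict:
    return json.loads(Path(path).read_text())
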