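"""Readers and writers for volumes, masks, and tidy tables.

Formats: NIfTI is the primary volume format (float32 HU, uint8 masks,
spacing from the header); MetaImage and DICOM series are read through
SimpleITK / pydicom.  Tables are plain CSV with documented column names
(UTF-8, '.' decimal): traces ``time_s, flow_ml_s, volume_ml[,
pressure_cmh2o]``; PV loops ``pressure_cmh2o, volume_ml, limb``; cohorts
``animal, genotype, sex, age_days, body_length_cm, <response>``;
inhibition curves ``volume_ul, activity``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

from .errors import InputError
from .types import CTVolume, BinaryMask3D, FlowVolumeTrace, PVLoop

TRACE_COLUMNS = ("time_s", "flow_ml_s", "volume_ml")
PV_COLUMNS = ("pressure_cmh2o", "volume_ml", "limb")
COHORT_COLUMNS = ("animal", "genotype", "sex", "age_days", "body_length_cm")
INHIBITION_COLUMNS = ("volume_ul", "activity")


# --------------------------------------------------------------------------
# Volumes
# --------------------------------------------------------------------------


def read_volume(path) -> CTVolume:
    """Read a CT volume from NIfTI, MetaImage, or a DICOM-series directory."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise InputError(f"{path}: header has non-positive voxel spacing {zooms}")
        data = np.asarray(img.dataobj, dtype=np.float32)
        return CTVolume(hu=data, spacing=tuple(float(z) for z in zooms), axis_order="xyz")
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk  # heavyweight; import on demand

        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()[::-1]  # sitk is (x, y, z); array is (z, y, x)
        if any(s <= 0 for s in spacing):
            raise InputError(f"{path}: missing or non-positive spacing in header")
        data = sitk.GetArrayFromImage(img).astype(np.float32)
        return CTVolume(hu=data, spacing=tuple(spacing), axis_order="zyx")
    raise InputError(f"unrecognised volume format: {path}")


def _read_dicom_series(directory: Path) -> CTVolume:
    """Collapse a single-series DICOM directory into one volume.

    Slices are sorted by their z position; a missing slice (a gap larger
    than the modal spacing) is an error naming the gap index.
    """
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    if not files:
        raise InputError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # unreadable file
            raise InputError(f"unreadable DICOM file {f}: {exc}") from exc
    try:
        slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
        zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    except AttributeError as exc:
        raise InputError(f"DICOM slices lack ImagePositionPatient: {exc}") from exc
    if len(slices) < 2:
        raise InputError("DICOM series needs at least 2 slices")
    dz = np.diff(zs)
    if np.any(dz <= 0):
        raise InputError("DICOM slice positions are not strictly increasing")
    # smallest inter-slice distance is the true spacing even when the
    # series has missing slices
    step = float(dz.min())
    gaps = np.flatnonzero(dz > 1.5 * step)
    if gaps.size:
        raise InputError(
            f"DICOM series has a gap after slice index {int(gaps[0])} "
            f"(z jump {dz[gaps[0]]:.3f} vs spacing {step:.3f})"
        )
    try:
        py, px = (float(v) for v in slices[0].PixelSpacing)
    except AttributeError as exc:
        raise InputError("DICOM slices lack PixelSpacing") from exc
    arrays = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        arrays.append(s.pixel_array.astype(np.float32) * slope + inter)
    return CTVolume(hu=np.stack(arrays), spacing=(step, py, px), axis_order="zyx")


def write_volume(volume: CTVolume, path) -> None:
    """Write a volume as NIfTI with spacing encoded in the affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.hu, dtype=np.float32), affine), str(path))


def write_mask(mask: BinaryMask3D, path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


def read_mask(path, role: str) -> BinaryMask3D:
    img = nib.load(str(path))
    return BinaryMask3D(
        np.asarray(img.dataobj) > 0,
        role=role,
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_trace_table(path):
    """Read a CSV and dispatch on its schema.

    Returns a :class:`FlowVolumeTrace`, :class:`PVLoop`, cohort
    DataFrame, or inhibition-curve DataFrame depending on the columns
    found.  Extra columns are preserved as metadata where applicable.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    if set(PV_COLUMNS) <= cols:
        return read_pv_csv(path)
    if "time_s" in cols or "flow_ml_s" in cols:
        return read_flow_volume_csv(path)
    if set(COHORT_COLUMNS) <= cols:
        return read_cohort_csv(path)
    if set(INHIBITION_COLUMNS) <= cols:
        return read_inhibition_csv(path)
    raise InputError(
        f"{path}: unrecognised table schema (columns: {', '.join(sorted(cols))})"
    )


def read_flow_volume_csv(path) -> FlowVolumeTrace:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) == 0):
        bad = int(np.flatnonzero(np.diff(t) == 0)[0]) + 1
        raise InputError(f"{path}: repeated timestamp at row {bad}")
    extra = {c: df[c].to_numpy() for c in df.columns if c not in TRACE_COLUMNS + ("pressure_cmh2o",)}
    trace = FlowVolumeTrace(
        time_s=t,
        flow_ml_s=df["flow_ml_s"].to_numpy(dtype=float),
        volume_ml=df["volume_ml"].to_numpy(dtype=float),
        pressure_cmh2o=df["pressure_cmh2o"].to_numpy(dtype=float)
        if "pressure_cmh2o" in df.columns
        else None,
        meta={"source": str(path), "extra_columns": extra, "dt_s": float(np.median(np.diff(t)))},
    )
    return trace


def write_flow_volume_csv(trace: FlowVolumeTrace, path) -> None:
    out = pd.DataFrame(
        {"time_s": trace.time_s, "flow_ml_s": trace.flow_ml_s, "volume_ml": trace.volume_ml}
    )
    if trace.pressure_cmh2o is not None:
        out["pressure_cmh2o"] = trace.pressure_cmh2o
    out.to_csv(path, index=False)


def read_pv_csv(path) -> PVLoop:
    df = pd.read_csv(path)
    _require_columns(df, PV_COLUMNS, path)
    return PVLoop(
        pressure_cmh2o=df["pressure_cmh2o"].to_numpy(dtype=float),
        volume_ml=df["volume_ml"].to_numpy(dtype=float),
        limb=df["limb"].to_numpy(),
        meta={"source": str(path)},
    )


def write_pv_csv(loop: PVLoop, path) -> None:
    pd.DataFrame(
        {
            "pressure_cmh2o": loop.pressure_cmh2o,
            "volume_ml": loop.volume_ml,
            "limb": loop.limb,
        }
    ).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    if (df["age_days"] < 0).any():
        raise InputError(f"{path}: negative ages")
    return df


def read_inhibition_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, INHIBITION_COLUMNS, path)
    return df


def write_json_sidecar(params: dict, path) -> None:
    """Echo fully resolved parameters next to an output artifact."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items() if not k.startswith("_")}
        return str(o)

    Path(path).write_text(json.dumps(params, indent=2, default=_default, sort_keys=True))
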