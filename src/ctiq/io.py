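"""Readers/writers for image stacks.

Two on-disk representations are supported:

``native_stack``
    A directory (or ``.ctstack`` prefix) holding ``header.json`` — dims,
    spacings, meta, plus the integer quantization (slope/intercept) — and
    ``voxels.raw``, little-endian int16 in (slice, row, col) order.  HU are
    stored as ``int16 = round((HU - intercept) / slope)``; with the default
    slope of 1 HU the round-trip error is at most 0.5 HU.

``dicom_series``
    A directory of single-frame CT DICOM files, one per slice, sorted by
    slice position.  RescaleSlope/RescaleIntercept are applied on read so
    the in-memory stack is always floating-point HU.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .stack import ImageStack

_HEADER_NAME = "header.json"
_VOXELS_NAME = "voxels.raw"


class FormatError(ValueError):
    """Input files do not form a readable, geometrically consistent stack."""


def write_stack(stack: ImageStack, path: str | Path, format: str = "native_stack") -> None:
    """Write a stack; see module docstring for the formats."""
    path = Path(path)
    if format == "native_stack":
        _write_native(stack, path)
    elif format == "dicom_series":
        _write_dicom(stack, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_stack(path: str | Path, format: str = "native_stack") -> ImageStack:
    """Read a stack written by :func:`write_stack` or a DICOM series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native_stack":
        return _read_native(path)
    if format == "dicom_series":
        return _read_dicom(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------- native

def _quantization(stack: ImageStack) -> tuple[float, float]:
    """Slope/intercept mapping HU to int16 with <=0.5*slope error."""
    lo = float(stack.voxels.min())
    hi = float(stack.voxels.max())
    # Keep slope 1 (error <= 0.5 HU) whenever the range fits int16.
    intercept = 0.0
    slope = 1.0
    if lo < -32000 or hi > 32000:
        intercept = (hi + lo) / 2.0
        slope = max((hi - lo) / 64000.0, 1e-6)
    return slope, intercept


def _write_native(stack: ImageStack, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    slope, intercept = _quantization(stack)
    stored = np.round((stack.voxels - intercept) / slope).astype("<i2")
    header = {
        "shape": list(stack.voxels.shape),
        "pixel_spacing_x": stack.pixel_spacing_x,
        "pixel_spacing_y": stack.pixel_spacing_y,
        "slice_thickness": stack.slice_thickness,
        "slice_increment": stack.slice_increment,
        "rescale_slope": slope,
        "rescale_intercept": intercept,
        "dtype": "int16-le",
        "meta": _jsonable(stack.meta),
    }
    (path / _HEADER_NAME).write_text(json.dumps(header, indent=2))
    (path / _VOXELS_NAME).write_bytes(stored.tobytes())


def _read_native(path: Path) -> ImageStack:
    header_path = path / _HEADER_NAME
    if not header_path.exists():
        raise FormatError(f"no {_HEADER_NAME} under {path}")
    header = json.loads(header_path.read_text())
    shape = tuple(header["shape"])
    raw = np.frombuffer((path / _VOXELS_NAME).read_bytes(), dtype="<i2")
    if raw.size != int(np.prod(shape)):
        raise FormatError(
            f"voxel payload has {raw.size} values, header promises {np.prod(shape)}"
        )
    hu = raw.reshape(shape).astype(np.float64)
    hu = hu * header["rescale_slope"] + header["rescale_intercept"]
    meta = dict(header.get("meta", {}))
    meta.setdefault("source", str(path))
    return ImageStack(
        voxels=hu,
        pixel_spacing_x=header["pixel_spacing_x"],
        pixel_spacing_y=header["pixel_spacing_y"],
        slice_thickness=header["slice_thickness"],
        slice_increment=header["slice_increment"],
        meta=meta,
    )


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


# ---------------------------------------------------------------- DICOM

def _write_dicom(stack: ImageStack, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    slope, intercept = _quantization(stack)
    stored = np.round((stack.voxels - intercept) / slope).astype("<i2")
    for i in range(stack.n_slices):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, i * stack.slice_increment]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [stack.pixel_spacing_y, stack.pixel_spacing_x]
        ds.SliceThickness = stack.slice_thickness
        ds.Rows, ds.Columns = stack.voxels.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[i].tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(path / f"slice_{i:04d}.dcm", ds, enforce_file_format=True)


def _read_dicom(path: Path) -> ImageStack:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM slices under {path}")

    def _z(ds: Dataset) -> float:
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_z)
    first = datasets[0]
    if "PixelSpacing" not in first:
        raise FormatError("DICOM series lacks PixelSpacing")
    spacing_y, spacing_x = (float(v) for v in first.PixelSpacing)
    shape = (int(first.Rows), int(first.Columns))
    slices = []
    for ds in datasets:
        if (int(ds.Rows), int(ds.Columns)) != shape:
            raise FormatError("mixed image dimensions in DICOM series")
        if "PixelSpacing" not in ds or [float(v) for v in ds.PixelSpacing] != [
            spacing_y,
            spacing_x,
        ]:
            raise FormatError("inconsistent pixel spacing in DICOM series")
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    zs = [_z(ds) for ds in datasets]
    increment = float(np.median(np.diff(zs))) if len(zs) > 1 else float(
        getattr(first, "SliceThickness", 1.0)
    )
    return ImageStack(
        voxels=np.stack(slices),
        pixel_spacing_x=spacing_x,
        pixel_spacing_y=spacing_y,
        slice_thickness=float(getattr(first, "SliceThickness", increment)),
        slice_increment=abs(increment),
        meta={"source": str(path), "n_files": len(datasets)},
    )
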