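"""Persistence: DICOM RT Dose import/export and the native bundle format.

The native plan-bundle format is a directory with a JSON manifest plus
compressed NumPy arrays — portable and diff-able.  DICOM RT Dose is an
import/export adapter only; the in-memory model stays :class:`DoseGrid`.

DICOM mapping: stored pixels are unsigned integers times ``DoseGridScaling``;
geometry comes from ``ImagePositionPatient`` (mm, first voxel center),
``PixelSpacing`` (row = y, column = x) and ``GridFrameOffsetVector`` (z
offsets per frame, which must be uniform).  The pixel array is frame-major
(z, y, x) and is transposed to the package's (x, y, z) axis order.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import __version__
from .cohort import (
    Capsule,
    CohortConfig,
    Ellipsoid,
    GridSpec,
    PlanBundle,
    PlanTechnique,
    Sphere,
    VirtualPatient,
    _ShapeUnion,
)
from .grid import DoseGrid, GridError
from .metrics import StructureMask

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

def write_rtdose(grid: DoseGrid, path) -> None:
    """Write a minimal, standard-conformant RT Dose object."""
    path = Path(path)
    scaling = float(grid.values.max()) / (2**32 - 1) if grid.values.max() > 0 else 1.0
    stored = np.round(grid.values / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.PatientName = "dosecloud^synthetic"
    ds.PatientID = "dosecloud"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
    nx, ny, nz = grid.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = scaling
    # (x, y, z) -> frame-major (z, y, x)
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_rtdose(path) -> DoseGrid:
    """Read an RT Dose file into a :class:`DoseGrid`."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", None) != RTDOSE_SOP_CLASS:
        raise GridError(f"{path}: not an RT Dose object")
    for tag in ("ImagePositionPatient", "PixelSpacing", "GridFrameOffsetVector",
                "DoseGridScaling"):
        if not hasattr(ds, tag):
            raise GridError(f"{path}: missing required RT Dose tag {tag}")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    steps = np.diff(offsets)
    if offsets.size < 2 or not np.allclose(steps, steps[0]):
        raise GridError(f"{path}: non-uniform GridFrameOffsetVector is not supported")
    dz = float(steps[0])
    if dz <= 0:
        raise GridError(f"{path}: GridFrameOffsetVector must be increasing")
    spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    frames = ds.pixel_array  # (frames=z, rows=y, cols=x)
    if frames.ndim == 2:
        frames = frames[None]
    values = frames.astype(np.float64).transpose(2, 1, 0) * float(ds.DoseGridScaling)
    return DoseGrid(values=values, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# native bundle format
# ---------------------------------------------------------------------------

def _shape_to_dict(shape) -> dict:
    if isinstance(shape, Sphere):
        return {"type": "sphere", "center": list(shape.center),
                "radius": shape.radius}
    if isinstance(shape, Ellipsoid):
        return {"type": "ellipsoid", "center": list(shape.center),
                "semi_axes": list(shape.semi_axes)}
    if isinstance(shape, Capsule):
        return {"type": "capsule", "a": list(shape.a), "b": list(shape.b),
                "radius": shape.radius}
    if isinstance(shape, _ShapeUnion):
        return {"type": "union", "parts": [_shape_to_dict(p) for p in shape.parts]}
    raise GridError(f"unknown shape {type(shape).__name__}")


def _shape_from_dict(d: dict):
    t = d["type"]
    if t == "sphere":
        return Sphere(tuple(d["center"]), d["radius"])
    if t == "ellipsoid":
        return Ellipsoid(tuple(d["center"]), tuple(d["semi_axes"]))
    if t == "capsule":
        return Capsule(tuple(d["a"]), tuple(d["b"]), d["radius"])
    if t == "union":
        return _ShapeUnion(tuple(_shape_from_dict(p) for p in d["parts"]))
    raise GridError(f"unknown shape type {t!r}")


def _array_digest(**arrays) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()


def save_bundle(bundle: PlanBundle, directory) -> Path:
    """Write a plan bundle as manifest.json + arrays.npz; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {"dose": bundle.dose.values}
    for name, mask in bundle.masks.items():
        arrays[f"mask_{name}"] = mask.voxels
    p = bundle.patient
    manifest = {
        "format": "dosecloud-bundle-v1",
        "package_version": __version__,
        "patient_id": p.patient_id,
        "technique": {
            "label": bundle.technique.label,
            "penumbra_width": bundle.technique.penumbra_width,
            "bath_level": bundle.technique.bath_level,
            "bath_sigma": bundle.technique.bath_sigma,
        },
        "prescription": list(p.prescription),
        "isocenter": list(p.isocenter),
        "brain": _shape_to_dict(p.brain),
        "gtvs": [_shape_to_dict(g) for g in p.gtvs],
        "oars": {k: _shape_to_dict(v) for k, v in sorted(p.oars.items())},
        "grid_spec": bundle.grid_spec.to_dict(),
        "seed": bundle.seed,
        "roi_names": sorted(bundle.masks),
        "sha256": _array_digest(**arrays),
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    np.savez_compressed(directory / "arrays.npz", **arrays)
    return directory


def load_bundle(directory) -> PlanBundle:
    """Read a bundle directory back; verifies the manifest content hash."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format") != "dosecloud-bundle-v1":
        raise GridError(f"{directory}: not a dosecloud bundle")
    with np.load(directory / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    if _array_digest(**arrays) != manifest["sha256"]:
        raise GridError(f"{directory}: payload does not match manifest hash")
    spec = GridSpec.from_dict(manifest["grid_spec"])
    spacing = np.asarray(spec.spacing)
    patient = VirtualPatient(
        patient_id=manifest["patient_id"],
        brain=_shape_from_dict(manifest["brain"]),
        gtvs=tuple(_shape_from_dict(g) for g in manifest["gtvs"]),
        oars={k: _shape_from_dict(v) for k, v in manifest["oars"].items()},
        prescription=(manifest["prescription"][0], int(manifest["prescription"][1])),
        isocenter=tuple(manifest["isocenter"]),
    )
    tech = manifest["technique"]
    masks = {
        name: StructureMask(name=name, voxels=arrays[f"mask_{name}"],
                            spacing=spacing)
        for name in manifest["roi_names"]
    }
    return PlanBundle(
        patient=patient,
        technique=PlanTechnique(
            label=tech["label"],
            penumbra_width=tech["penumbra_width"],
            bath_level=tech["bath_level"],
            bath_sigma=tech.get("bath_sigma", 60.0),
        ),
        dose=DoseGrid(arrays["dose"], spacing, np.asarray(spec.origin)),
        masks=masks,
        grid_spec=spec,
        seed=manifest.get("seed"),
    )


def read_dose_any(path) -> DoseGrid:
    """Read a dose grid from RT Dose (.dcm), a bundle directory, or .npz."""
    path = Path(path)
    if path.is_dir():
        return load_bundle(path).dose
    if path.suffix.lower() == ".npz":
        with np.load(path) as npz:
            return DoseGrid(npz["dose"], npz["spacing"], npz["origin"])
    return read_rtdose(path)


def save_provenance(directory, seed: int | None, config: CohortConfig | None,
                    extra: dict | None = None) -> None:
    """Record enough (config, seed, version) to reproduce a run exactly."""
    record = {
        "package_version": __version__,
        "seed": seed,
        "config": (config or CohortConfig()).to_dict(),
    }
    if extra:
        record.update(extra)
    Path(directory).mkdir(parents=True, exist_ok=True)
    (Path(directory) / "provenance.json").write_text(
        json.dumps(record, indent=1, sort_keys=True)
    )
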