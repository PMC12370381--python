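"""DICOM export/import: CT series, RT Structure Set, RT Dose.

The writer produces a minimal but standard-conformant bundle that the
package's own readers (and typical RT software) can load: one CT instance
per slice, one RTSTRUCT with each structure's planar contours as
``ContourData`` triplets (patient coordinates, mm), and multi-frame RTDOSE
objects with a ``GridFrameOffsetVector``.  UIDs are generated
deterministically from the frame-of-reference tag and instance names, so a
re-exported bundle is reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .contours import PlanarContour, StructureSet
from .dose import DoseGrid
from .grid import VoxelGrid

__all__ = [
    "write_ct_series",
    "write_rtstruct",
    "write_rtdose",
    "read_ct_series",
    "read_rtstruct",
    "read_rtdose",
    "write_dicom_case",
]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"


def _uid(*parts: str) -> str:
    return generate_uid(entropy_srcs=[str(p) for p in parts])


def _base_dataset(path: Path, sop_class: str, sop_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.PatientName = "QA^Phantom"
    ds.PatientID = "SRSQA"
    ds.Modality = {"1.2.840.10008.5.1.4.1.1.2": "CT"}.get(sop_class, "")
    return ds


def write_ct_series(grid: VoxelGrid, directory: str | Path, frame_of_reference: str) -> list[Path]:
    """Write one CT instance per slice (uniform water-equivalent image)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for_uid = _uid("FOR", frame_of_reference)
    series_uid = _uid("CT-series", frame_of_reference)
    study_uid = _uid("study", frame_of_reference)
    nx, ny, nz = grid.dims
    pixels = np.zeros((ny, nx), dtype=np.int16)
    paths = []
    for k, z in enumerate(grid.slice_positions):
        path = directory / f"ct_{k:04d}.dcm"
        ds = _base_dataset(path, _CT_SOP, _uid("CT", frame_of_reference, k))
        ds.Modality = "CT"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = for_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], float(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # row (y), col (x)
        ds.SliceThickness = grid.spacing[2]
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = 0.0
        ds.RescaleSlope = 1.0
        ds.PixelData = pixels.tobytes()
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_rtstruct(
    structures: StructureSet, grid: VoxelGrid, path: str | Path, frame_of_reference: str
) -> Path:
    path = Path(path)
    ds = _base_dataset(path, _RTSTRUCT_SOP, _uid("RTSTRUCT", frame_of_reference))
    ds.Modality = "RTSTRUCT"
    ds.StudyInstanceUID = _uid("study", frame_of_reference)
    ds.SeriesInstanceUID = _uid("RTSTRUCT-series", frame_of_reference)
    ds.StructureSetLabel = "srsqa"
    for_uid = _uid("FOR", frame_of_reference)

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = for_uid
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    rois, roi_contours, roi_obs = [], [], []
    for number, name in enumerate(structures.names(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        rois.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        contour_seq = []
        for c in structures[name]:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(c.vertices)
            data = np.column_stack([c.vertices, np.full(len(c.vertices), c.z)])
            item.ContourData = [f"{v:.6f}" for v in data.ravel()]
            contour_seq.append(item)
        rc.ContourSequence = contour_seq
        roi_contours.append(rc)
        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = "PTV" if not name.endswith("_eval") else "AVOIDANCE"
        roi_obs.append(obs)
    ds.StructureSetROISequence = rois
    ds.ROIContourSequence = roi_contours
    ds.RTROIObservationsSequence = roi_obs
    ds.save_as(path, enforce_file_format=True)
    return path


def write_rtdose(dose: DoseGrid, path: str | Path, frame_of_reference: str) -> Path:
    """Multi-frame RTDOSE with GridFrameOffsetVector and 32-bit scaling."""
    path = Path(path)
    ds = _base_dataset(path, _RTDOSE_SOP, _uid("RTDOSE", frame_of_reference, path.name))
    ds.Modality = "RTDOSE"
    ds.StudyInstanceUID = _uid("study", frame_of_reference)
    ds.SeriesInstanceUID = _uid("RTDOSE-series", frame_of_reference, path.name)
    ds.FrameOfReferenceUID = _uid("FOR", frame_of_reference)
    grid = dose.grid
    nx, ny, nz = grid.dims
    scaling = max(float(dose.values.max()), 1e-12) / (2**32 - 1)
    stored = np.round(dose.values / scaling).astype(np.uint32)
    # DICOM dose frames are z-slices of (rows=y, cols=x)
    frames = np.transpose(stored, (2, 1, 0))
    ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], grid.origin[2]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(nz)]
    ds.NumberOfFrames = nz
    ds.Rows, ds.Columns = ny, nx
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.DoseComment = f"prescription_gy={dose.prescription_gy:.6f}"
    ds.PixelData = frames.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_ct_series(directory: str | Path) -> VoxelGrid:
    files = sorted(Path(directory).glob("ct_*.dcm"))
    if not files:
        raise FileNotFoundError(f"no CT instances found in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    st = float(np.median(np.diff(zs))) if len(zs) > 1 else float(first.SliceThickness)
    return VoxelGrid(
        origin=(
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            float(zs[0]),
        ),
        spacing=(float(first.PixelSpacing[1]), float(first.PixelSpacing[0]), st),
        dims=(int(first.Columns), int(first.Rows), len(slices)),
    )


def read_rtstruct(path: str | Path) -> StructureSet:
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out = StructureSet(frame_of_reference=str(getattr(ds, "StructureSetLabel", "")))
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        for item in getattr(rc, "ContourSequence", []):
            data = np.array([float(v) for v in item.ContourData]).reshape(-1, 3)
            out.add(name, PlanarContour(z=float(data[0, 2]), vertices=data[:, :2]))
    return out


def read_rtdose(path: str | Path, prescription_gy: float | None = None) -> DoseGrid:
    ds = pydicom.dcmread(path)
    nz = int(ds.NumberOfFrames)
    ny, nx = int(ds.Rows), int(ds.Columns)
    raw = np.frombuffer(ds.PixelData, dtype=np.uint32).reshape(nz, ny, nx)
    values = np.transpose(raw, (2, 1, 0)).astype(float) * float(ds.DoseGridScaling)
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(np.median(np.diff(offsets))) if nz > 1 else 1.0
    grid = VoxelGrid(
        origin=(
            float(ds.ImagePositionPatient[0]),
            float(ds.ImagePositionPatient[1]),
            float(ds.ImagePositionPatient[2]) + float(offsets[0]),
        ),
        spacing=(float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz),
        dims=(nx, ny, nz),
    )
    if prescription_gy is None:
        comment = str(getattr(ds, "DoseComment", ""))
        if comment.startswith("prescription_gy="):
            prescription_gy = float(comment.split("=", 1)[1])
        else:
            raise ValueError("prescription dose not recorded in file; pass prescription_gy")
    return DoseGrid(grid, np.ascontiguousarray(values), prescription_gy)


def write_dicom_case(bundle, directory: str | Path) -> dict[str, list[Path]]:
    """Export a phantom bundle as DICOM: CT series, RTSTRUCT, RTDOSE file(s).

    Ground-truth bundles (one dose matrix per target) produce one RTDOSE per
    target; clinical-like cases produce a single combined RTDOSE covering
    the CT lattice at the bundle's dose spacing.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fr = bundle.structures.frame_of_reference or f"srsqa-{bundle.seed}"
    out: dict[str, list[Path]] = {}
    out["ct"] = write_ct_series(bundle.ct_grid, directory / "ct", fr)
    out["rtstruct"] = [
        write_rtstruct(bundle.structures, bundle.ct_grid, directory / "rtstruct.dcm", fr)
    ]
    doses = []
    if bundle.per_target_dose:
        for t in bundle.targets:
            dose = bundle.dose_window(t)
            doses.append(write_rtdose(dose, directory / f"rtdose_{t.name}.dcm", fr))
    else:
        lo = [bundle.ct_grid.extent(a)[0] for a in range(3)]
        hi = [bundle.ct_grid.extent(a)[1] for a in range(3)]
        grid = VoxelGrid.from_extent(
            tuple(lo), tuple(hi), bundle.dose_spacing, lattice_origin=bundle.dose_lattice_origin
        )
        dose = DoseGrid.from_model(bundle.dose_model(), grid, bundle.prescription_gy)
        doses.append(write_rtdose(dose, directory / "rtdose.dcm", fr))
    out["rtdose"] = doses
    return out
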