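"""DICOM RT Dose / RT Structure Set import and RT Dose export.

Supported inputs are axial, axis-aligned grids (the common TPS export):
RT Dose frames stacked along z with a uniform GridFrameOffsetVector, dose in
Gy after DoseGridScaling, and closed planar axial contours rasterised onto a
caller-supplied reference grid with even-odd fill per slice. These readers
exist for interoperability; the test interchange format is the fixture case
directory, which never requires clinical data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.draw import polygon as _sk_polygon

from .grid import DoseGrid, Grid3D, Modality, OrganClass, StructureMask

__all__ = [
    "RTDoseFormatError",
    "RTStructFormatError",
    "read_rt_dose",
    "write_rt_dose",
    "read_rt_struct",
]

RT_DOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_AXIAL_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class RTDoseFormatError(ValueError):
    pass


class RTStructFormatError(ValueError):
    pass


def read_rt_dose(
    path: str | Path,
    n_fractions: int = 1,
    modality: Modality = Modality.EBRT,
    course_id: str = "",
) -> DoseGrid:
    """Read an RT Dose file into a :class:`DoseGrid` (values in Gy).

    The fraction count and delivery modality are not stored in RT Dose
    objects, so the caller supplies them (they live in the RT Plan).
    """
    ds = pydicom.dcmread(str(path))
    units = getattr(ds, "DoseUnits", None)
    if units != "GY":
        raise RTDoseFormatError(
            f"unsupported DoseUnits {units!r}; absolute dose in GY is required"
        )
    summation = getattr(ds, "DoseSummationType", None)
    if summation in ("BEAM", "BEAM_SESSION", "CONTROL_POINT"):
        raise RTDoseFormatError(
            f"per-beam dose (DoseSummationType={summation}) cannot be "
            "accumulated directly; export a PLAN dose sum instead"
        )
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise RTDoseFormatError("DoseGridScaling is missing")
    orientation = tuple(float(v) for v in ds.ImageOrientationPatient)
    if not np.allclose(orientation, _AXIAL_ORIENTATION):
        raise RTDoseFormatError(
            "only axial, axis-aligned dose grids are supported "
            f"(ImageOrientationPatient={orientation})"
        )
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size < 2:
        raise RTDoseFormatError("need at least two dose frames")
    dz = np.diff(offsets)
    if not np.allclose(dz, dz[0]):
        raise RTDoseFormatError("non-uniform frame spacing is not supported")
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)  # row = y, col = x
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = Grid3D(
        origin=(origin[0], origin[1], origin[2] + offsets[0]),
        spacing=(col_mm, row_mm, float(dz[0])),
        shape=(int(ds.Columns), int(ds.Rows), int(ds.NumberOfFrames)),
    )
    frames = ds.pixel_array.astype(np.float64)  # (z, y, x)
    values = frames.transpose(2, 1, 0) * float(scaling)
    return DoseGrid(
        grid=grid, values=values, n_fractions=n_fractions,
        modality=modality, course_id=course_id,
    )


def write_rt_dose(
    dose: DoseGrid, path: str | Path, dose_grid_scaling: float | None = None
) -> None:
    """Write a minimal PLAN-summation RT Dose file (32-bit scaled integers).

    With the default scaling (max dose / (2**32 - 1)) quantisation error is
    below 1e-8 Gy per voxel; pass an explicit power-of-two scaling to make
    doses that are exact multiples of it round-trip bit-identically.
    """
    values = dose.values
    if dose_grid_scaling is None:
        vmax = float(values.max())
        dose_grid_scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    ints = np.round(values / dose_grid_scaling)
    if np.any(ints > 2**32 - 1):
        raise RTDoseFormatError("dose exceeds 32-bit range at this scaling")
    ints = ints.astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_DOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RT_DOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = dose_grid_scaling
    ds.ImageOrientationPatient = list(_AXIAL_ORIENTATION)
    ds.ImagePositionPatient = list(dose.grid.origin)
    ds.PixelSpacing = [dose.grid.spacing[1], dose.grid.spacing[0]]  # [row, col]
    ds.GridFrameOffsetVector = [
        i * dose.grid.spacing[2] for i in range(dose.grid.shape[2])
    ]
    ds.Columns = dose.grid.shape[0]
    ds.Rows = dose.grid.shape[1]
    ds.NumberOfFrames = dose.grid.shape[2]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.PixelData = ints.transpose(2, 1, 0).tobytes()  # (z, y, x) frame order
    ds.save_as(str(path), enforce_file_format=True)


def read_rt_struct(
    path: str | Path,
    reference: Grid3D,
    organ_classes: Mapping[str, OrganClass] | None = None,
) -> list[StructureMask]:
    """Rasterise an RT Structure Set onto ``reference`` (one mask per ROI).

    Each closed planar axial contour is filled over voxel centres; multiple
    contours on one slice combine with even-odd parity (so holes and islands
    are honoured). ``organ_classes`` maps ROI names to organ classes
    (default OTHER).
    """
    ds = pydicom.dcmread(str(path))
    organ_classes = dict(organ_classes or {})
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    masks: list[StructureMask] = []
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = names.get(number, f"ROI {number}")
        values = np.zeros(reference.shape, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            geom = getattr(contour, "ContourGeometricType", "CLOSED_PLANAR")
            if geom != "CLOSED_PLANAR":
                raise RTStructFormatError(
                    f"{name}: unsupported contour type {geom!r}"
                )
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            if not np.allclose(pts[:, 2], pts[0, 2], atol=1e-6):
                raise RTStructFormatError(
                    f"{name}: non-axial contour plane (z varies within contour)"
                )
            k = (pts[0, 2] - reference.origin[2]) / reference.spacing[2]
            k_idx = int(round(k))
            if abs(k - k_idx) > 0.5 or not 0 <= k_idx < reference.shape[2]:
                raise RTStructFormatError(
                    f"{name}: contour plane z={pts[0, 2]:g} mm is not on a "
                    "reference grid slice"
                )
            i = (pts[:, 0] - reference.origin[0]) / reference.spacing[0]
            j = (pts[:, 1] - reference.origin[1]) / reference.spacing[1]
            rr, cc = _sk_polygon(i, j, shape=reference.shape[:2])
            values[rr, cc, k_idx] ^= True  # even-odd fill across contours
        masks.append(
            StructureMask(
                grid=reference,
                values=values,
                name=name,
                organ_class=organ_classes.get(name, OrganClass.OTHER),
            )
        )
    return masks
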