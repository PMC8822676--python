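"""Read and write the DICOM objects the contouring pipeline lives on.

CT image series are read into calibrated :class:`CTVolume` grids (Hounsfield
units, geometry in mm), RT Structure Set files are converted to and from
binary label volumes (:class:`StructureSet`), and predicted masks are written
back out as DICOM-compliant structure sets referencing the source CT slices.

Coordinate convention (documented once, used everywhere): voxel indices are
0-based ``(slice, row, col)``; ImagePositionPatient addresses the *center* of
the first (row 0, col 0) pixel, so pixel ``(r, c)`` on slice ``k`` has patient
coordinates ``origin + c * col_spacing * col_cosine + r * row_spacing *
row_cosine`` with ``z = slice_positions[k]``.  Only axial-aligned series
(row/col direction cosines within 1e-3 of (1,0,0)/(0,1,0)) are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage
from skimage import measure

__all__ = [
    "CTVolume",
    "StructureROI",
    "StructureSet",
    "ContourPolygon",
    "DicomIOError",
    "read_ct_series",
    "contours_to_mask",
    "mask_to_contours",
    "read_rtstruct",
    "write_rtstruct",
    "DEFAULT_UID_ROOT",
]

#: Configurable UID root for objects this package creates.
DEFAULT_UID_ROOT = "1.2.826.0.1.3680043.10.1842."

_Z_TOL = 0.01  # mm; tolerance for matching contour z to a slice position
_AXIAL_TOL = 1e-3  # tolerance on direction cosines for axial alignment

CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"


class DicomIOError(ValueError):
    """Raised on malformed, inconsistent, or unsupported DICOM input."""


@dataclass
class CTVolume:
    """A calibrated axial CT volume with the geometry needed for RTSTRUCT I/O.

    ``voxels`` is ``(n_slices, rows, cols)`` in Hounsfield units, slices
    sorted by ascending patient-z.
    """

    voxels: np.ndarray
    pixel_spacing: Tuple[float, float]  # (row mm, col mm)
    slice_thickness: float
    slice_positions: np.ndarray  # (n_slices,) patient z, mm
    origin: Tuple[float, float, float]  # patient coords of voxel (0,0,0) center
    orientation: Tuple[float, ...] = (1, 0, 0, 0, 1, 0)
    sop_instance_uids: List[str] = field(default_factory=list)
    series_uid: str = ""
    frame_of_reference_uid: str = ""
    patient_id: str = ""

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.voxels.shape)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.voxels)):
            raise DicomIOError("CT volume contains non-finite HU values")
        if self.sop_instance_uids and len(self.sop_instance_uids) != self.n_slices:
            raise DicomIOError("one SOP instance UID required per slice")
        dz = np.diff(self.slice_positions)
        if len(dz) and (np.any(dz <= 0) or np.ptp(dz) > _Z_TOL):
            raise DicomIOError(
                f"slice positions not uniformly ascending: {self.slice_positions}"
            )


@dataclass
class StructureROI:
    """One named region: a binary mask on the CT grid plus RTSTRUCT metadata."""

    mask: np.ndarray
    number: int
    color: Tuple[int, int, int] = (255, 0, 0)


@dataclass
class StructureSet:
    """Named binary label volumes aligned to one CT grid."""

    ct_ref: str  # series UID of the referenced CTVolume
    rois: Dict[str, StructureROI] = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray, number: int | None = None,
            color: Tuple[int, int, int] = (255, 0, 0)) -> None:
        if number is None:
            number = 1 + max((r.number for r in self.rois.values()), default=0)
        if number <= 0 or any(r.number == number for r in self.rois.values()):
            raise ValueError(f"ROI number {number} not unique and positive")
        self.rois[name] = StructureROI(np.asarray(mask, dtype=bool), number, color)

    def names(self) -> List[str]:
        return list(self.rois)


@dataclass
class ContourPolygon:
    """A closed planar contour: patient-coordinate vertices on one slice.

    The polygon closes implicitly (last point connects to the first).
    """

    slice_index: int
    points: np.ndarray  # (n, 3) of (x, y, z) mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 3 or self.points.shape[1] != 3:
            raise ValueError("a contour polygon needs >= 3 (x, y, z) points")
        if np.ptp(self.points[:, 2]) > _Z_TOL:
            raise ValueError("contour polygon is not planar in z")


# ---------------------------------------------------------------------------
# CT series reading


def _is_axial(orientation: Sequence[float]) -> bool:
    o = np.asarray(orientation, dtype=float)
    return bool(
        np.all(np.abs(o[:3] - (1, 0, 0)) < _AXIAL_TOL)
        and np.all(np.abs(o[3:] - (0, 1, 0)) < _AXIAL_TOL)
    )


def read_ct_series(directory: str | Path) -> CTVolume:
    """Read one axial CT series from a directory into Hounsfield units.

    Slices are sorted by ascending z regardless of filename order; stored
    pixel values are mapped to HU with the per-file rescale slope/intercept.

    Raises :class:`DicomIOError` on mixed series, non-axial orientation,
    non-uniform slice spacing (beyond 0.01 mm) or missing rescale metadata.
    """
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if getattr(ds, "SOPClassUID", None) == RTSTRUCT_STORAGE:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if len(datasets) < 2:
        raise DicomIOError(f"need >= 2 CT image files in {directory}")

    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) != 1:
        raise DicomIOError(f"mixed series in {directory}: {sorted(series_uids)}")

    for ds in datasets:
        if not _is_axial(ds.ImageOrientationPatient):
            raise DicomIOError("only axial-aligned CT series are supported")
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise DicomIOError("missing rescale slope/intercept metadata")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    positions = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        raise DicomIOError(f"duplicate or non-monotonic slice positions: {positions}")
    if np.ptp(gaps) > _Z_TOL:
        bad = positions[np.r_[True, np.abs(gaps - np.median(gaps)) > _Z_TOL / 2]]
        raise DicomIOError(
            f"non-uniform slice spacing (gaps {gaps}); offending positions {bad}"
        )

    first = datasets[0]
    hu = np.stack(
        [
            ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope)
            + float(ds.RescaleIntercept)
            for ds in datasets
        ]
    )
    vol = CTVolume(
        voxels=hu,
        pixel_spacing=(float(first.PixelSpacing[0]), float(first.PixelSpacing[1])),
        slice_thickness=float(gaps.mean()),
        slice_positions=positions,
        origin=tuple(float(v) for v in first.ImagePositionPatient),
        orientation=tuple(float(v) for v in first.ImageOrientationPatient),
        sop_instance_uids=[ds.SOPInstanceUID for ds in datasets],
        series_uid=first.SeriesInstanceUID,
        frame_of_reference_uid=getattr(first, "FrameOfReferenceUID", ""),
        patient_id=str(getattr(first, "PatientID", "")),
    )
    vol.validate()
    return vol


# ---------------------------------------------------------------------------
# Polygon <-> mask


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing number) point-in-polygon test.

    Uses the half-open rule ``(y1 > p) != (y2 > p)`` so a center lying exactly
    on a horizontal boundary is attributed to the entering edge — the
    deterministic tie-break the rasterizer promises.
    """
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if y1 == y2:
            continue
        crosses = (y1 > py) != (y2 > py)
        xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def _patient_to_index(points: np.ndarray, volume: CTVolume) -> np.ndarray:
    """(x, y) patient mm -> fractional (col, row) indices on the volume grid."""
    ox, oy, _ = volume.origin
    col = (points[:, 0] - ox) / volume.pixel_spacing[1]
    row = (points[:, 1] - oy) / volume.pixel_spacing[0]
    return np.column_stack([col, row])


def contours_to_mask(polygons: Sequence[ContourPolygon], volume: CTVolume) -> np.ndarray:
    """Rasterize closed planar contours onto the CT grid.

    A pixel is set iff its center is inside the polygon under the even-odd
    rule; multiple polygons on one slice are unioned.  Polygon z must match a
    slice position within 0.01 mm.
    """
    mask = np.zeros(volume.shape, dtype=bool)
    n_rows, n_cols = volume.shape[1:]
    for poly in polygons:
        z = float(np.mean(poly.points[:, 2]))
        dz = np.abs(volume.slice_positions - z)
        k = int(np.argmin(dz))
        if dz[k] > _Z_TOL:
            raise DicomIOError(f"contour z={z} matches no slice position")
        cr = _patient_to_index(poly.points, volume)
        c0 = max(int(np.floor(cr[:, 0].min())) - 1, 0)
        c1 = min(int(np.ceil(cr[:, 0].max())) + 2, n_cols)
        r0 = max(int(np.floor(cr[:, 1].min())) - 1, 0)
        r1 = min(int(np.ceil(cr[:, 1].max())) + 2, n_rows)
        if c0 >= c1 or r0 >= r1:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = _points_in_polygon(cc.astype(float), rr.astype(float), cr)
        mask[k, r0:r1, c0:c1] |= inside
    return mask


def mask_to_contours(mask: np.ndarray, volume: CTVolume) -> List[ContourPolygon]:
    """Trace one closed polygon per connected region per slice, in patient mm.

    Holes are filled before tracing (inner/outer contour polarity is not
    modeled); an empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise DicomIOError("mask shape does not match the CT grid")
    ox, oy, _ = volume.origin
    row_sp, col_sp = volume.pixel_spacing
    out: List[ContourPolygon] = []
    for k in range(mask.shape[0]):
        sl = mask[k]
        if not sl.any():
            continue
        sl = ndimage.binary_fill_holes(sl)
        labels, n = ndimage.label(sl, structure=np.ones((3, 3), dtype=int))
        z = float(volume.slice_positions[k])
        for lab in range(1, n + 1):
            region = np.pad(labels == lab, 1).astype(float)
            contours = measure.find_contours(region, 0.5)
            if not contours:
                continue
            # outer boundary = the longest traced contour
            contour = max(contours, key=len) - 1.0  # remove padding offset
            if len(contour) < 3:
                continue
            rows, cols = contour[:, 0], contour[:, 1]
            pts = np.column_stack(
                [ox + cols * col_sp, oy + rows * row_sp, np.full(len(rows), z)]
            )
            if np.allclose(pts[0], pts[-1]):
                pts = pts[:-1]
            if len(pts) < 3:
                continue
            out.append(ContourPolygon(slice_index=k, points=pts))
    return out


# ---------------------------------------------------------------------------
# RTSTRUCT reading/writing


def read_rtstruct(file: str | Path, volume: CTVolume) -> StructureSet:
    """Read an RT Structure Set and rasterize every ROI onto the CT grid.

    The file must reference the volume's frame of reference.  ROIs without
    contour data are kept as empty masks with a warning.
    """
    ds = pydicom.dcmread(file)
    frames = set()
    for ref in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        frames.add(ref.FrameOfReferenceUID)
    for roi in getattr(ds, "StructureSetROISequence", []):
        if "ReferencedFrameOfReferenceUID" in roi:
            frames.add(roi.ReferencedFrameOfReferenceUID)
    if volume.frame_of_reference_uid and frames and volume.frame_of_reference_uid not in frames:
        raise DicomIOError(
            f"structure set frame of reference {sorted(frames)} does not match "
            f"CT frame {volume.frame_of_reference_uid}"
        )

    roi_meta = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    structs = StructureSet(ct_ref=volume.series_uid)
    contour_seqs = {
        int(rc.ReferencedROINumber): rc for rc in getattr(ds, "ROIContourSequence", [])
    }
    for number, name in roi_meta.items():
        rc = contour_seqs.get(number)
        color = (255, 0, 0)
        polygons: List[ContourPolygon] = []
        if rc is not None:
            if "ROIDisplayColor" in rc:
                color = tuple(int(v) for v in rc.ROIDisplayColor)
            for c in getattr(rc, "ContourSequence", []):
                data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
                if len(data) < 3:
                    raise DicomIOError(f"ROI {name!r} has a contour with < 3 points")
                z = float(np.mean(data[:, 2]))
                k = int(np.argmin(np.abs(volume.slice_positions - z)))
                polygons.append(ContourPolygon(slice_index=k, points=data))
        if not polygons:
            warnings.warn(f"ROI {name!r} has no contour data; kept as empty mask")
            mask = np.zeros(volume.shape, dtype=bool)
        else:
            mask = contours_to_mask(polygons, volume)
        structs.add(name, mask, number=number, color=color)
    return structs


def _base_file_dataset(sop_class: str, sop_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    return ds


def write_rtstruct(
    structs: StructureSet,
    volume: CTVolume,
    out: str | Path,
    uid_root: str = DEFAULT_UID_ROOT,
    label: str = "autocontour",
) -> Path:
    """Write a DICOM-compliant RT Structure Set for ``structs`` on ``volume``.

    Each contour references the SOP instance UID of the CT slice it lies on.
    Returns the written path.
    """
    out = Path(out)
    if not structs.rois:
        warnings.warn("writing a structure set with zero ROIs")

    sop_uid = generate_uid(prefix=uid_root)
    ds = _base_file_dataset(RTSTRUCT_STORAGE, sop_uid)
    ds.Modality = "RTSTRUCT"
    ds.Manufacturer = "autocontour"
    ds.PatientID = volume.patient_id or "anonymous"
    ds.PatientName = ds.PatientID
    ds.StructureSetLabel = label
    ds.StructureSetDate = ""
    ds.StructureSetTime = ""
    ds.StudyInstanceUID = generate_uid(prefix=uid_root)
    ds.SeriesInstanceUID = generate_uid(prefix=uid_root)
    ds.FrameOfReferenceUID = volume.frame_of_reference_uid

    # Referenced Frame of Reference -> study -> series -> CT slices
    contour_image_seq = []
    for uid in volume.sop_instance_uids:
        item = Dataset()
        item.ReferencedSOPClassUID = CT_IMAGE_STORAGE
        item.ReferencedSOPInstanceUID = uid
        contour_image_seq.append(item)
    series_item = Dataset()
    series_item.SeriesInstanceUID = volume.series_uid
    series_item.ContourImageSequence = contour_image_seq
    study_item = Dataset()
    study_item.ReferencedSOPClassUID = "1.2.840.10008.3.1.2.3.1"
    study_item.ReferencedSOPInstanceUID = generate_uid(prefix=uid_root)
    study_item.RTReferencedSeriesSequence = [series_item]
    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = volume.frame_of_reference_uid
    ref_frame.RTReferencedStudySequence = [study_item]
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ss_rois, roi_contours, observations = [], [], []
    for name, roi in structs.rois.items():
        ss_roi = Dataset()
        ss_roi.ROINumber = roi.number
        ss_roi.ReferencedFrameOfReferenceUID = volume.frame_of_reference_uid
        ss_roi.ROIName = name
        ss_roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ss_rois.append(ss_roi)

        rc = Dataset()
        rc.ROIDisplayColor = list(roi.color)
        rc.ReferencedROINumber = roi.number
        contour_seq = []
        for poly in mask_to_contours(roi.mask, volume):
            c = Dataset()
            img = Dataset()
            img.ReferencedSOPClassUID = CT_IMAGE_STORAGE
            img.ReferencedSOPInstanceUID = volume.sop_instance_uids[poly.slice_index]
            c.ContourImageSequence = [img]
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly.points)
            c.ContourData = [float(v) for v in poly.points.ravel()]
            contour_seq.append(c)
        rc.ContourSequence = contour_seq
        roi_contours.append(rc)

        obs = Dataset()
        obs.ObservationNumber = roi.number
        obs.ReferencedROINumber = roi.number
        obs.ROIObservationLabel = name
        obs.RTROIInterpretedType = "ORGAN"
        obs.ROIInterpreter = ""
        observations.append(obs)

    ds.StructureSetROISequence = ss_rois
    ds.ROIContourSequence = roi_contours
    ds.RTROIObservationsSequence = observations

    out.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(out, enforce_file_format=True)
    return out
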