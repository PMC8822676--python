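"""Deterministic synthetic head phantoms: CT series + ground-truth RTSTRUCT.

Each phantom is a soft-tissue elliptical "head" (~40 HU) wrapped in a bony
ring (~700 HU) on an air background (-1000 HU), with ellipsoid/cylinder
"organs" of distinct HU embedded inside, plus seeded Gaussian noise.  The
ground-truth masks are the exact pre-noise organ supports.  Geometry mimics
the head-and-neck planning-CT protocol the pipeline targets: 512x512 pixels,
sub-millimeter in-plane spacing (deliberately not 1.0 mm, so resampling is
always exercised), 2.5 mm slices.

Organ contrast is exaggerated relative to real anatomy: the cohort validates
plumbing and learnability, not clinical difficulty.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pydicom
from pydicom.uid import ExplicitVRLittleEndian

from . import dicom_io
from .dicom_io import (
    CT_IMAGE_STORAGE,
    CTVolume,
    DEFAULT_UID_ROOT,
    StructureSet,
    write_rtstruct,
)

__all__ = [
    "OrganShape",
    "PhantomSpec",
    "default_organs",
    "generate_phantom",
    "write_phantom_dicom",
    "make_cohort",
]

_COLORS = [(255, 85, 0), (0, 170, 255), (0, 200, 80), (230, 0, 126),
           (255, 210, 0), (140, 90, 255)]


@dataclass(frozen=True)
class OrganShape:
    """One synthetic organ: an ellipsoid or a cylinder in patient mm."""

    name: str
    shape: str  # "ellipsoid" | "cylinder"
    center_mm: Tuple[float, float, float]  # (x, y, z)
    semi_axes_mm: Tuple[float, float, float]  # (ax, ay, az)
    hu: float

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "cylinder"):
            raise ValueError(f"unknown organ shape {self.shape!r}")


def default_organs(z_center: float = 25.0) -> List[OrganShape]:
    """Three-organ default set: a midline cylinder and two lateral ellipsoids.

    HU values keep >= 80 HU contrast against the 40 HU soft-tissue body;
    ``z_center`` places the organs along the scan axis (mid-volume by
    default for the shipped 20-slice phantom).
    """
    return [
        OrganShape("brainstem", "cylinder", (0.0, 25.0, z_center), (8.0, 8.0, 6.0), 160.0),
        OrganShape("parotid_l", "ellipsoid", (-45.0, 5.0, z_center), (12.0, 9.0, 7.0), 320.0),
        OrganShape("parotid_r", "ellipsoid", (45.0, 5.0, z_center), (12.0, 9.0, 7.0), 320.0),
    ]


@dataclass
class PhantomSpec:
    """Geometry and intensities of one synthetic head phantom."""

    matrix: Tuple[int, int] = (512, 512)  # (rows, cols)
    n_slices: int = 20
    pixel_spacing: Tuple[float, float] = (0.977, 0.977)  # (row, col) mm
    slice_thickness: float = 2.5
    body_semi_axes: Tuple[float, float] = (80.0, 100.0)  # (x, y) mm
    body_hu: float = 40.0
    skull_frac: float = 0.88  # skull ring spans [skull_frac, 1.0] of the body ellipse
    skull_hu: float = 700.0
    air_hu: float = -1000.0
    organs: List[OrganShape] | None = None  # None -> default set, mid-volume
    noise_sd: float = 8.0  # HU
    seed: int = 0
    patient_id: str = "phantom_000"

    def __post_init__(self):
        if self.organs is None:
            self.organs = default_organs(
                z_center=(self.n_slices - 1) * self.slice_thickness / 2.0
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.n_slices, self.matrix[0], self.matrix[1])


def _grids_mm(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Patient-coordinate grids; the in-plane center of the image is (0, 0)."""
    rows, cols = spec.matrix
    row_sp, col_sp = spec.pixel_spacing
    x = (np.arange(cols) - (cols - 1) / 2.0) * col_sp
    y = (np.arange(rows) - (rows - 1) / 2.0) * row_sp
    z = np.arange(spec.n_slices) * spec.slice_thickness
    xx, yy = np.meshgrid(x, y)
    return xx, yy, z


def _uid(spec_or_id: str, kind: str, i: int = 0, root: str = DEFAULT_UID_ROOT) -> str:
    """Deterministic DICOM UID from a patient id and object kind."""
    h = hashlib.md5(f"{spec_or_id}/{kind}".encode()).hexdigest()
    return f"{root}{int(h[:12], 16)}.{i}"


def generate_phantom(spec: PhantomSpec) -> Tuple[CTVolume, StructureSet]:
    """Paint the phantom volume and its exact ground-truth structure set.

    Raises if any organ support leaves the soft-tissue body.  Fixed seed
    means bitwise-identical output.
    """
    xx, yy, z = _grids_mm(spec)
    ax, ay = spec.body_semi_axes
    body2d = (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0
    inner2d = (xx / (ax * spec.skull_frac)) ** 2 + (yy / (ay * spec.skull_frac)) ** 2 <= 1.0
    skull2d = body2d & ~inner2d

    hu = np.full(spec.shape, spec.air_hu, dtype=np.float32)
    hu[:, body2d] = spec.body_hu
    hu[:, skull2d] = spec.skull_hu

    structs = StructureSet(ct_ref=_uid(spec.patient_id, "series"))
    for idx, organ in enumerate(spec.organs):
        cx, cy, cz = organ.center_mm
        sx, sy, sz = organ.semi_axes_mm
        r2 = ((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2
        mask = np.zeros(spec.shape, dtype=bool)
        for k, zk in enumerate(z):
            if organ.shape == "ellipsoid":
                rz = ((zk - cz) / sz) ** 2
                if rz > 1.0:
                    continue
                mask[k] = r2 <= 1.0 - rz
            else:  # cylinder
                if abs(zk - cz) <= sz:
                    mask[k] = r2 <= 1.0
        if not mask.any():
            raise ValueError(f"organ {organ.name!r} has empty support on this grid")
        if np.any(mask & ~inner2d[None, :, :]):
            raise ValueError(f"organ {organ.name!r} extends outside the body")
        for k in range(spec.n_slices):
            hu[k][mask[k]] = organ.hu
        structs.add(organ.name, mask, number=idx + 1,
                    color=_COLORS[idx % len(_COLORS)])

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)

    rows, cols = spec.matrix
    row_sp, col_sp = spec.pixel_spacing
    origin = (
        -(cols - 1) / 2.0 * col_sp,
        -(rows - 1) / 2.0 * row_sp,
        0.0,
    )
    volume = CTVolume(
        voxels=hu,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        slice_positions=z.astype(float),
        origin=origin,
        orientation=(1, 0, 0, 0, 1, 0),
        sop_instance_uids=[_uid(spec.patient_id, "sop", k) for k in range(spec.n_slices)],
        series_uid=_uid(spec.patient_id, "series"),
        frame_of_reference_uid=_uid(spec.patient_id, "frame"),
        patient_id=spec.patient_id,
    )
    volume.validate()
    return volume, structs


def write_phantom_dicom(volume: CTVolume, structs: StructureSet,
                        out_dir: str | Path) -> Dict[str, object]:
    """Write one CT file per slice plus an RTSTRUCT referencing the series.

    Stored pixels are integer HU with slope 1 / intercept -1024, so reading
    the series back recovers HU within the 0.5 HU rounding quantum.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study_uid = _uid(volume.patient_id, "study")
    intercept = 0.0  # signed storage: stored pixel == rounded HU
    ct_paths = []
    for k in range(volume.n_slices):
        sop_uid = volume.sop_instance_uids[k]
        ds = dicom_io._base_file_dataset(CT_IMAGE_STORAGE, sop_uid)
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id
        ds.PatientName = volume.patient_id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = volume.series_uid
        ds.FrameOfReferenceUID = volume.frame_of_reference_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            volume.origin[0], volume.origin[1], float(volume.slice_positions[k]),
        ]
        ds.ImageOrientationPatient = [float(v) for v in volume.orientation]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = volume.slice_thickness
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = volume.voxels.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed stored values
        stored = np.round(volume.voxels[k] - intercept)
        stored = np.clip(stored, -32768, 32767).astype(np.int16)
        ds.PixelData = stored.tobytes()
        path = out_dir / f"CT_{k:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        ct_paths.append(path)
    rs_path = write_rtstruct(structs, volume, out_dir / "RS_truth.dcm",
                             label="ground_truth")
    return {"ct": ct_paths, "rtstruct": rs_path}


def make_cohort(
    n_patients: int,
    out_dir: str | Path,
    base_spec: PhantomSpec | None = None,
    center_jitter_mm: Tuple[float, float, float] = (6.0, 6.0, 2.5),
    axis_jitter_frac: float = 0.10,
    seed: int = 0,
) -> Path:
    """Generate ``n_patients`` perturbed phantoms as DICOM directory trees.

    Organ centers and semi-axes are jittered per patient with seeds derived
    deterministically from the cohort seed; an organ pushed outside the body
    is re-jittered (up to 100 tries).  Writes ``manifest.csv`` listing each
    patient's ground-truth organ heights and returns its path.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs >= 2 patients")
    base = base_spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["patient_id,organ,height_mm,center_x,center_y,center_z"]
    for i in range(n_patients):
        child_seed = int(
            np.random.SeedSequence([seed, i]).generate_state(1, np.uint32)[0]
        )
        rng = np.random.default_rng(child_seed)
        pid = f"phantom_{i:03d}"
        for attempt in range(100):
            organs = []
            for organ in base.organs:
                jc = rng.uniform(-1, 1, 3) * np.asarray(center_jitter_mm)
                ja = rng.uniform(1 - axis_jitter_frac, 1 + axis_jitter_frac, 3)
                organs.append(replace(
                    organ,
                    center_mm=tuple(np.asarray(organ.center_mm) + jc),
                    semi_axes_mm=tuple(np.asarray(organ.semi_axes_mm) * ja),
                ))
            spec = replace(base, organs=organs, seed=child_seed + attempt,
                           patient_id=pid)
            try:
                volume, structs = generate_phantom(spec)
                break
            except ValueError:
                continue
        else:
            raise ValueError(f"could not place organs inside the body for {pid}")
        write_phantom_dicom(volume, structs, out_dir / pid)
        for organ in organs:
            mask = structs.rois[organ.name].mask
            pos = np.flatnonzero(mask.any(axis=(1, 2)))
            height = float((pos.max() - pos.min() + 1) * spec.slice_thickness)
            cx, cy, cz = organ.center_mm
            rows.append(f"{pid},{organ.name},{height},{cx:.3f},{cy:.3f},{cz:.3f}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
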