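"""Normalization chain from calibrated CT to the 2D network representation.

Every slice fed to the network goes through the same chain: in-plane
resampling to 1 mm pixels, a central 256x256 crop, and a window/level map
onto [0, 1].  Labels follow the same geometry with nearest-neighbor
interpolation.  Training sets additionally keep, of the slices with no organ
label, only every 20th — a class-balance rule for small organs that appear
on a handful of slices of a long scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .dicom_io import CTVolume, StructureSet

__all__ = [
    "WindowPreset",
    "TISSUE_WINDOW",
    "BONE_WINDOW",
    "WINDOW_PRESETS",
    "OrganConfig",
    "DEFAULT_ORGANS",
    "AXIAL_LIMITED_ORGANS",
    "TrainingSample",
    "CROP_SIZE",
    "PAD_HU",
    "resample_inplane",
    "resample_mask_inplane",
    "center_crop",
    "uncrop_center",
    "window_normalize",
    "select_training_slices",
    "build_dataset",
    "preprocess_slice",
]

CROP_SIZE = 256
PAD_HU = -1000.0  # air, for undersized fields of view
EMPTY_SLICE_STRIDE = 20


@dataclass(frozen=True)
class WindowPreset:
    """A window/level display filter: HU in [L - W/2, L + W/2] maps to [0, 1]."""

    name: str
    width_W: float
    level_L: float

    def __post_init__(self):
        if self.width_W <= 0:
            raise ValueError("window width must be positive")


TISSUE_WINDOW = WindowPreset("tissue", 400.0, 40.0)
BONE_WINDOW = WindowPreset("bone", 2000.0, 400.0)
WINDOW_PRESETS: Dict[str, WindowPreset] = {
    "tissue": TISSUE_WINDOW,
    "bone": BONE_WINDOW,
}


@dataclass
class OrganConfig:
    """Per-organ settings: window preset and axial-limit behavior.

    ``axial_k`` is the SD multiplier (1 or 2) for the post-processing height
    cap; organs not subject to the cap carry ``axial_limited=False``.
    """

    name: str
    window: str = "tissue"
    axial_limited: bool = False
    axial_k: int = 2
    height_mean: float | None = None
    height_sd: float | None = None

    def __post_init__(self):
        if self.window not in WINDOW_PRESETS:
            raise ValueError(f"unknown window preset {self.window!r}")
        if self.axial_k not in (1, 2):
            raise ValueError("axial_k must be 1 or 2")

    @property
    def window_preset(self) -> WindowPreset:
        return WINDOW_PRESETS[self.window]


#: Organs whose predictions get the height cap (mean + k.SD of training heights).
AXIAL_LIMITED_ORGANS = {
    "parotid_l", "parotid_r", "submandibular_l", "submandibular_r",
    "brainstem", "larynx",
}

#: The eleven head-and-neck organs at risk; spinal cord and brachial plexus
#: use the bone window, everything else the tissue window.
DEFAULT_ORGANS: Dict[str, OrganConfig] = {
    name: OrganConfig(
        name=name,
        window="bone" if name in ("spinal_cord", "brachial_plexus") else "tissue",
        axial_limited=name in AXIAL_LIMITED_ORGANS,
    )
    for name in (
        "brain", "brainstem", "cochlea_l", "cochlea_r",
        "parotid_l", "parotid_r", "submandibular_l", "submandibular_r",
        "larynx", "spinal_cord", "brachial_plexus",
    )
}


def get_organ_config(name: str) -> OrganConfig:
    """Config for ``name``, falling back to a tissue-window default."""
    key = name.lower()
    if key in DEFAULT_ORGANS:
        return replace(DEFAULT_ORGANS[key])
    return OrganConfig(name=name)


@dataclass
class TrainingSample:
    """One preprocessed image/label pair for one organ.

    ``image`` is 256x256 in [0, 1]; ``label`` the matching binary ground
    truth; provenance keeps the sample traceable to its patient and slice.
    """

    image: np.ndarray
    label: np.ndarray
    organ: str
    patient_id: str
    slice_index: int


# ---------------------------------------------------------------------------
# Geometry


def _resample_slice(img: np.ndarray, spacing: Tuple[float, float], order: int) -> np.ndarray:
    rows, cols = img.shape
    row_sp, col_sp = spacing
    if row_sp <= 0 or col_sp <= 0:
        raise ValueError("pixel spacing must be positive")
    out_rows = int(round(rows * row_sp))
    out_cols = int(round(cols * col_sp))
    # output pixel j sits at j*1.0 mm from the first pixel center, i.e. at
    # fractional input index j / spacing
    rr = np.arange(out_rows, dtype=np.float64) / row_sp
    cc = np.arange(out_cols, dtype=np.float64) / col_sp
    coords = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(
        img.astype(np.float64), coords, order=order, mode="nearest"
    )


def resample_inplane(volume: CTVolume) -> CTVolume:
    """Bilinearly resample each slice to exactly 1.0 x 1.0 mm pixels.

    Through-plane geometry is untouched (2D slice model).  A volume already
    at 1 mm is returned with voxels unchanged.
    """
    row_sp, col_sp = volume.pixel_spacing
    if row_sp <= 0 or col_sp <= 0:
        raise ValueError("pixel spacing must be positive")
    if row_sp == 1.0 and col_sp == 1.0:
        return volume
    slices = [
        _resample_slice(volume.voxels[k], volume.pixel_spacing, order=1)
        for k in range(volume.n_slices)
    ]
    return CTVolume(
        voxels=np.stack(slices).astype(np.float32),
        pixel_spacing=(1.0, 1.0),
        slice_thickness=volume.slice_thickness,
        slice_positions=volume.slice_positions,
        origin=volume.origin,
        orientation=volume.orientation,
        sop_instance_uids=volume.sop_instance_uids,
        series_uid=volume.series_uid,
        frame_of_reference_uid=volume.frame_of_reference_uid,
        patient_id=volume.patient_id,
    )


def resample_mask_inplane(mask: np.ndarray, spacing: Tuple[float, float]) -> np.ndarray:
    """Nearest-neighbor in-plane resampling of a binary volume to 1 mm pixels."""
    mask = np.asarray(mask)
    if spacing[0] == 1.0 and spacing[1] == 1.0:
        return mask.astype(bool)
    out = [
        _resample_slice(mask[k].astype(np.float64), spacing, order=0)
        for k in range(mask.shape[0])
    ]
    return np.stack(out) > 0.5


def _crop_window(dim: int, size: int) -> Tuple[int, int]:
    """(source offset, destination offset) for a central crop/pad along one axis."""
    if dim >= size:
        return (dim - size) // 2, 0
    return 0, (size - dim) // 2


def center_crop(image2d: np.ndarray, size: int = CROP_SIZE, pad_value: float = PAD_HU) -> np.ndarray:
    """Take the centermost ``size``x``size`` window; pad smaller inputs.

    Larger axes are cropped at offset ``(dim - size) // 2``; smaller axes are
    centered in a field of ``pad_value``.
    """
    image2d = np.asarray(image2d)
    rows, cols = image2d.shape
    out = np.full((size, size), pad_value, dtype=image2d.dtype)
    r_src, r_dst = _crop_window(rows, size)
    c_src, c_dst = _crop_window(cols, size)
    nr, nc = min(rows, size), min(cols, size)
    out[r_dst:r_dst + nr, c_dst:c_dst + nc] = image2d[r_src:r_src + nr, c_src:c_src + nc]
    return out


def uncrop_center(image2d: np.ndarray, target_shape: Tuple[int, int],
                  fill_value: float = 0.0) -> np.ndarray:
    """Inverse of :func:`center_crop`: place a crop back onto the full grid."""
    size = image2d.shape[0]
    rows, cols = target_shape
    out = np.full(target_shape, fill_value, dtype=image2d.dtype)
    r_src, r_dst = _crop_window(rows, size)
    c_src, c_dst = _crop_window(cols, size)
    nr, nc = min(rows, size), min(cols, size)
    out[r_src:r_src + nr, c_src:c_src + nc] = image2d[r_dst:r_dst + nr, c_dst:c_dst + nc]
    return out


def window_normalize(image2d: np.ndarray, preset: WindowPreset) -> np.ndarray:
    """Map HU linearly so [L - W/2, L + W/2] spans [0, 1], clamping outside."""
    if preset.width_W <= 0:
        raise ValueError("window width must be positive")
    lo = preset.level_L - preset.width_W / 2.0
    out = (np.asarray(image2d, dtype=np.float32) - lo) / preset.width_W
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Slice selection and dataset assembly


def select_training_slices(label_volume: np.ndarray) -> List[int]:
    """Indices to train on: all labeled slices plus every 20th empty slice.

    Empty slices are enumerated in ascending order and positions 0, 20, 40,
    ... of that list are kept.  A volume with no labeled slice returns an
    empty list — the signal that this patient lacks the organ (any present
    organ yields at least one index).
    """
    label_volume = np.asarray(label_volume)
    positive = np.where(label_volume.any(axis=(1, 2)))[0]
    if positive.size == 0:
        return []
    empty = np.setdiff1d(np.arange(label_volume.shape[0]), positive)
    keep = np.union1d(positive, empty[::EMPTY_SLICE_STRIDE])
    return [int(i) for i in keep]


def preprocess_slice(hu_slice_1mm: np.ndarray, preset: WindowPreset) -> np.ndarray:
    """Crop then window one already-resampled HU slice into the network frame."""
    return window_normalize(center_crop(hu_slice_1mm), preset)


def _patient_samples(volume: CTVolume, mask: np.ndarray, organ: OrganConfig) -> List[TrainingSample]:
    rvol = resample_inplane(volume)
    rmask = resample_mask_inplane(mask, volume.pixel_spacing)
    indices = select_training_slices(rmask)
    preset = organ.window_preset
    samples = []
    for k in indices:
        img = preprocess_slice(rvol.voxels[k], preset)
        lab = center_crop(rmask[k].astype(np.float32), pad_value=0.0) > 0.5
        samples.append(
            TrainingSample(
                image=img.astype(np.float32),
                label=lab,
                organ=organ.name,
                patient_id=volume.patient_id,
                slice_index=k,
            )
        )
    return samples


def build_dataset(
    patients: Sequence[Tuple[CTVolume, StructureSet]],
    organ: OrganConfig,
    val_fraction: float = 0.15,
) -> Tuple[List[TrainingSample], List[TrainingSample]]:
    """Assemble (train, validation) samples for one organ across a cohort.

    The full chain (resample, crop, window, slice selection) runs per
    patient; patients without the organ are excluded.  The last
    ``ceil(val_fraction * n)`` eligible patients (stable input order) form
    the validation partition, so no patient contributes slices to both.
    """
    eligible: List[Tuple[CTVolume, np.ndarray]] = []
    for volume, structs in patients:
        roi = structs.rois.get(organ.name)
        if roi is None:
            for name, r in structs.rois.items():
                if name.lower() == organ.name.lower():
                    roi = r
                    break
        if roi is None or not roi.mask.any():
            continue
        eligible.append((volume, roi.mask))
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 patients with organ {organ.name!r}, found {len(eligible)}"
        )
    n_val = math.ceil(val_fraction * len(eligible))
    train_patients = eligible[: len(eligible) - n_val]
    val_patients = eligible[len(eligible) - n_val:]
    train = [s for vol, m in train_patients for s in _patient_samples(vol, m, organ)]
    val = [s for vol, m in val_patients for s in _patient_samples(vol, m, organ)]
    return train, val
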