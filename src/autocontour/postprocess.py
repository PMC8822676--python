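"""Clean raw probability volumes into single-structure binary masks.

Three rules, applied in order: binarize at 0.33, keep only the largest
26-connected 3D component (everything discontinuous is an outlier), and —
for the parotid glands, submandibular glands, brainstem and larynx — cap the
cranio-caudal extent at the training cohort's mean organ height plus one or
two standard deviations.  Every stage only removes voxels, so the composed
pipeline is shrinking and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
from scipy import ndimage

from .model import PredictionVolume
from .preprocess import OrganConfig

__all__ = [
    "HeightStats",
    "DEFAULT_THRESHOLD",
    "binarize",
    "largest_component",
    "measure_height",
    "fit_height_stats",
    "apply_axial_limit",
    "postprocess_prediction",
]

DEFAULT_THRESHOLD = 0.33
_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass(frozen=True)
class HeightStats:
    """Cranio-caudal height statistics of one organ over training patients.

    ``height_sd`` uses the sample (n-1) denominator.
    """

    organ: str
    height_mean: float  # mm
    height_sd: float  # mm
    n: int

    def __post_init__(self):
        if self.height_mean <= 0 or self.height_sd < 0 or self.n < 2:
            raise ValueError("invalid height statistics")

    def limit(self, k: int) -> float:
        if k not in (1, 2):
            raise ValueError("axial-limit multiplier k must be 1 or 2")
        return self.height_mean + k * self.height_sd


def binarize(pred: PredictionVolume | np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Voxel set iff probability >= threshold (ties count as positive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    probs = pred.probs if isinstance(pred, PredictionVolume) else np.asarray(pred)
    return probs >= threshold


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected 3D component.

    Size ties break to the component with the smallest minimum slice index,
    then the smallest minimum row index.  Empty input passes through.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n <= 1:
        return mask.copy()
    sizes = np.bincount(labels.ravel())[1:]
    best = None
    for lab in np.flatnonzero(sizes == sizes.max()) + 1:
        sl, rw, _ = np.nonzero(labels == lab)
        key = (int(sl.min()), int(rw.min()))
        if best is None or key < best[0]:
            best = (key, lab)
    return labels == best[1]


def measure_height(mask: np.ndarray, slice_thickness: float) -> float:
    """Cranio-caudal extent in mm: (occupied slice span) x slice thickness."""
    mask = np.asarray(mask, dtype=bool)
    pos = np.flatnonzero(mask.any(axis=(1, 2)))
    if pos.size == 0:
        return 0.0
    return float((pos.max() - pos.min() + 1) * slice_thickness)


def fit_height_stats(masks_by_patient: Mapping[str, np.ndarray], organ: str,
                     slice_thickness: float) -> HeightStats:
    """Mean and sample SD of organ height across >= 2 training patients."""
    heights = [
        measure_height(m, slice_thickness)
        for m in masks_by_patient.values()
        if np.asarray(m).any()
    ]
    if len(heights) < 2:
        raise ValueError(f"need >= 2 patients with organ {organ!r} to fit heights")
    arr = np.asarray(heights, dtype=float)
    return HeightStats(
        organ=organ,
        height_mean=float(arr.mean()),
        height_sd=float(arr.std(ddof=1)),
        n=len(heights),
    )


def apply_axial_limit(mask: np.ndarray, stats: HeightStats, k: int,
                      slice_thickness: float) -> np.ndarray:
    """Trim slices until the mask's height fits within mean + k.SD.

    Whole end slices farthest from the mask's center-of-mass slice are
    removed first, alternating between the two far ends as distances dictate;
    on a tie the superior (higher-index) end is trimmed.  If the limit is
    below one slice thickness only the positive slice nearest the center of
    mass survives.
    """
    limit = stats.limit(k)  # validates k
    mask = np.asarray(mask, dtype=bool).copy()
    pos = np.flatnonzero(mask.any(axis=(1, 2)))
    if pos.size == 0:
        return mask
    counts = mask.sum(axis=(1, 2)).astype(float)
    com = float(np.average(np.arange(mask.shape[0]), weights=counts))
    lo, hi = int(pos.min()), int(pos.max())
    occupied = set(int(i) for i in pos)

    def height() -> float:
        return (hi - lo + 1) * slice_thickness

    while height() > limit and lo < hi:
        if (hi - com) >= (com - lo):
            mask[hi] = False
            occupied.discard(hi)
        else:
            mask[lo] = False
            occupied.discard(lo)
        if not occupied:
            break
        lo, hi = min(occupied), max(occupied)
    if slice_thickness > limit:
        keep = min(occupied, key=lambda i: (abs(i - com), i))
        out = np.zeros_like(mask)
        out[keep] = mask[keep]
        return out
    return mask


def postprocess_prediction(pred: PredictionVolume | np.ndarray, organ: OrganConfig,
                           stats: HeightStats | None = None,
                           slice_thickness: float = 2.5,
                           threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold, keep the largest volume, then (for the four capped organs)
    apply the axial height limit.

    ``stats`` may be omitted for organs that are not axially limited; for
    limited organs it is required.
    """
    mask = largest_component(binarize(pred, threshold))
    if organ.axial_limited:
        if stats is None:
            if organ.height_mean is None or organ.height_sd is None:
                raise ValueError(
                    f"organ {organ.name!r} is axially limited but no height "
                    "statistics were provided"
                )
            stats = HeightStats(organ.name, organ.height_mean, organ.height_sd, n=2)
        mask = apply_axial_limit(mask, stats, organ.axial_k, slice_thickness)
        # slice trimming can split the component; keep the output single-piece
        mask = largest_component(mask)
    return mask
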