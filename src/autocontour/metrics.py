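"""Contour agreement metrics and the paired statistical comparison.

Conventions (these matter — surface metrics are convention-sensitive):

* The surface of a mask is the set of *centers* of positive voxels with at
  least one face-adjacent (6-connectivity) background or out-of-bounds
  neighbor, scaled to mm by the (slice, row, col) spacing.
* MSD is the symmetric mean of directed nearest-surface distances,
  ``(mean_a min_b d(a,b) + mean_b min_a d(b,a)) / 2``.
* HD95 pools both directed nearest-distance multisets and takes the 95th
  percentile (linear interpolation) of the pooled multiset.
* DSC of two empty masks is 1.0 (agreement on absence); surface metrics on
  an empty mask are undefined and reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats
from scipy.spatial import cKDTree

from .dicom_io import StructureSet

__all__ = [
    "EvalRecord",
    "PairedTestResult",
    "CohortEvaluation",
    "dsc",
    "surface_voxels",
    "mean_surface_distance",
    "hausdorff95",
    "paired_ttest",
    "evaluate_cohort",
]

SIGNIFICANCE_LEVEL = 0.05
_FACE_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class EvalRecord:
    """Scores for one patient x organ x method triple."""

    patient_id: str
    organ: str
    method: str
    dsc: float
    msd: float  # mm; NaN if undefined
    hd95: float  # mm; NaN if undefined


@dataclass(frozen=True)
class PairedTestResult:
    """Two-tailed paired Student t test between two methods on one metric."""

    organ: str
    metric: str
    t: float
    p: float
    n: int
    significant: bool
    n_dropped: int = 0


def _check_shapes(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A.B| / (|A| + |B|)``; both empty -> 1."""
    a, b = _check_shapes(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def surface_voxels(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Centers (mm) of positive voxels on the mask boundary, as an (n, 3) array.

    A voxel is on the boundary if any 6-connected neighbor is background or
    out of bounds.  ``spacing`` is (slice, row, col) mm.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3))
    interior = ndimage.binary_erosion(mask, structure=_FACE_CONN, border_value=0)
    surf = mask & ~interior
    idx = np.column_stack(np.nonzero(surf)).astype(float)
    return idx * np.asarray(spacing, dtype=float)


def _directed_distances(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    return cKDTree(b_pts).query(a_pts, k=1)[0]


def mean_surface_distance(a: np.ndarray, b: np.ndarray,
                          spacing: Sequence[float]) -> float:
    """Symmetric mean surface distance in mm; NaN if either mask is empty."""
    a, b = _check_shapes(a, b)
    if not a.any() or not b.any():
        return float("nan")
    sa = surface_voxels(a, spacing)
    sb = surface_voxels(b, spacing)
    return 0.5 * (
        float(_directed_distances(sa, sb).mean())
        + float(_directed_distances(sb, sa).mean())
    )


def hausdorff95(a: np.ndarray, b: np.ndarray, spacing: Sequence[float]) -> float:
    """95th percentile of the pooled directed nearest-surface distances, mm."""
    a, b = _check_shapes(a, b)
    if not a.any() or not b.any():
        return float("nan")
    sa = surface_voxels(a, spacing)
    sb = surface_voxels(b, spacing)
    pooled = np.concatenate(
        [_directed_distances(sa, sb), _directed_distances(sb, sa)]
    )
    return float(np.percentile(pooled, 95))


def paired_ttest(x: Sequence[float], y: Sequence[float], organ: str = "",
                 metric: str = "") -> PairedTestResult:
    """Paired two-tailed Student t test on matched per-patient scores.

    NaN scores are dropped pairwise (count reported).  All-equal differences
    give t=0, p=1 by convention; zero-variance nonzero differences give an
    infinite t with p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    d = x[ok] - y[ok]
    n = len(d)
    if n < 2:
        raise ValueError("paired t test needs >= 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(d.mean()) * np.inf), 0.0
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2.0 * sstats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(
        organ=organ, metric=metric, t=t, p=p, n=n,
        significant=p < SIGNIFICANCE_LEVEL, n_dropped=n_dropped,
    )


@dataclass
class CohortEvaluation:
    """Tables produced by :func:`evaluate_cohort`."""

    records: pd.DataFrame  # one row per patient x organ x method
    tests: pd.DataFrame  # one row per organ x metric x method pair
    summary: pd.DataFrame  # mean +/- sd per organ x metric x method

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.tests.to_csv(out / "paired_tests.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)


def evaluate_cohort(
    predictions: Mapping[str, Mapping[str, StructureSet]],
    truths: Mapping[str, StructureSet],
    spacing: Mapping[str, Sequence[float]] | Sequence[float],
) -> CohortEvaluation:
    """Score every method against ground truth and run paired comparisons.

    ``predictions`` maps method -> patient -> StructureSet; ``truths`` maps
    patient -> StructureSet; ``spacing`` is per-patient (slice, row, col) mm
    or one tuple for all.  Patients missing from a method are excluded from
    that method's paired tests (reported via n).  Surface metrics are pooled
    as NaN where a mask is empty.
    """
    organs: List[str] = []
    for ss in truths.values():
        for name in ss.names():
            if name not in organs:
                organs.append(name)

    def spac(pid: str) -> Sequence[float]:
        if isinstance(spacing, Mapping):
            return spacing[pid]
        return spacing

    rows = []
    for method, per_patient in predictions.items():
        for pid, truth_ss in truths.items():
            pred_ss = per_patient.get(pid)
            if pred_ss is None:
                continue
            for organ in organs:
                t_roi = truth_ss.rois.get(organ)
                p_roi = pred_ss.rois.get(organ)
                if t_roi is None:
                    continue
                tmask = t_roi.mask
                pmask = p_roi.mask if p_roi is not None else np.zeros_like(tmask)
                sp = spac(pid)
                rows.append(EvalRecord(
                    patient_id=pid, organ=organ, method=method,
                    dsc=dsc(tmask, pmask),
                    msd=mean_surface_distance(tmask, pmask, sp),
                    hd95=hausdorff95(tmask, pmask, sp),
                ))
    records = pd.DataFrame([r.__dict__ for r in rows])

    tests_rows = []
    methods = list(predictions)
    if not records.empty:
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                m1, m2 = methods[i], methods[j]
                for organ in organs:
                    sub1 = records[(records.method == m1) & (records.organ == organ)]
                    sub2 = records[(records.method == m2) & (records.organ == organ)]
                    common = sorted(set(sub1.patient_id) & set(sub2.patient_id))
                    if len(common) < 2:
                        continue
                    s1 = sub1.set_index("patient_id").loc[common]
                    s2 = sub2.set_index("patient_id").loc[common]
                    for metric in ("dsc", "msd", "hd95"):
                        try:
                            res = paired_ttest(
                                s1[metric].to_numpy(), s2[metric].to_numpy(),
                                organ=organ, metric=metric,
                            )
                        except ValueError:
                            continue
                        tests_rows.append({
                            "organ": organ, "metric": metric,
                            "method_1": m1, "method_2": m2,
                            "t": res.t, "p": res.p, "n": res.n,
                            "significant": res.significant,
                            "n_dropped": res.n_dropped,
                        })
    tests = pd.DataFrame(tests_rows)

    if records.empty:
        summary = pd.DataFrame()
    else:
        long = records.melt(
            id_vars=["patient_id", "organ", "method"],
            value_vars=["dsc", "msd", "hd95"],
            var_name="metric",
        )
        summary = (
            long.groupby(["organ", "metric", "method"], sort=False)["value"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index()
        )
    return CohortEvaluation(records=records, tests=tests, summary=summary)
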