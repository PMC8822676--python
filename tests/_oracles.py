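"""Independent brute-force oracles used across the test modules.

These deliberately avoid the code paths they check: plain Python loops and
O(n^2) scans instead of vectorized/spatial-index implementations.
"""

from __future__ import annotations

import math

import numpy as np

_OFFSETS26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def point_in_polygon(px: float, py: float, poly) -> bool:
    """Even-odd crossing-number test, one point at a time."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def rasterize_polygon(poly, shape):
    """Brute-force pixel-center rasterization on an (rows, cols) grid."""
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            out[r, c] = point_in_polygon(float(c), float(r), poly)
    return out


def flood_components(mask: np.ndarray):
    """26-connected components by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            comp.append((z, y, x))
            for dz, dy, dx in _OFFSETS26:
                q = (z + dz, y + dy, x + dx)
                if (0 <= q[0] < mask.shape[0] and 0 <= q[1] < mask.shape[1]
                        and 0 <= q[2] < mask.shape[2]
                        and mask[q] and not seen[q]):
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


def surface_points_bf(mask: np.ndarray, spacing):
    """Boundary voxel centers in mm, by explicit 6-neighbor checks."""
    mask = np.asarray(mask, dtype=bool)
    pts = []
    nz, ny, nx = mask.shape
    for z, y, x in zip(*np.nonzero(mask)):
        boundary = False
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            q = (z + dz, y + dy, x + dx)
            if not (0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx):
                boundary = True
                break
            if not mask[q]:
                boundary = True
                break
        if boundary:
            pts.append((z * spacing[0], y * spacing[1], x * spacing[2]))
    return np.asarray(pts)


def _all_pairs_min(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    d = np.sqrt(((a_pts[:, None, :] - b_pts[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)


def msd_bf(a, b, spacing) -> float:
    """Symmetric mean surface distance by O(n^2) all-pairs scan."""
    sa = surface_points_bf(a, spacing)
    sb = surface_points_bf(b, spacing)
    return 0.5 * (_all_pairs_min(sa, sb).mean() + _all_pairs_min(sb, sa).mean())


def hd95_bf(a, b, spacing) -> float:
    """Pooled 95th-percentile Hausdorff distance by all-pairs scan."""
    sa = surface_points_bf(a, spacing)
    sb = surface_points_bf(b, spacing)
    pooled = np.concatenate([_all_pairs_min(sa, sb), _all_pairs_min(sb, sa)])
    return float(np.percentile(pooled, 95))


def dsc_bf(a, b) -> float:
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    inter = sum(1 for u, v in zip(a, b) if u and v)
    tot = int(a.sum()) + int(b.sum())
    return 1.0 if tot == 0 else 2.0 * inter / tot


def student_t_sf(t: float, df: int, n_grid: int = 200001) -> float:
    """P(T > t) for Student's t by trapezoid integration of the density.

    The density is written out from the closed form with log-gamma; the
    upper tail beyond the grid is estimated by substitution u = 1/x decay
    (grid reaches far enough that the remainder is negligible at 4 decimals).
    """
    norm = math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2)) / math.sqrt(df * math.pi)

    def pdf(x):
        return norm * (1.0 + x * x / df) ** (-(df + 1) / 2)

    hi = max(abs(t) + 200.0, 400.0)
    xs = np.linspace(t, hi, n_grid)
    body = float(np.trapezoid([pdf(x) for x in xs], xs))
    # analytic tail beyond the grid: pdf ~ norm * (x^2/df)^-(df+1)/2
    tail = norm * df ** ((df + 1) / 2) * hi ** (-df) / df
    return body + tail


def paired_t_p_bf(d) -> tuple:
    """Two-tailed paired-t (t, p) from first principles."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    mean = d.sum() / n
    sd = math.sqrt(((d - mean) ** 2).sum() / (n - 1))
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * student_t_sf(abs(t), n - 1)
    return t, p


def random_blob_mask(rng, shape, min_pixels_per_slice=100):
    """Random per-slice ellipse stack: every nonempty slice has >= the
    requested pixel count (for round-trip fidelity bounds)."""
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    z0 = rng.integers(0, nz - 1)
    z1 = rng.integers(z0 + 1, nz + 1)
    cy = rng.uniform(0.35, 0.65) * ny
    cx = rng.uniform(0.35, 0.65) * nx
    for z in range(z0, z1):
        ry = rng.uniform(8.0, 0.3 * ny)
        rx = max(8.0, min_pixels_per_slice / (math.pi * ry) * 1.3)
        rx = min(rx + rng.uniform(0, 6), 0.3 * nx)
        yy, xx = np.mgrid[0:ny, 0:nx]
        sl = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if sl.sum() < min_pixels_per_slice:
            continue
        mask[z] = sl
    return mask
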