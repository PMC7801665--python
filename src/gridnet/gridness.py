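"""Gridness score and grid geometry from the spatial autocorrelogram.

The gridness score quantifies six-fold rotational symmetry: an annulus of
the autocorrelogram covering the six peripheral peaks (central peak
masked out) is rotated in 30 degree steps and correlated with itself;
``score = min(r60, r120) - max(r30, r90, r150)``. Scores above ~0 indicate
hexagonal structure; ideal lattices exceed 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .ratemaps import Autocorrelogram

__all__ = ["GridnessResult", "find_autocorr_peaks", "gridness_score", "grid_spacing"]

ROTATIONS = (30, 60, 90, 120, 150)


@dataclass
class GridnessResult:
    score: float
    center_peak: Optional[Tuple[int, int]] = None
    six_peaks: List[Tuple[int, int]] = field(default_factory=list)
    inner_mask_radius: float = np.nan  # bins
    outer_mask_radius: float = np.nan  # bins
    rotation_correlations: Dict[int, float] = field(default_factory=dict)
    spacing: float = np.nan  # m
    bin_size: float = np.nan  # m


def _as_array(acorr) -> Tuple[np.ndarray, float]:
    if isinstance(acorr, Autocorrelogram):
        return acorr.values, acorr.bin_size
    return np.asarray(acorr, dtype=float), 1.0


def find_autocorr_peaks(acorr, rel_threshold: float = 0.1):
    """Local maxima of the autocorrelogram, split into center + peripheral.

    Maxima are detected in a 3x3 neighbourhood. The peak closest to the
    array center is the central peak; remaining peaks with a value above
    ``rel_threshold`` times the largest off-center peak are returned
    sorted by distance to the center (ties broken by angle from the
    positive x-axis, smallest first).

    Returns ``(center_peak, peripheral_peaks)`` as (ix, iy) tuples, or
    ``(None, [])`` when the array is constant.
    """
    a, _ = _as_array(acorr)
    if np.all(a == a.flat[0]):
        return None, []
    footprint = np.ones((3, 3), dtype=bool)
    is_max = (a == ndimage.maximum_filter(a, footprint=footprint)) & np.isfinite(a)
    # suppress plateau duplicates: keep one representative per labelled plateau
    lbl, n_lbl = ndimage.label(is_max)
    coords = np.array(ndimage.center_of_mass(is_max, lbl, range(1, n_lbl + 1)))
    if coords.size == 0:
        return None, []
    coords = np.round(coords).astype(int)
    c = np.array([a.shape[0] // 2, a.shape[1] // 2])
    d = np.hypot(*(coords - c).T)
    center_idx = int(np.argmin(d))
    center = tuple(coords[center_idx])
    rest = np.delete(coords, center_idx, axis=0)
    if len(rest) == 0:
        return center, []
    vals = a[rest[:, 0], rest[:, 1]]
    keep = vals > rel_threshold * vals.max()
    rest = rest[keep]
    dd = np.hypot(rest[:, 0] - center[0], rest[:, 1] - center[1])
    ang = np.mod(np.arctan2(rest[:, 1] - center[1], rest[:, 0] - center[0]), 2 * np.pi)
    order = np.lexsort((ang, np.round(dd, 9)))
    return center, [tuple(p) for p in rest[order]]


def _subpixel_peak(a: np.ndarray, p) -> np.ndarray:
    """Refine an integer peak location by a 1-D quadratic fit per axis.

    Integer-bin peak positions quantise center-to-peak distances to the
    bin grid; the parabola through the peak and its two neighbours gives
    a sub-bin estimate (clamped to ±0.5 bin).
    """
    out = np.array(p, dtype=float)
    for ax in range(2):
        i, j = p
        if ax == 0 and 0 < i < a.shape[0] - 1:
            fm, f0, fp = a[i - 1, j], a[i, j], a[i + 1, j]
        elif ax == 1 and 0 < j < a.shape[1] - 1:
            fm, f0, fp = a[i, j - 1], a[i, j], a[i, j + 1]
        else:
            continue
        denom = fm - 2 * f0 + fp
        if np.isfinite(denom) and denom < 0:
            out[ax] += float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))
    return out


def gridness_score(acorr, rel_threshold: float = 0.1) -> GridnessResult:
    """Rotational-symmetry gridness score of an autocorrelogram.

    The central peak is masked with a disk of radius half the distance to
    the closest peripheral peak; everything beyond 3/2 times the distance
    to the outermost of the six closest peaks is masked as well. The
    remaining annulus is rotated by 30..150 degrees (bilinear
    interpolation about the array center) and Pearson-correlated with the
    unrotated annulus over jointly valid bins.

    Returns a result with ``score`` NaN when fewer than six peripheral
    peaks exist or the annulus is degenerate.
    """
    a, bin_size = _as_array(acorr)
    center, peripheral = find_autocorr_peaks(acorr, rel_threshold)
    res = GridnessResult(score=np.nan, center_peak=center, bin_size=bin_size)
    if center is None or len(peripheral) < 6:
        return res
    six = peripheral[:6]
    res.six_peaks = six
    refined = np.array([_subpixel_peak(a, p) for p in six])
    d = np.hypot(refined[:, 0] - center[0], refined[:, 1] - center[1])
    inner = 0.5 * d.min()
    outer = 1.5 * d.max()
    res.inner_mask_radius = inner
    res.outer_mask_radius = outer
    res.spacing = float(np.median(d) * bin_size)
    if outer <= inner:
        return res

    yy, xx = np.meshgrid(np.arange(a.shape[1]), np.arange(a.shape[0]))
    # radius measured from the array center (rotation axis)
    cx, cy = a.shape[0] // 2, a.shape[1] // 2
    r = np.hypot(xx - cx, yy - cy)
    annulus = (r > inner) & (r < outer)
    if annulus.sum() < 2:
        return res

    corrs: Dict[int, float] = {}
    for angle in ROTATIONS:
        rot = ndimage.rotate(a, angle, reshape=False, order=1,
                             mode="constant", cval=np.nan)
        valid = annulus & np.isfinite(rot) & np.isfinite(a)
        u, v = a[valid], rot[valid]
        if u.size < 2 or np.std(u) == 0 or np.std(v) == 0:
            corrs[angle] = np.nan
        else:
            corrs[angle] = float(np.corrcoef(u, v)[0, 1])
    res.rotation_correlations = corrs
    res.score = float(min(corrs[60], corrs[120])
                      - max(corrs[30], corrs[90], corrs[150]))
    return res


def grid_spacing(result: GridnessResult) -> float:
    """Grid spacing in meters: median center-to-peak distance times bin size."""
    if not result.six_peaks or result.center_peak is None:
        return np.nan
    return result.spacing
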