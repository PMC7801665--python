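"""Firing-field segmentation and field-based spatial statistics.

Fields are detected by combining three criteria: rate-map peaks pruned by
a global field radius derived from the autocorrelogram, exclusion of
rate-map valleys via the sign of the Laplacian (positive curvature =
valley), and a minimum area of 9 bins. Spatial specificity is
``log10(FR_in / FR_out)``; spatial information is the classic
position-coding divergence ``sum_i p_i (λ_i/λ) log2(λ_i/λ)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .gridness import find_autocorr_peaks
from .ratemaps import Autocorrelogram, RateMap
from .types import SpikeTrain, Trajectory

__all__ = [
    "FieldMap",
    "InOutRates",
    "identify_fields",
    "in_out_field_rates",
    "spatial_specificity",
    "spatial_information",
]

MIN_FIELD_BINS = 9
EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class FieldMap:
    labels: np.ndarray  # int image, 0 = background, 1..K fields (rate-sorted)
    fields: List[dict] = field(default_factory=list)
    global_field_radius: float = np.nan  # bins

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    def in_field_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class InOutRates:
    fr_in_field: float  # Hz
    fr_out_field: float  # Hz
    in_field_time: float  # s
    out_field_time: float  # s
    in_field_spikes: int
    out_field_spikes: int


def _rate_map_peaks(values: np.ndarray) -> np.ndarray:
    is_max = (values == ndimage.maximum_filter(values, footprint=np.ones((3, 3)))) \
        & (values > 0)
    lbl, n = ndimage.label(is_max)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    coords = np.round(np.array(
        ndimage.center_of_mass(is_max, lbl, range(1, n + 1)))).astype(int)
    return coords


def identify_fields(
    rate_map: RateMap,
    acorr: Optional[Autocorrelogram] = None,
    global_field_radius: Optional[float] = None,
) -> FieldMap:
    """Segment firing fields of a rate map.

    Procedure: (1) the global field radius is 0.7 times half the distance
    from the autocorrelogram's central peak to its closest peak (or an
    explicit value in bins); (2) rate-map peaks are detected and the lower
    of any two peaks closer than this radius is discarded; (3) bins with
    positive Laplacian of the smoothed map (valleys) are excluded;
    (4) remaining bins are labelled into 8-connected components;
    (5) components smaller than 9 bins are dropped; (6) components that
    contain a surviving peak become fields, sorted by descending mean
    rate. A component holding several surviving peaks counts once.
    """
    v = rate_map.values
    if global_field_radius is None:
        if acorr is None:
            raise ValueError("need an autocorrelogram or an explicit radius")
        center, peripheral = find_autocorr_peaks(acorr)
        if center is None or not peripheral:
            return FieldMap(labels=np.zeros_like(v, dtype=int))
        p = peripheral[0]
        dist = np.hypot(p[0] - center[0], p[1] - center[1])
        global_field_radius = 0.7 * 0.5 * dist

    peaks = _rate_map_peaks(v)
    if len(peaks) == 0:
        return FieldMap(labels=np.zeros_like(v, dtype=int),
                        global_field_radius=global_field_radius)
    # prune peak pairs closer than the global field radius (keep the higher)
    order = np.argsort(-v[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]
    kept: List[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) >= global_field_radius for q in kept):
            kept.append(p)
    kept_arr = np.array(kept)

    lap = ndimage.laplace(v)
    # valleys (positive curvature) and silent bins cannot belong to a field
    candidate = (lap <= 0) & (v > 0)
    lbl, n_lbl = ndimage.label(candidate, structure=EIGHT_CONN)
    fields = []
    for comp in range(1, n_lbl + 1):
        mask = lbl == comp
        if mask.sum() < MIN_FIELD_BINS:
            continue
        has_peak = any(mask[p[0], p[1]] for p in kept_arr)
        if not has_peak:
            continue
        mean_rate = float(v[mask].mean())
        peak_in = max((tuple(p) for p in kept_arr if mask[p[0], p[1]]),
                      key=lambda p: v[p])
        fields.append({"mask": mask, "peak": peak_in, "mean_rate": mean_rate,
                       "area_bins": int(mask.sum())})
    fields.sort(key=lambda f: -f["mean_rate"])
    labels = np.zeros_like(v, dtype=int)
    out_fields = []
    for i, f in enumerate(fields, start=1):
        labels[f["mask"]] = i
        out_fields.append({"id": i, "bins": np.argwhere(f["mask"]),
                           "peak": f["peak"], "mean_rate": f["mean_rate"],
                           "area_bins": f["area_bins"]})
    return FieldMap(labels=labels, fields=out_fields,
                    global_field_radius=float(global_field_radius))


def _position_labels(traj: Trajectory, fieldmap: FieldMap, bin_size: float,
                     times: np.ndarray) -> np.ndarray:
    """Field label (0 = out of field) at arbitrary times along the trajectory."""
    x = np.interp(times, traj.t, traj.x)
    y = np.interp(times, traj.t, traj.y)
    n = fieldmap.labels.shape[0]
    ix = np.clip((x / bin_size).astype(int), 0, n - 1)
    iy = np.clip((y / bin_size).astype(int), 0, fieldmap.labels.shape[1] - 1)
    return fieldmap.labels[ix, iy]


def in_out_field_rates(
    spikes: SpikeTrain,
    traj: Trajectory,
    fieldmap: FieldMap,
    bin_size: float = 0.02,
) -> InOutRates:
    """Mean firing rate inside vs outside the detected fields."""
    dwell = 1.0 / traj.fs
    pos_lab = _position_labels(traj, fieldmap, bin_size, traj.t)
    t_in = float(np.sum(pos_lab > 0) * dwell)
    t_out = float(np.sum(pos_lab == 0) * dwell)
    spk_lab = _position_labels(traj, fieldmap, bin_size, spikes.times)
    n_in = int(np.sum(spk_lab > 0))
    n_out = int(np.sum(spk_lab == 0))
    fr_in = n_in / t_in if t_in > 0 else np.nan
    fr_out = n_out / t_out if t_out > 0 else np.nan
    return InOutRates(fr_in_field=fr_in, fr_out_field=fr_out,
                      in_field_time=t_in, out_field_time=t_out,
                      in_field_spikes=n_in, out_field_spikes=n_out)


def spatial_specificity(rates: InOutRates) -> float:
    """log10 ratio of in-field to out-of-field firing rate.

    Degenerate cases return signed infinity with a warning so that group
    statistics can exclude them explicitly.
    """
    if rates.fr_out_field == 0:
        warnings.warn("FR_out = 0; specificity is +inf")
        return np.inf
    if rates.fr_in_field == 0:
        warnings.warn("FR_in = 0; specificity is -inf")
        return -np.inf
    return float(np.log10(rates.fr_in_field / rates.fr_out_field))


def spatial_information(rate_map: RateMap, per_second: bool = False) -> float:
    """Spatial information of a rate map.

    Default: ``sum_i p_i (λ_i/λ) log2(λ_i/λ)`` with ``p_i`` the occupancy
    probability of bin i, ``λ_i`` its firing rate and ``λ`` the mean rate
    (bits per spike convention; ``0*log 0 := 0``). With
    ``per_second=True`` the bits-per-second variant
    ``sum_i p_i λ_i log2(λ_i/λ)`` is returned instead.
    """
    p = rate_map.occupancy_probability()
    if p.sum() == 0:
        warnings.warn("zero total occupancy")
        return 0.0
    lam_i = rate_map.values
    lam = float(np.sum(p * lam_i))
    if lam == 0:
        warnings.warn("mean rate is zero; information undefined, returning 0")
        return 0.0
    pos = lam_i > 0
    ratio = lam_i[pos] / lam
    if per_second:
        return float(np.sum(p[pos] * lam_i[pos] * np.log2(ratio)))
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))
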