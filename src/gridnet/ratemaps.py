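"""Occupancy-normalised rate maps, spatial autocorrelograms and stability.

A rate map divides the arena into square bins (2 cm by default), counts
spikes and dwell time per bin, smooths both maps with the same 2-D
Gaussian and divides them bin-wise. The spatial autocorrelogram is the
full (un-normalised) sliding dot product of the smoothed rate map with
itself, the input to the gridness analysis.

Conventions: bin (0, 0) sits at the lower-left corner of the arena; bins
are half-open ``[k*b, (k+1)*b)``; ``values[ix, iy]`` indexes x then y.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .types import SpikeTrain, Trajectory

__all__ = [
    "RateMap",
    "Autocorrelogram",
    "compute_rate_map",
    "compute_autocorrelogram",
    "spatial_correlation",
    "within_trial_stability",
]


@dataclass
class RateMap:
    values: np.ndarray  # Hz, smoothed
    occupancy: np.ndarray  # seconds, raw (unsmoothed)
    spike_count: np.ndarray  # raw spike counts per bin
    bin_size: float  # m
    sigma: float  # m, smoothing kernel SD
    arena_size: float  # m

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def total_time(self) -> float:
        return float(self.occupancy.sum())

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate (the symbol λ in the information measure)."""
        tot = self.total_time
        if tot == 0:
            return np.nan
        return float(np.sum(self.occupancy / tot * self.values))

    def occupancy_probability(self) -> np.ndarray:
        """p_i = dwell time in bin i / total session time."""
        tot = self.total_time
        return self.occupancy / tot if tot > 0 else np.zeros_like(self.occupancy)


@dataclass
class Autocorrelogram:
    values: np.ndarray  # (2n-1, 2n-1)
    bin_size: float  # m

    @property
    def center(self) -> tuple:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def _bin_edges(arena_size: float, bin_size: float) -> np.ndarray:
    n = int(np.ceil(arena_size / bin_size - 1e-9))
    return np.arange(n + 1) * bin_size


def compute_rate_map(
    spikes: SpikeTrain,
    traj: Trajectory,
    bin_size: float = 0.02,
    sigma: float = 0.03,
) -> RateMap:
    """Occupancy-normalised smoothed firing-rate map.

    Spike map and occupancy map are binned at ``bin_size`` and each
    convolved with a 2-D Gaussian of standard deviation ``sigma`` (in
    meters; truncated at 4 sigma, zero-padded boundaries), then divided
    bin-wise. Two presets are in common use: sigma = 3 cm and 5 cm.

    Bins whose smoothed occupancy is zero get rate 0.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    edges = _bin_edges(traj.arena_size, bin_size)
    dwell = 1.0 / traj.fs
    occ, _, _ = np.histogram2d(traj.x, traj.y, bins=[edges, edges])
    occ *= dwell
    sx = np.interp(spikes.times, traj.t, traj.x)
    sy = np.interp(spikes.times, traj.t, traj.y)
    cnt, _, _ = np.histogram2d(sx, sy, bins=[edges, edges])

    sig_bins = sigma / bin_size
    if sig_bins > 0:
        occ_s = ndimage.gaussian_filter(occ, sig_bins, mode="constant", truncate=4.0)
        cnt_s = ndimage.gaussian_filter(cnt, sig_bins, mode="constant", truncate=4.0)
    else:
        occ_s, cnt_s = occ, cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_s > 0, cnt_s / np.where(occ_s > 0, occ_s, 1.0), 0.0)
    return RateMap(values=rate, occupancy=occ, spike_count=cnt,
                   bin_size=bin_size, sigma=sigma, arena_size=traj.arena_size)


def compute_autocorrelogram(rate_map, method: str = "fft",
                            normalize: bool = False) -> Autocorrelogram:
    """Full 2-D spatial autocorrelation of the smoothed rate map.

    Un-normalised sliding dot product, output size ``(2n-1, 2n-1)``.
    ``method='direct'`` uses explicit summation (slow; kept as an oracle
    for the FFT path).

    With ``normalize=True`` each lag holds the Pearson correlation of the
    two overlapping map segments instead of their raw product. The raw
    product carries a triangular overlap envelope plus mean cross-terms
    that pull peripheral peaks inward and bias spacing estimates low; the
    Pearson form removes both and is the better basis for grid-geometry
    estimation. Gridness itself is largely insensitive to the choice
    because it Pearson-normalises over the masked annulus.
    """
    if isinstance(rate_map, RateMap):
        m = rate_map.values
        b = rate_map.bin_size
    else:
        m = np.asarray(rate_map, dtype=float)
        b = 1.0
    if not np.all(np.isfinite(m)):
        raise ValueError("rate map must be finite")
    if normalize:
        return Autocorrelogram(values=_pearson_acorr(m, method), bin_size=b)
    if method == "fft":
        ac = signal.fftconvolve(m, m[::-1, ::-1], mode="full")
    elif method == "direct":
        ac = signal.correlate2d(m, m, mode="full")
    else:
        raise ValueError("method must be 'fft' or 'direct'")
    return Autocorrelogram(values=ac, bin_size=b)


def _pearson_acorr(m: np.ndarray, method: str = "fft") -> np.ndarray:
    """Pearson product-moment autocorrelation at every lag.

    ``r(lag) = [n*Sxy - Sx*Sy] / sqrt((n*Sxx - Sx^2)(n*Syy - Sy^2))``
    over the ``n`` bins where the shifted copies overlap; lags with zero
    variance in either segment are set to 0. The direct method loops over
    lags explicitly (oracle for the FFT identity).
    """
    ones = np.ones_like(m)
    if method == "fft":
        conv = lambda a, b: signal.fftconvolve(a, b[::-1, ::-1], mode="full")
    elif method == "direct":
        conv = lambda a, b: signal.correlate2d(a, b, mode="full")
    else:
        raise ValueError("method must be 'fft' or 'direct'")
    n = conv(ones, ones)
    sx = conv(m, ones)
    sy = conv(ones, m)
    sxy = conv(m, m)
    sxx = conv(m**2, ones)
    syy = conv(ones, m**2)
    num = n * sxy - sx * sy
    den = np.sqrt(np.maximum(n * sxx - sx**2, 0.0)
                  * np.maximum(n * syy - sy**2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def spatial_correlation(map_a, map_b) -> float:
    """Pearson correlation between two rate maps of identical shape.

    Bins with zero raw occupancy in either map (unvisited) are excluded,
    as are non-finite bins; returns NaN when fewer than two bins remain.
    """
    if isinstance(map_a, RateMap):
        va, occ_a = map_a.values, map_a.occupancy
    else:
        va, occ_a = np.asarray(map_a, float), None
    if isinstance(map_b, RateMap):
        vb, occ_b = map_b.values, map_b.occupancy
    else:
        vb, occ_b = np.asarray(map_b, float), None
    if va.shape != vb.shape:
        raise ValueError("rate maps must have identical shapes")
    valid = np.isfinite(va) & np.isfinite(vb)
    if occ_a is not None:
        valid &= occ_a > 0
    if occ_b is not None:
        valid &= occ_b > 0
    a, b = va[valid], vb[valid]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def within_trial_stability(
    spikes: SpikeTrain,
    traj: Trajectory,
    bin_size: float = 0.02,
    sigma: float = 0.03,
    block: float = 600.0,
    min_spikes: int = 10,
) -> float:
    """Within-trial spatial stability: first vs last block of the session.

    The rate map of the first ``block`` seconds (10 min by default) is
    correlated with the rate map of the last ``block`` seconds. Sessions
    shorter than ``2*block`` are split at the midpoint instead.
    """
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    span = t1 - t0
    half = block
    if span < 2 * block:
        warnings.warn("session shorter than two blocks; splitting at midpoint")
        half = span / 2.0
    traj_a = traj.slice(t0, t0 + half)
    traj_b = traj.slice(t1 - half, t1 + 1.0 / traj.fs)
    spk_a = spikes.slice(t0, t0 + half)
    spk_b = spikes.slice(t1 - half, t1 + 1.0 / traj.fs)
    if len(spk_a) < min_spikes or len(spk_b) < min_spikes:
        warnings.warn("too few spikes in a half-session; stability undefined")
        return np.nan
    ma = compute_rate_map(spk_a, traj_a, bin_size, sigma)
    mb = compute_rate_map(spk_b, traj_b, bin_size, sigma)
    return spatial_correlation(ma, mb)
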