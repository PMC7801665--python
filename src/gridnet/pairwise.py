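"""Pairwise spatiotemporal cross-correlations of grid cells.

Two complementary views of pairwise structure: (1) the temporal
cross-correlogram of kernel-smoothed instantaneous rates at lags up to
±1 s, and (2) the periodic 2-D cross-correlation of the two rate maps.
Both are normalised to [-1, 1] by z-scoring each series/map and dividing
by the sample count. Stability of a pair across two sessions is the
Pearson correlation of its correlograms in the two sessions — a
population-level fingerprint that survives coherent remapping (which
preserves relative spatial offsets) but not independent drift.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .fields import identify_fields, in_out_field_rates, _position_labels
from .ratemaps import RateMap, compute_autocorrelogram, compute_rate_map
from .tuning import instantaneous_rate
from .types import SpikeTrain, Trajectory

__all__ = [
    "CrossCorrelogram",
    "SpatialCrossMap",
    "temporal_cross_correlation",
    "spatial_cross_correlation",
    "pairwise_stability",
]

XCORR_FS = 1000.0  # Hz, rate sampling for temporal correlograms
XCORR_KERNEL = 0.010  # s, Gaussian kernel SD
MAX_LAG = 1.0  # s


@dataclass
class CrossCorrelogram:
    lags: np.ndarray  # s, symmetric about 0
    values: np.ndarray  # in [-1, 1]
    pair: Tuple[str, str] = ("", "")
    session: str = ""


@dataclass
class SpatialCrossMap:
    values: np.ndarray  # wrap cross-correlation, zero offset at center
    pair: Tuple[str, str] = ("", "")
    session: str = ""

    @property
    def center(self) -> tuple:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.full_like(x, np.nan)
    return (x - np.mean(x)) / sd


def _bandstop_theta(x: np.ndarray, fs: float, band=(4.0, 10.0), order: int = 4) -> np.ndarray:
    sos = sps.butter(order, band, btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def temporal_cross_correlation(
    spk_a: SpikeTrain,
    spk_b: SpikeTrain,
    fs: float = XCORR_FS,
    kernel_sigma: float = XCORR_KERNEL,
    max_lag: float = MAX_LAG,
    theta_bandstop: bool = False,
) -> CrossCorrelogram:
    """Normalised temporal cross-correlogram of two spike trains.

    Instantaneous rates (10 ms Gaussian kernel, 1 kHz) are z-scored and
    cross-correlated; dividing by the sample count bounds values in
    [-1, 1]. Positive lag means unit b fires after unit a. The
    ``theta_bandstop`` control removes 4-10 Hz from the rate series with
    a zero-phase band-stop filter before correlating.
    """
    t0 = min(spk_a.t_start, spk_b.t_start)
    t1 = max(spk_a.t_stop, spk_b.t_stop)
    n_lag = int(round(max_lag * fs))
    lags = np.arange(-n_lag, n_lag + 1) / fs
    if len(spk_a) == 0 or len(spk_b) == 0:
        return CrossCorrelogram(lags, np.full(len(lags), np.nan),
                                (spk_a.unit_id, spk_b.unit_id))
    ra = instantaneous_rate(spk_a, kernel_sigma, fs, t0, t1)
    rb = instantaneous_rate(spk_b, kernel_sigma, fs, t0, t1)
    if theta_bandstop:
        ra = _bandstop_theta(ra, fs)
        rb = _bandstop_theta(rb, fs)
    za, zb = _zscore(ra), _zscore(rb)
    n = len(za)
    # c[lag] = (1/n) sum_t za[t] zb[t+lag]; peak at +d when b trails a by d
    full = sps.correlate(zb, za, mode="full", method="fft") / n
    mid = n - 1
    vals = full[mid - n_lag: mid + n_lag + 1]
    return CrossCorrelogram(lags, vals, (spk_a.unit_id, spk_b.unit_id))


def spatial_cross_correlation(map_a, map_b, method: str = "fft") -> SpatialCrossMap:
    """Periodic (wrap-boundary) 2-D cross-correlation of two rate maps.

    Maps are z-scored over all bins and correlated on the torus; dividing
    by the bin count bounds values in [-1, 1]. The zero offset sits at
    the array center; when ``map_b`` equals ``map_a`` circularly shifted
    by (di, dj), the maximum appears at offset (di, dj).
    """
    va = map_a.values if isinstance(map_a, RateMap) else np.asarray(map_a, float)
    vb = map_b.values if isinstance(map_b, RateMap) else np.asarray(map_b, float)
    if va.shape != vb.shape:
        raise ValueError("maps must have identical shapes")
    if np.std(va) == 0 or np.std(vb) == 0:
        return SpatialCrossMap(values=np.full(va.shape, np.nan))
    za, zb = _zscore(va), _zscore(vb)
    za = np.nan_to_num(za)
    zb = np.nan_to_num(zb)
    n = va.size
    if method == "fft":
        c = np.fft.ifft2(np.fft.fft2(zb) * np.conj(np.fft.fft2(za))).real / n
    elif method == "direct":
        c = np.empty_like(za)
        for di in range(va.shape[0]):
            for dj in range(va.shape[1]):
                c[di, dj] = np.sum(np.roll(zb, (-di, -dj), axis=(0, 1)) * za) / n
    else:
        raise ValueError("method must be 'fft' or 'direct'")
    # put zero offset at the array center
    c = np.roll(c, (va.shape[0] // 2, va.shape[1] // 2), axis=(0, 1))
    return SpatialCrossMap(values=c)


def _in_field_spikes(spk: SpikeTrain, traj: Trajectory, bin_size: float,
                     sigma: float) -> SpikeTrain:
    """Delete spikes falling outside the unit's detected firing fields."""
    rm = compute_rate_map(spk, traj, bin_size, sigma)
    ac = compute_autocorrelogram(rm)
    fm = identify_fields(rm, ac)
    if fm.n_fields == 0:
        return spk
    lab = _position_labels(traj, fm, bin_size, spk.times)
    return SpikeTrain(spk.unit_id, spk.times[lab > 0], spk.t_start, spk.t_stop,
                      group=spk.group)


def _pair_correlogram(
    spikes: Dict[str, SpikeTrain],
    traj: Trajectory,
    pair: Tuple[str, str],
    mode: str,
    theta_bandstop: bool,
    bin_size: float,
    sigma: float,
) -> np.ndarray:
    a, b = spikes[pair[0]], spikes[pair[1]]
    if mode == "temporal":
        return temporal_cross_correlation(a, b, theta_bandstop=theta_bandstop).values
    if mode == "spatial":
        ma = compute_rate_map(a, traj, bin_size, sigma)
        mb = compute_rate_map(b, traj, bin_size, sigma)
        return spatial_cross_correlation(ma, mb).values.ravel()
    raise ValueError("mode must be 'temporal' or 'spatial'")


def pairwise_stability(
    session_a: dict,
    session_b: dict,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    mode: str = "temporal",
    theta_bandstop: bool = False,
    in_field_only: bool = False,
    bin_size: float = 0.02,
    sigma: float = 0.03,
) -> Dict[Tuple[str, str], float]:
    """Stability of pairwise cross-correlograms across two sessions.

    Sessions are dicts ``{"trajectory": Trajectory, "spikes": [SpikeTrain]}``
    (the synthetic-protocol bundle format). For each pair the correlogram
    is computed in both sessions and the stability is the Pearson r
    between the two (2-D maps flattened). Pairs whose correlogram is
    undefined in either session are dropped. Symmetric in session order.
    """
    out: Dict[Tuple[str, str], float] = {}
    sess = []
    for s in (session_a, session_b):
        spk = {u.unit_id: u for u in s["spikes"]}
        traj = s["trajectory"]
        if in_field_only:
            spk = {k: _in_field_spikes(v, traj, bin_size, sigma)
                   for k, v in spk.items()}
        sess.append((spk, traj))
    if pairs is None:
        ids = sorted(set(sess[0][0]) & set(sess[1][0]))
        pairs = [(ids[i], ids[j]) for i in range(len(ids))
                 for j in range(i + 1, len(ids))]
    for pair in pairs:
        cors = []
        ok = True
        for spk, traj in sess:
            if pair[0] not in spk or pair[1] not in spk:
                ok = False
                break
            c = _pair_correlogram(spk, traj, pair, mode, theta_bandstop,
                                  bin_size, sigma)
            if not np.all(np.isfinite(c)):
                ok = False
                break
            cors.append(c)
        if not ok:
            continue
        a, b = cors
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        out[pair] = float(np.corrcoef(a, b)[0, 1])
    return out
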