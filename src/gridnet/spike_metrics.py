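"""Temporal spiking statistics: ISI variability, bursting, waveform typing.

The coefficient of variation of inter-spike intervals (CV = σ_ISI/μ_ISI,
1 for a Poisson process) is offered in three variants: per pass through a
firing field (removes between-field travel bias), over the whole session,
and within low-speed segments. Bursting is quantified as the ratio of
burst-start events (pre-ISI > 10 ms, post-ISI < 10 ms) to single-spike
events (both ISIs > 10 ms). Units are typed narrow/broad-spiking from the
trough-to-peak time and half-width of their mean waveform.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import interp1d
from sklearn.cluster import KMeans

from .fields import FieldMap, _position_labels
from .types import SpikeTrain, Trajectory

__all__ = [
    "IsiStats",
    "BurstCounts",
    "WaveformFeatures",
    "cv_isi",
    "bursting_ratio",
    "waveform_features",
    "classify_waveform_types",
]

BURST_ISI = 0.010  # s
LOW_SPEED = 0.08  # m/s
LOW_SPEED_MIN_DURATION = 0.2  # s


@dataclass
class IsiStats:
    sigma_isi: float  # s (NaN for aggregated methods)
    mu_isi: float  # s (NaN for aggregated methods)
    cv: float
    method: str
    n_segments: int = 1


@dataclass
class BurstCounts:
    n_burst: int
    n_single: int
    n_uncounted: int
    ratio: float


@dataclass
class WaveformFeatures:
    trough_to_peak: float  # ms
    half_width: float  # ms
    label: str = ""


def _cv(isis: np.ndarray, ddof: int = 0) -> float:
    """CV of an ISI list; population σ (ddof=0) by default."""
    if len(isis) < 2:
        return np.nan
    mu = isis.mean()
    if mu == 0:
        return np.nan
    return float(isis.std(ddof=ddof) / mu)


def _segment_runs(mask: np.ndarray) -> List[tuple]:
    """(start, stop) index pairs of maximal True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def cv_isi(
    spikes: SpikeTrain,
    traj: Optional[Trajectory] = None,
    fieldmap: Optional[FieldMap] = None,
    method: str = "whole_session",
    bin_size: float = 0.02,
    min_pass_spikes: int = 3,
    ddof: int = 0,
) -> IsiStats:
    """Coefficient of variation of the inter-spike-interval distribution.

    methods
    -------
    ``whole_session``
        σ/μ over every ISI of the session.
    ``in_field_pass``
        One CV per contiguous traversal of a firing field (a pass starts
        and ends when the tracked position crosses a field boundary;
        passes shorter than two tracking samples are discarded, passes
        with fewer than ``min_pass_spikes`` spikes are skipped); the unit
        value is the unweighted mean of pass CVs.
    ``low_speed``
        One CV per segment with speed < 8 cm/s lasting > 0.2 s and
        containing at least two spikes; unit value is the mean.
    """
    if method == "whole_session":
        isis = np.diff(spikes.times)
        cv = _cv(isis, ddof)
        return IsiStats(float(isis.std(ddof=ddof)) if len(isis) > 1 else np.nan,
                        float(isis.mean()) if len(isis) else np.nan,
                        cv, method)
    if traj is None:
        raise ValueError(f"method {method!r} needs a trajectory")

    if method == "in_field_pass":
        if fieldmap is None:
            raise ValueError("in_field_pass needs a field map")
        lab = _position_labels(traj, fieldmap, bin_size, traj.t)
        runs = [(a, b) for a, b in _segment_runs(lab > 0) if b - a >= 2]
        min_spk = min_pass_spikes
    elif method == "low_speed":
        slow = traj.speed() < LOW_SPEED
        runs = [(a, b) for a, b in _segment_runs(slow)
                if (b - a) / traj.fs > LOW_SPEED_MIN_DURATION]
        min_spk = 2
    else:
        raise ValueError(f"unknown method {method!r}")

    cvs = []
    for a, b in runs:
        t0, t1 = traj.t[a], traj.t[b - 1] + 1.0 / traj.fs
        st = spikes.times[(spikes.times >= t0) & (spikes.times < t1)]
        if len(st) < min_spk:
            continue
        c = _cv(np.diff(st), ddof)
        if np.isfinite(c):
            cvs.append(c)
    if not cvs:
        return IsiStats(np.nan, np.nan, np.nan, method, 0)
    return IsiStats(np.nan, np.nan, float(np.mean(cvs)), method, len(cvs))


def bursting_ratio(spikes: SpikeTrain, isi_threshold: float = BURST_ISI) -> BurstCounts:
    """Ratio of burst-start events to single-spike events.

    A spike with pre-ISI > 10 ms and post-ISI < 10 ms starts a burst; one
    with both ISIs > 10 ms is a single-spike event; everything else
    (spikes inside a burst) is uncounted. The first/last spikes have
    infinite pre-/post-ISI.
    """
    t = spikes.times
    if len(t) < 2:
        raise ValueError("need at least two spikes")
    isi = np.diff(t)
    pre = np.concatenate([[np.inf], isi])
    post = np.concatenate([isi, [np.inf]])
    burst = (pre > isi_threshold) & (post < isi_threshold)
    single = (pre > isi_threshold) & (post > isi_threshold)
    n_b = int(burst.sum())
    n_s = int(single.sum())
    n_u = len(t) - n_b - n_s
    ratio = n_b / n_s if n_s > 0 else np.nan
    return BurstCounts(n_b, n_s, n_u, ratio)


def waveform_features(
    waveform: np.ndarray,
    fs: float = 48000.0,
    upsample: int = 200,
) -> WaveformFeatures:
    """Trough-to-peak time and half-width of a mean spike waveform.

    The channel with the deepest trough is used. The trace is upsampled
    ``upsample``-fold by cubic interpolation; trough-to-peak is the time
    from the (negative) trough to the subsequent maximum. The half-width
    is the time between the two crossings of half the trough amplitude,
    refined by linear interpolation.
    """
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    ch = int(np.argmin(w.min(axis=1)))
    tr = w[ch]
    n = len(tr)
    t = np.arange(n) / fs
    if np.all(np.diff(tr) >= 0) or np.all(np.diff(tr) <= 0):
        raise ValueError("monotone trace has no trough")
    f = interp1d(t, tr, kind="cubic")
    tu = np.linspace(t[0], t[-1], n * upsample)
    x = f(tu)
    i_tr = int(np.argmin(x))
    after = x[i_tr:]
    i_pk = i_tr + int(np.argmax(after))
    ttp_ms = (tu[i_pk] - tu[i_tr]) * 1e3

    half = x[i_tr] / 2.0  # negative-going half amplitude
    below = x < half
    # crossings bracketing the trough, linearly interpolated
    left = None
    for i in range(i_tr, 0, -1):
        if not below[i - 1] and below[i]:
            frac = (half - x[i - 1]) / (x[i] - x[i - 1])
            left = tu[i - 1] + frac * (tu[i] - tu[i - 1])
            break
    right = None
    for i in range(i_tr, len(x) - 1):
        if below[i] and not below[i + 1]:
            frac = (half - x[i]) / (x[i + 1] - x[i])
            right = tu[i] + frac * (tu[i + 1] - tu[i])
            break
    hw_ms = (right - left) * 1e3 if (left is not None and right is not None) else np.nan
    return WaveformFeatures(trough_to_peak=float(ttp_ms), half_width=float(hw_ms))


def classify_waveform_types(
    features: Sequence[WaveformFeatures],
    groups: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> List[str]:
    """Split units into narrow- and broad-spiking by 2-means clustering.

    Clustering runs on (trough_to_peak, half_width), separately per
    experimental group when ``groups`` is given; the cluster with the
    smaller mean trough-to-peak is labelled ``narrow``. Deterministic
    under a fixed seed.
    """
    if len(features) < 2:
        raise ValueError("need at least two units")
    feats = np.array([[f.trough_to_peak, f.half_width] for f in features])
    groups = list(groups) if groups is not None else ["all"] * len(features)
    labels = [""] * len(features)
    for g in sorted(set(groups)):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        sub = feats[idx]
        if np.allclose(sub, sub[0]):
            warnings.warn(f"group {g!r}: identical features, single cluster")
            for i in idx:
                labels[i] = "broad"
            continue
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(sub)
        means = [sub[km.labels_ == k, 0].mean() for k in (0, 1)]
        narrow_k = int(np.argmin(means))
        for i, lab in zip(idx, km.labels_):
            labels[i] = "narrow" if lab == narrow_k else "broad"
    for f, lab in zip(features, labels):
        f.label = lab
    return labels
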