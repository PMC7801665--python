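"""Speed and head-direction tuning, shuffle nulls, functional classification.

Tuning statistics are computed on kernel-smoothed instantaneous firing
rates. Statistical significance of any single-unit statistic is assessed
against a null distribution built from time-shifted surrogate spike
trains: the whole train is shifted by a random amount and wrapped
circularly at the session edges, which preserves the ISI structure while
destroying the relation to behaviour. A unit is classified as a grid
cell when both its gridness and spatial information exceed the 95th
percentile of their nulls, as speed- or head-direction-tuned when the
corresponding score does.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np

from .types import SpikeTrain, Trajectory

__all__ = [
    "ShuffleNull",
    "TuningScores",
    "instantaneous_rate",
    "speed_score",
    "head_direction_tuning",
    "shuffle_distribution",
    "classify_functional_cell_types",
]

SPEED_RANGE = (0.02, 1.0)  # m/s, samples outside are excluded from speed scores


@dataclass
class ShuffleNull:
    values: np.ndarray
    shift: float  # s
    observed: float

    @property
    def percentile_95(self) -> float:
        return float(np.percentile(self.values, 95))

    @property
    def significant(self) -> bool:
        return bool(self.observed > self.percentile_95)


@dataclass
class TuningScores:
    speed_score: float = np.nan
    hd_vector_length: float = np.nan
    preferred_direction: float = np.nan
    classifications: set = field(default_factory=set)


def instantaneous_rate(
    spikes: SpikeTrain,
    kernel_sigma: float = 0.4,
    fs_out: float = 50.0,
    t_start: Optional[float] = None,
    t_stop: Optional[float] = None,
) -> np.ndarray:
    """Gaussian-kernel instantaneous firing rate on a regular grid (Hz).

    Spike mass overhanging the session edges is folded back (reflection),
    so the time integral of the returned series equals the spike count
    exactly up to floating-point error.
    """
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    t0 = spikes.t_start if t_start is None else t_start
    t1 = spikes.t_stop if t_stop is None else t_stop
    n = int(round((t1 - t0) * fs_out))
    if n <= 0:
        return np.zeros(0)
    if len(spikes.times) == 0:
        return np.zeros(n)
    dt = 1.0 / fs_out
    counts = np.histogram(spikes.times, bins=n, range=(t0, t1))[0].astype(float)
    half = int(np.ceil(6 * kernel_sigma / dt))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) * dt / kernel_sigma) ** 2)
    k /= k.sum()
    full = np.convolve(counts, k, mode="full")
    rate = full[half:half + n].copy()
    # fold overhanging tails back across the edges (mass preserving)
    left, right = full[:half], full[half + n:]
    rate[:half] += left[::-1]
    rate[-half:] += right[::-1]
    return rate * fs_out


def speed_score(
    spikes: SpikeTrain,
    traj: Trajectory,
    kernel_sigma: float = 0.4,
    speed_range: tuple = SPEED_RANGE,
) -> float:
    """Pearson correlation between instantaneous firing rate and running speed.

    The rate is evaluated on the tracking clock; only samples with speed
    inside ``speed_range`` (0.02-1.0 m/s) enter the correlation.
    """
    rate = instantaneous_rate(spikes, kernel_sigma, fs_out=traj.fs,
                              t_start=traj.t[0],
                              t_stop=traj.t[-1] + 1.0 / traj.fs)
    v = traj.speed()
    n = min(len(rate), len(v))
    rate, v = rate[:n], v[:n]
    m = (v >= speed_range[0]) & (v <= speed_range[1])
    if m.sum() < 2 or np.std(rate[m]) == 0 or np.std(v[m]) == 0:
        return np.nan
    return float(np.corrcoef(rate[m], v[m])[0, 1])


def head_direction_tuning(
    spikes: SpikeTrain,
    traj: Trajectory,
    n_bins: int = 60,
) -> tuple:
    """Head-direction tuning: (resultant vector length, preferred angle).

    The occupancy-normalised firing rate per angular bin weights unit
    vectors at the bin centers; the resultant length lies in [0, 1]
    (1 = all firing at one angle) and its argument is the preferred
    direction in radians.
    """
    if traj.hd is None:
        raise ValueError("trajectory has no head direction")
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    occ = np.histogram(traj.hd, bins=edges)[0] / traj.fs
    hd_unwrapped = np.unwrap(traj.hd)
    spike_hd = np.mod(np.interp(spikes.times, traj.t, hd_unwrapped), 2 * np.pi)
    cnt = np.histogram(spike_hd, bins=edges)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ > 0, cnt / np.where(occ > 0, occ, 1.0), 0.0)
    if rate.sum() == 0:
        return np.nan, np.nan
    centers = (edges[:-1] + edges[1:]) / 2.0
    z = np.sum(rate * np.exp(1j * centers)) / rate.sum()
    return float(np.abs(z)), float(np.mod(np.angle(z), 2 * np.pi))


def shuffle_distribution(
    spikes: SpikeTrain,
    statistic_fn: Callable[[SpikeTrain], float],
    n: int = 1000,
    shift: float = 30.0,
    seed: Optional[int] = None,
    edges: str = "wrap",
) -> ShuffleNull:
    """Null distribution of a statistic under whole-train time shifts.

    Each surrogate shifts every spike by one amount drawn uniformly from
    ``[-shift, +shift]``; with ``edges='wrap'`` spikes leaving the session
    wrap circularly to the other end, with ``'drop'`` they are discarded.
    Returns the null values together with the observed statistic.
    """
    if spikes.duration <= 2 * shift:
        raise ValueError("session must be longer than twice the shift")
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn(spikes))
    vals = np.empty(n)
    for i in range(n):
        s = rng.uniform(-shift, shift)
        vals[i] = statistic_fn(spikes.time_shift(s, wrap=(edges == "wrap")))
    n_nan = int(np.sum(~np.isfinite(vals)))
    if n_nan > 0.1 * n:
        warnings.warn(f"statistic undefined on {n_nan}/{n} surrogates")
    return ShuffleNull(values=vals, shift=shift, observed=observed)


def classify_functional_cell_types(nulls: Dict[str, ShuffleNull]) -> set:
    """Functional classification from shuffle nulls.

    ``nulls`` maps statistic names (``gridness``, ``spatial_information``,
    ``speed_score``, ``hd_vector_length``) to their ShuffleNull. A unit
    is ``grid`` when gridness AND spatial information both beat their
    95th-percentile thresholds, ``speed``/``hd`` when the respective
    score does, and additionally ``pure_speed`` when speed-tuned but
    neither grid nor head-direction-tuned.
    """
    required = {"gridness", "spatial_information", "speed_score"}
    missing = required - set(nulls)
    if missing:
        raise ValueError(f"missing nulls: {sorted(missing)}")
    classes = set()
    if nulls["gridness"].significant and nulls["spatial_information"].significant:
        classes.add("grid")
    if nulls["speed_score"].significant:
        classes.add("speed")
    if "hd_vector_length" in nulls and nulls["hd_vector_length"].significant:
        classes.add("hd")
    if "speed" in classes and "grid" not in classes and "hd" not in classes:
        classes.add("pure_speed")
    return classes
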