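"""Core containers shared across the analysis modules.

Units are SI throughout: times in seconds, positions in meters, angles in
radians, rates in Hz. Waveform samples are in microvolts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class Trajectory:
    """Tracked position of the animal in an open-field arena.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with spacing ``1/fs``.
    x, y : ndarray
        Position in meters, within ``[0, arena_size]``.
    hd : ndarray or None
        Head direction in radians, wrapped to ``[0, 2*pi)``.
    fs : float
        Tracking sample rate in Hz.
    arena_size : float
        Side length of the square arena in meters.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float
    arena_size: float
    hd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.hd is not None:
            self.hd = np.mod(np.asarray(self.hd, dtype=float), 2 * np.pi)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def speed(self, smooth_window: float = 0.1) -> np.ndarray:
        """Running speed (m/s) from central differences of low-passed positions.

        Positions are smoothed with a boxcar of ``smooth_window`` seconds
        before differentiation to suppress tracking jitter.
        """
        n_win = max(1, int(round(smooth_window * self.fs)))
        if n_win > 1:
            kernel = np.ones(n_win) / n_win
            pad = n_win // 2
            xs = np.convolve(np.pad(self.x, pad, mode="edge"), kernel, "same")[pad:pad + len(self.x)]
            ys = np.convolve(np.pad(self.y, pad, mode="edge"), kernel, "same")[pad:pad + len(self.y)]
        else:
            xs, ys = self.x, self.y
        vx = np.gradient(xs, self.t)
        vy = np.gradient(ys, self.t)
        return np.hypot(vx, vy)

    def slice(self, t0: float, t1: float) -> "Trajectory":
        """Restrict to samples with ``t0 <= t < t1``."""
        m = (self.t >= t0) & (self.t < t1)
        return Trajectory(
            t=self.t[m], x=self.x[m], y=self.y[m], fs=self.fs,
            arena_size=self.arena_size,
            hd=None if self.hd is None else self.hd[m],
        )


@dataclass
class SpikeTrain:
    """Spike times of a single unit within one recording session."""

    unit_id: str
    times: np.ndarray
    t_start: float
    t_stop: float
    waveform: Optional[np.ndarray] = None  # (n_channels, 50) mean trace, µV
    group: str = "control"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times):
            if np.any(np.diff(self.times) < 0):
                self.times = np.sort(self.times)
            if self.times[0] < self.t_start - 1e-9 or self.times[-1] > self.t_stop + 1e-9:
                raise ValueError("spike times outside [t_start, t_stop]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def mean_rate(self) -> float:
        return len(self.times) / self.duration if self.duration > 0 else np.nan

    def slice(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.unit_id, self.times[m], t0, t1,
                          waveform=self.waveform, group=self.group)

    def time_shift(self, shift: float, wrap: bool = True) -> "SpikeTrain":
        """Shift all spike times by ``shift`` seconds.

        With ``wrap=True`` spikes leaving the session are wrapped circularly
        to the other edge (used for shuffle surrogates); otherwise they are
        dropped.
        """
        t = self.times + shift
        span = self.t_stop - self.t_start
        if wrap:
            t = self.t_start + np.mod(t - self.t_start, span)
            t = np.sort(t)
        else:
            t = t[(t >= self.t_start) & (t <= self.t_stop)]
        return SpikeTrain(self.unit_id, t, self.t_start, self.t_stop,
                          waveform=self.waveform, group=self.group)


@dataclass
class GroundTruth:
    """Generative parameters of a synthetic unit (known tuning)."""

    cell_type: str = "grid"  # {grid, hd, speed, noise}
    spacing: float = 0.4  # m, between neighbouring field centres
    orientation: float = 0.0  # rad
    phase: tuple = (0.0, 0.0)  # m, 2-vector offset of the lattice
    peak_rate: float = 15.0  # Hz
    baseline_rate: float = 0.5  # Hz
    hd_kappa: float = 0.0  # von Mises concentration (hd cells)
    hd_mu: float = 0.0  # preferred direction, rad
    speed_slope: float = 0.0  # Hz per m/s (speed cells)
    burst_prob: float = 0.0  # fraction of spikes seeding a burst

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.peak_rate < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SessionProtocol:
    """Familiar I -> Novel I-III -> Familiar II recording protocol."""

    labels: tuple = ("Familiar I", "Novel I", "Novel II", "Novel III", "Familiar II")
    durations: tuple = (1200.0,) * 5  # seconds per session
    remap_rotation: float = 0.5  # rad, coherent lattice rotation in Novel
    remap_shift: tuple = (0.1, 0.05)  # m, coherent phase shift in Novel
    drift_sigma: float = 0.0  # m/sqrt(s), common phase random walk (destabilisation)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.durations):
            raise ValueError("labels and durations must match")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")


@dataclass
class LfpSignal:
    """Continuous local field potential trace."""

    samples: np.ndarray
    fs: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.samples)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs
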