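"""Synthetic open-field recordings with known ground truth.

Every analysis stage in this package is exercisable without access to real
recordings: this module generates foraging trajectories, spike trains of
grid / head-direction / speed-modulated / untuned cells, speed-coupled
theta LFP, extracellular waveform templates, and full multi-session
protocols (Familiar I -> Novel I-III -> Familiar II) with coherent
remapping and optional destabilising phase drift.

Design notes
------------
* Trajectories follow an Ornstein-Uhlenbeck velocity process (correlation
  time 1 s) with reflective walls — a smooth space-filling walk whose
  speed distribution is Rayleigh, so the mean speed is controlled exactly.
* Grid-cell intensity is a sum of three plane waves at 60 degree
  separation with wavenumber ``4*pi/(sqrt(3)*spacing)``, rescaled to
  [0, 1]: spacing, orientation and phase are then analytically known,
  which is what the parameter-recovery tests rely on.
* Spikes are drawn by exact thinning of an inhomogeneous Poisson process
  (no time discretisation bias); rate is evaluated at the linearly
  interpolated position.
"""
from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .types import GroundTruth, LfpSignal, SessionProtocol, SpikeTrain, Trajectory

THETA_FREQ = 8.0  # Hz, carrier for optional theta modulation of spiking

__all__ = [
    "generate_trajectory",
    "grid_intensity",
    "generate_grid_spikes",
    "generate_spikes",
    "generate_session_protocol",
    "generate_lfp",
    "generate_waveforms",
    "waveform_template",
]


def generate_trajectory(
    duration: float,
    arena_size: float = 1.0,
    fs: float = 50.0,
    mean_speed: float = 0.15,
    tau: float = 1.0,
    goal_gain: float = 1.8,
    goal_timeout: float = 8.0,
    hd_noise_kappa: float = 50.0,
    seed: Optional[int] = None,
) -> Trajectory:
    """Simulate a foraging trajectory in a square arena.

    Velocity follows a 2-D Ornstein-Uhlenbeck process with correlation
    time ``tau``, plus a weak drift toward an exploration goal; positions
    reflect off the walls. Goals emulate crumb-chasing foraging (rats in
    open-field recordings are motivated by food crumbs thrown into the
    arena): each goal is drawn from the least-visited 2 cm bins and is
    replaced once its bin has been visited, the rat passes nearby, or a
    timeout expires. This keeps the walk smooth while actively filling
    coverage gaps that a plain random walk leaves open.

    The OU scale is calibrated so the realised mean speed stays within
    10% of ``mean_speed`` despite the goal drift. Head direction is the
    heading of motion plus von Mises noise with concentration
    ``hd_noise_kappa`` (two-LED geometry is not simulated).
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    dt = 1.0 / fs
    # 0.80: empirical compensation for the extra drift speed from goal pursuit
    sigma_v = 0.80 * mean_speed / np.sqrt(np.pi / 2.0)

    nb = max(1, int(np.ceil(arena_size / 0.02)))
    cell = arena_size / nb
    visits = np.zeros((nb, nb))

    def new_goal():
        m = visits + rng.uniform(0.0, 0.5, visits.shape)
        ij = np.unravel_index(np.argmin(m), m.shape)
        return np.array(ij), (np.array(ij) + 0.5) * cell

    v = np.zeros((n, 2))
    pos = np.empty((n, 2))
    pos[0] = rng.uniform(0.2, 0.8, size=2) * arena_size
    v[0] = rng.normal(0.0, sigma_v, size=2)
    decay = np.exp(-dt / tau)
    kick = sigma_v * np.sqrt(1.0 - decay**2)
    noise = rng.normal(0.0, 1.0, size=(n - 1, 2))
    goal_ij, goal = new_goal()
    t_goal = 0.0
    for i in range(1, n):
        ij = np.minimum((pos[i - 1] / cell).astype(int), nb - 1)
        visits[ij[0], ij[1]] += 1
        t = i * dt
        if (visits[goal_ij[0], goal_ij[1]] > 0
                or np.hypot(*(pos[i - 1] - goal)) < 0.025
                or t - t_goal > goal_timeout):
            goal_ij, goal = new_goal()
            t_goal = t
        dvec = goal - pos[i - 1]
        dvec = dvec / max(np.hypot(*dvec), 1e-9)
        v[i] = (v[i - 1] * decay + kick * noise[i - 1]
                + goal_gain * sigma_v * dt / tau * dvec)
        p = pos[i - 1] + v[i] * dt
        # reflective walls: fold position back and flip the velocity component
        for d in range(2):
            if p[d] < 0:
                p[d] = -p[d]
                v[i, d] = -v[i, d]
            elif p[d] > arena_size:
                p[d] = 2 * arena_size - p[d]
                v[i, d] = -v[i, d]
        pos[i] = np.clip(p, 0.0, arena_size)

    heading = np.arctan2(v[:, 1], v[:, 0])
    if hd_noise_kappa > 0:
        heading = heading + rng.vonmises(0.0, hd_noise_kappa, size=n)
    t = np.arange(n) * dt
    return Trajectory(t=t, x=pos[:, 0], y=pos[:, 1], fs=fs,
                      arena_size=arena_size, hd=np.mod(heading, 2 * np.pi))


def grid_intensity(
    x: np.ndarray,
    y: np.ndarray,
    spacing: float,
    orientation: float = 0.0,
    phase: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """Normalised hexagonal firing pattern ``g(x, y)`` in [0, 1].

    Sum of three cosines with wave vectors separated by 60 degrees and
    magnitude ``4*pi/(sqrt(3)*spacing)``; the raw sum spans [-1.5, 3] and
    is rescaled linearly to [0, 1] with maxima at the lattice points.
    """
    k = 4.0 * np.pi / (np.sqrt(3.0) * spacing)
    angles = orientation + np.array([0.0, np.pi / 3.0, 2.0 * np.pi / 3.0])
    dx = np.asarray(x) - phase[0]
    dy = np.asarray(y) - phase[1]
    g = np.zeros(np.broadcast(dx, dy).shape)
    for a in angles:
        g = g + np.cos(k * (np.cos(a) * dx + np.sin(a) * dy))
    return (g + 1.5) / 4.5


def _intensity_at(
    traj: Trajectory,
    gt: GroundTruth,
    t: np.ndarray,
    phase_drift: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Evaluate the cell's rate (Hz) at arbitrary times by interpolation."""
    x = np.interp(t, traj.t, traj.x)
    y = np.interp(t, traj.t, traj.y)
    if gt.cell_type == "grid":
        if phase_drift is not None:
            px = gt.phase[0] + np.interp(t, traj.t, phase_drift[:, 0])
            py = gt.phase[1] + np.interp(t, traj.t, phase_drift[:, 1])
            k = 4.0 * np.pi / (np.sqrt(3.0) * gt.spacing)
            angles = gt.orientation + np.array([0.0, np.pi / 3, 2 * np.pi / 3])
            g = np.zeros_like(x)
            for a in angles:
                g += np.cos(k * (np.cos(a) * (x - px) + np.sin(a) * (y - py)))
            g = (g + 1.5) / 4.5
        else:
            g = grid_intensity(x, y, gt.spacing, gt.orientation, gt.phase)
        return gt.baseline_rate + (gt.peak_rate - gt.baseline_rate) * g
    if gt.cell_type == "hd":
        hd = np.interp(t, traj.t, np.unwrap(traj.hd))
        tune = np.exp(gt.hd_kappa * (np.cos(hd - gt.hd_mu) - 1.0))
        return gt.baseline_rate + (gt.peak_rate - gt.baseline_rate) * tune
    if gt.cell_type == "speed":
        sp = np.interp(t, traj.t, traj.speed())
        return np.maximum(gt.baseline_rate + gt.speed_slope * sp, 0.0)
    # untuned
    return np.full_like(x, gt.baseline_rate)


def _max_rate(traj: Trajectory, gt: GroundTruth) -> float:
    if gt.cell_type == "speed":
        vmax = float(np.max(traj.speed())) if len(traj.t) else 0.0
        return max(gt.baseline_rate + gt.speed_slope * vmax, gt.baseline_rate)
    return max(gt.peak_rate, gt.baseline_rate)


def generate_spikes(
    traj: Trajectory,
    gt: GroundTruth,
    theta_mod: float = 0.0,
    seed: Optional[int] = None,
    unit_id: str = "u0",
    phase_drift: Optional[np.ndarray] = None,
) -> SpikeTrain:
    """Draw spikes from an inhomogeneous Poisson process by exact thinning.

    ``theta_mod`` multiplies the rate by ``1 + m*cos(2*pi*f_theta*t)``
    (f_theta = 8 Hz). ``gt.burst_prob`` optionally replaces an accepted
    spike with a burst of 2-4 spikes at 5 ms inter-spike interval.
    ``phase_drift`` is an (n_samples, 2) array of lattice-phase offsets on
    the trajectory clock (grid cells only).
    """
    if gt.cell_type == "grid" and gt.peak_rate < gt.baseline_rate:
        raise ValueError("peak_rate must be >= baseline_rate")
    if not 0.0 <= theta_mod <= 1.0:
        raise ValueError("theta_mod must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t0, t1 = float(traj.t[0]), float(traj.t[-1] + 1.0 / traj.fs)
    lam_max = _max_rate(traj, gt) * (1.0 + theta_mod)
    if lam_max <= 0:
        return SpikeTrain(unit_id, np.array([]), t0, t1)

    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    lam = _intensity_at(traj, gt, cand, phase_drift=phase_drift)
    if theta_mod > 0:
        lam = lam * (1.0 + theta_mod * np.cos(2 * np.pi * THETA_FREQ * cand))
    keep = rng.uniform(0.0, lam_max, size=n_cand) < lam
    times = cand[keep]

    if gt.burst_prob > 0 and len(times):
        seeds = rng.uniform(size=len(times)) < gt.burst_prob
        extra = []
        for ts in times[seeds]:
            n_extra = rng.integers(1, 4)  # burst of 2-4 spikes total
            extra.append(ts + 0.005 * np.arange(1, n_extra + 1))
        if extra:
            times = np.concatenate([times] + extra)
            times = np.sort(times[times < t1])
    return SpikeTrain(unit_id, np.unique(times), t0, t1)


def generate_grid_spikes(
    traj: Trajectory,
    gt: GroundTruth,
    theta_mod: float = 0.0,
    seed: Optional[int] = None,
    unit_id: str = "u0",
    phase_drift: Optional[np.ndarray] = None,
) -> SpikeTrain:
    """Grid-cell spike train (thin wrapper enforcing ``cell_type='grid'``)."""
    if gt.cell_type != "grid":
        raise ValueError("generate_grid_spikes requires cell_type='grid'")
    return generate_spikes(traj, gt, theta_mod=theta_mod, seed=seed,
                           unit_id=unit_id, phase_drift=phase_drift)


def _remap(gt: GroundTruth, rotation: float, shift: Sequence[float]) -> GroundTruth:
    """Coherent remap: rotate the lattice and shift all phases together."""
    c, s = np.cos(rotation), np.sin(rotation)
    px, py = gt.phase
    return GroundTruth(
        cell_type=gt.cell_type,
        spacing=gt.spacing,
        orientation=gt.orientation + rotation,
        phase=(c * px - s * py + shift[0], s * px + c * py + shift[1]),
        peak_rate=gt.peak_rate, baseline_rate=gt.baseline_rate,
        hd_kappa=gt.hd_kappa, hd_mu=gt.hd_mu,
        speed_slope=gt.speed_slope, burst_prob=gt.burst_prob,
    )


def generate_session_protocol(
    protocol: SessionProtocol,
    population: Sequence[GroundTruth],
    arena_size: float = 1.0,
    fs: float = 50.0,
    mean_speed: float = 0.15,
    theta_mod: float = 0.0,
    drift_mode: str = "common",
    seed: Optional[int] = None,
) -> dict:
    """Generate a full multi-session experiment with a shared population.

    In Novel sessions every grid cell receives the same lattice rotation
    and phase shift (coherent remapping); Familiar II reuses the
    Familiar I map. ``protocol.drift_sigma > 0`` adds a random-walk phase
    drift within Novel sessions — shared by all cells (``drift_mode=
    'common'``, preserving pairwise offsets) or drawn per cell
    (``'independent'``, destroying them).

    Returns
    -------
    dict
        ``{"sessions": [{"label", "trajectory", "spikes": [SpikeTrain...]}],
        "population": [...], "protocol": protocol}``
    """
    if not population:
        raise ValueError("population must be non-empty")
    if drift_mode not in ("common", "independent"):
        raise ValueError("drift_mode must be 'common' or 'independent'")
    root = np.random.default_rng(seed)
    sessions = []
    for si, (label, dur) in enumerate(zip(protocol.labels, protocol.durations)):
        traj = generate_trajectory(dur, arena_size, fs, mean_speed,
                                   seed=int(root.integers(2**31)))
        novel = label.startswith("Novel")
        spikes = []
        n_samp = len(traj.t)
        dt = 1.0 / fs
        common_drift = None
        if novel and protocol.drift_sigma > 0 and drift_mode == "common":
            steps = root.normal(0.0, protocol.drift_sigma * np.sqrt(dt), (n_samp, 2))
            steps[0] = 0.0
            common_drift = np.cumsum(steps, axis=0)
        for ci, gt in enumerate(population):
            gt_s = gt
            drift = common_drift
            if novel and gt.cell_type == "grid":
                gt_s = _remap(gt, protocol.remap_rotation, protocol.remap_shift)
                if protocol.drift_sigma > 0 and drift_mode == "independent":
                    steps = root.normal(0.0, protocol.drift_sigma * np.sqrt(dt),
                                        (n_samp, 2))
                    steps[0] = 0.0
                    drift = np.cumsum(steps, axis=0)
            elif not novel:
                drift = None
            spikes.append(generate_spikes(
                traj, gt_s, theta_mod=theta_mod,
                seed=int(root.integers(2**31)),
                unit_id=f"u{ci}", phase_drift=drift))
        sessions.append({"label": label, "trajectory": traj, "spikes": spikes})
    return {"sessions": sessions, "population": list(population),
            "protocol": protocol}


def generate_lfp(
    traj: Trajectory,
    f0: float = 7.0,
    beta_f: float = 2.0,
    a0: float = 1.0,
    beta_a: float = 1.5,
    noise_exponent: float = 1.0,
    noise_sd: float = 0.5,
    fs: float = 250.0,
    seed: Optional[int] = None,
) -> LfpSignal:
    """Speed-coupled theta LFP plus 1/f^exponent background noise.

    The theta oscillator has instantaneous frequency ``f0 + beta_f*v(t)``
    and amplitude ``a0 + beta_a*v(t)`` where ``v`` is the running speed
    resampled to the LFP clock. Synthesized directly at the analysis rate
    (250 Hz by default).
    """
    vmax = float(np.max(traj.speed())) if len(traj.t) else 0.0
    if fs < 2.0 * (f0 + beta_f * vmax):
        raise ValueError("fs violates Nyquist for the requested theta band")
    rng = np.random.default_rng(seed)
    n = int(round(traj.duration * fs))
    t = traj.t[0] + np.arange(n) / fs
    v = np.interp(t, traj.t, traj.speed())
    freq = f0 + beta_f * v
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    amp = a0 + beta_a * v
    sig = amp * np.cos(phase)
    if noise_sd > 0:
        white = rng.normal(size=n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        shaping = np.ones_like(f)
        nz = f > 0
        shaping[nz] = f[nz] ** (-noise_exponent / 2.0)
        shaping[0] = 0.0
        noise = np.fft.irfft(spec * shaping, n=n)
        noise *= noise_sd / np.std(noise)
        sig = sig + noise
    return LfpSignal(samples=sig, fs=fs, t_start=float(traj.t[0]))


def waveform_template(
    trough_to_peak_ms: float,
    half_width_ms: float = 0.25,
    fs: float = 48000.0,
    n_samples: int = 50,
    amplitude: float = 100.0,
) -> np.ndarray:
    """Biphasic extracellular waveform: negative trough then positive peak.

    Built from two Gaussians; ``half_width_ms`` sets the FWHM of the
    trough. Returns a single-channel ``(1, n_samples)`` array in µV.
    """
    t = np.arange(n_samples) / fs * 1e3  # ms
    t_trough = 0.25  # ms into the window
    s_tr = half_width_ms / 2.355  # FWHM -> sigma
    s_pk = s_tr * 1.8
    w = (-amplitude * np.exp(-0.5 * ((t - t_trough) / s_tr) ** 2)
         + 0.45 * amplitude * np.exp(-0.5 * ((t - t_trough - trough_to_peak_ms) / s_pk) ** 2))
    return w[np.newaxis, :]


def generate_waveforms(
    n_narrow: int,
    n_broad: int,
    noise_sd: float = 0.0,
    fs: float = 48000.0,
    seed: Optional[int] = None,
) -> tuple:
    """Mean waveforms for narrow- (~0.2 ms) and broad- (~0.6 ms) spiking units.

    Returns ``(waveforms, labels)`` where labels are the ground-truth
    strings ``'narrow'`` / ``'broad'``.
    """
    if n_narrow < 0 or n_broad < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    waveforms: List[np.ndarray] = []
    labels: List[str] = []
    for _ in range(n_narrow):
        w = waveform_template(0.2, half_width_ms=0.15, fs=fs)
        waveforms.append(w + rng.normal(0.0, noise_sd, size=w.shape))
        labels.append("narrow")
    for _ in range(n_broad):
        w = waveform_template(0.6, half_width_ms=0.3, fs=fs)
        waveforms.append(w + rng.normal(0.0, noise_sd, size=w.shape))
        labels.append("broad")
    return waveforms, labels
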