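"""Theta-band LFP analysis: Morlet wavelet spectrogram, speed coupling, PSD.

The LFP is analysed at 250 Hz after anti-alias decimation and per-session
z-scoring. Time-frequency decomposition uses a Morlet wavelet with
nondimensional frequency omega0 = 80 — an unusually narrow-band choice
that trades time resolution for precise instantaneous-frequency
estimates in the 4-12 Hz theta band. Speed coupling is summarised by a
power score and a frequency score: the Pearson correlation of theta-band
power (respectively peak frequency) with running speed over 1 s bins.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .types import LfpSignal, Trajectory

__all__ = [
    "Spectrogram",
    "ThetaSpeedProfile",
    "preprocess_lfp",
    "wavelet_spectrogram",
    "speed_theta_profile",
    "power_frequency_scores",
    "psd_theta_peak",
]

OMEGA0 = 80.0
THETA_BAND = (4.0, 12.0)  # Hz, wavelet measures
PSD_THETA_BAND = (6.0, 12.0)  # Hz, Welch peak search
SPEED_RANGE = (0.02, 1.0)  # m/s


@dataclass
class Spectrogram:
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s
    power: np.ndarray  # (n_freqs, n_times), |W|^2, COI bins are NaN
    omega0: float = OMEGA0

    def band_power(self, band: Tuple[float, float] = THETA_BAND) -> np.ndarray:
        """Mean power over the band per time sample.

        Samples where any band frequency lies inside the cone of
        influence are NaN: the band's lowest frequency has the widest
        cone, and mixing partially valid columns would bias both the
        average and the peak toward high frequencies near the edges.
        """
        m = (self.freqs >= band[0]) & (self.freqs <= band[1])
        p = self.power[m]
        out = np.full(p.shape[1], np.nan)
        ok = ~np.any(np.isnan(p), axis=0)
        out[ok] = p[:, ok].mean(axis=0)
        return out

    def peak_frequency(self, band: Tuple[float, float] = THETA_BAND) -> np.ndarray:
        """Frequency of maximum power within the band per time sample.

        Valid only where the whole band is outside the cone of influence
        (see ``band_power``).
        """
        m = (self.freqs >= band[0]) & (self.freqs <= band[1])
        p = self.power[m]
        f = self.freqs[m]
        out = np.full(p.shape[1], np.nan)
        ok = ~np.any(np.isnan(p), axis=0)
        out[ok] = f[np.argmax(p[:, ok], axis=0)]
        return out


@dataclass
class ThetaSpeedProfile:
    speed_edges: np.ndarray  # m/s
    band_power: np.ndarray  # mean theta power per speed bin
    peak_frequency: np.ndarray  # mean theta peak frequency per speed bin
    counts: np.ndarray  # samples per bin


def preprocess_lfp(raw: np.ndarray, raw_fs: float, target_fs: float = 250.0) -> LfpSignal:
    """Decimate a raw LFP trace to the analysis rate and z-score it.

    Applies an anti-alias low-pass (built into the polyphase resampler)
    before downsampling. Raises on NaN samples and on zero variance.
    """
    raw = np.asarray(raw, dtype=float)
    if raw_fs < 2 * target_fs:
        raise ValueError("raw_fs must be at least twice the target rate")
    bad = np.where(~np.isfinite(raw))[0]
    if len(bad):
        raise ValueError(f"non-finite samples at indices {bad[:10].tolist()}"
                         + ("..." if len(bad) > 10 else ""))
    if np.ptp(raw) == 0:
        raise ValueError("constant signal cannot be z-scored")
    from fractions import Fraction
    frac = Fraction(target_fs / raw_fs).limit_denominator(10000)
    x = sps.resample_poly(raw, frac.numerator, frac.denominator)
    sd = np.std(x)
    if sd < 1e-6 * max(1.0, float(np.max(np.abs(x), initial=0.0))):
        raise ValueError("constant signal cannot be z-scored")
    return LfpSignal(samples=(x - np.mean(x)) / sd, fs=target_fs)


def _morlet_fft_kernel(freqs: np.ndarray, omega: np.ndarray, dt: float,
                       omega0: float) -> np.ndarray:
    """Fourier transform of the Morlet wavelet at each analysis frequency.

    Torrence-Compo normalisation: psi_hat(s*w) = pi^(-1/4) * sqrt(2*pi*s/dt)
    * H(w) * exp(-(s*w - omega0)^2 / 2), with scale s = omega0/(2*pi*f)
    (the large-omega0 limit of the exact relation).
    """
    scales = omega0 / (2 * np.pi * freqs)
    k = np.zeros((len(freqs), len(omega)))
    pos = omega > 0
    for i, s in enumerate(scales):
        k[i, pos] = (np.pi ** -0.25) * np.sqrt(2 * np.pi * s / dt) \
            * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
    return k


def wavelet_spectrogram(
    lfp: LfpSignal,
    fmin: float = 2.0,
    fmax: float = 20.0,
    df: float = 0.1,
    omega0: float = OMEGA0,
    mask_coi: bool = True,
) -> Spectrogram:
    """Morlet continuous wavelet power of an LFP trace.

    Frequencies run from ``fmin`` to ``fmax`` in steps of ``df``. Samples
    inside the cone of influence (within sqrt(2)*scale of either edge)
    are set to NaN when ``mask_coi`` so that band averages are not biased
    by edge effects at the lowest frequencies.
    """
    x = lfp.samples
    n = len(x)
    dt = 1.0 / lfp.fs
    freqs = np.arange(fmin, fmax + df / 2, df)
    min_support = (2 * np.sqrt(2) * omega0 / (2 * np.pi * fmin)) / dt
    if n < min_support:
        raise ValueError("signal too short for the lowest analysis frequency")
    omega = 2 * np.pi * np.fft.fftfreq(n, d=dt)
    xf = np.fft.fft(x)
    kern = _morlet_fft_kernel(freqs, omega, dt, omega0)
    power = np.empty((len(freqs), n), dtype=np.float32)
    scales = omega0 / (2 * np.pi * freqs)
    for i in range(len(freqs)):
        w = np.fft.ifft(xf * kern[i])
        p = (np.abs(w) ** 2).astype(np.float32)
        if mask_coi:
            n_edge = int(np.ceil(np.sqrt(2) * scales[i] / dt))
            if n_edge > 0:
                p[:min(n_edge, n)] = np.nan
                p[max(n - n_edge, 0):] = np.nan
        power[i] = p
    times = lfp.t_start + np.arange(n) * dt
    return Spectrogram(freqs=freqs, times=times, power=power, omega0=omega0)


def speed_theta_profile(
    spec: Spectrogram,
    traj: Trajectory,
    band: Tuple[float, float] = THETA_BAND,
    speed_range: Tuple[float, float] = SPEED_RANGE,
    bin_width: float = 0.02,
) -> ThetaSpeedProfile:
    """Theta power and peak frequency conditioned on running speed.

    Speed is linearly resampled to the LFP clock; a weighted histogram
    over speed bins of ``bin_width`` m/s yields the mean theta-band power
    and mean peak frequency per bin. Empty bins are NaN.
    """
    v = np.interp(spec.times, traj.t, traj.speed())
    bp = spec.band_power(band)
    pf = spec.peak_frequency(band)
    edges = np.arange(speed_range[0], speed_range[1] + bin_width / 2, bin_width)
    nb = len(edges) - 1
    power = np.full(nb, np.nan)
    freq = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    idx = np.digitize(v, edges) - 1
    for b in range(nb):
        m = (idx == b) & np.isfinite(bp)
        counts[b] = int(m.sum())
        if counts[b]:
            power[b] = float(np.mean(bp[m]))
            mf = (idx == b) & np.isfinite(pf)
            if mf.any():
                freq[b] = float(np.mean(pf[mf]))
    return ThetaSpeedProfile(edges, power, freq, counts)


def power_frequency_scores(
    lfp: LfpSignal,
    traj: Trajectory,
    band: Tuple[float, float] = THETA_BAND,
    bin_duration: float = 1.0,
    speed_range: Tuple[float, float] = SPEED_RANGE,
    min_bins: int = 10,
) -> Tuple[float, float]:
    """Speed coupling of theta power and frequency (Pearson r each).

    Theta-band power and peak frequency are averaged in ``bin_duration``
    time bins; bins whose mean speed falls outside ``speed_range`` are
    discarded; the scores are the correlations of the binned power and
    frequency against the binned speed.
    """
    if lfp.duration < 60.0:
        raise ValueError("session must be at least 60 s")
    spec = wavelet_spectrogram(lfp, fmin=band[0], fmax=band[1])
    bp = spec.band_power(band)
    pf = spec.peak_frequency(band)
    v = np.interp(spec.times, traj.t, traj.speed())
    n_per = int(round(bin_duration * lfp.fs))
    n_bins = len(bp) // n_per

    def binmean(x):
        return np.nanmean(x[:n_bins * n_per].reshape(n_bins, n_per), axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        bp_b, pf_b, v_b = binmean(bp), binmean(pf), binmean(v)
    ok = ((v_b >= speed_range[0]) & (v_b <= speed_range[1])
          & np.isfinite(bp_b) & np.isfinite(pf_b))
    if ok.sum() < min_bins:
        return np.nan, np.nan
    power_score = float(np.corrcoef(bp_b[ok], v_b[ok])[0, 1])
    freq_score = float(np.corrcoef(pf_b[ok], v_b[ok])[0, 1])
    return power_score, freq_score


def psd_theta_peak(
    lfp: LfpSignal,
    band: Tuple[float, float] = PSD_THETA_BAND,
    nperseg: int = 1024,
) -> Tuple[float, float]:
    """Welch-PSD theta peak: (peak power in dB/Hz, peak frequency in Hz).

    The peak is the maximum of the PSD within ``band`` (6-12 Hz by
    default). When the maximum sits on the band edge (no interior local
    maximum) a warning is issued and the boundary value returned.
    """
    f, pxx = sps.welch(lfp.samples, fs=lfp.fs, nperseg=min(nperseg, len(lfp.samples)))
    m = (f >= band[0]) & (f <= band[1])
    fb, pb = f[m], pxx[m]
    i = int(np.argmax(pb))
    if i in (0, len(pb) - 1):
        warnings.warn("theta peak at band boundary; no interior maximum")
    return float(10 * np.log10(pb[i])), float(fb[i])
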