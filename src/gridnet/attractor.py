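"""Continuous attractor network of exponential integrate-and-fire neurons.

Excitatory (E) and inhibitory (I) populations sit on equal square grids
spanning a periodic sheet [0, 2*pi)^2. Each E unit projects to I units
inside a doughnut-shaped annulus of torus distance around it; each I unit
inhibits all E units inside a local disc. There are no E-E or I-I
chemical connections: excitatory units interact only through inhibition,
and the competitive surround suppression makes the population activity
settle into a hexagonal bump pattern on the sheet — the attractor-model
account of grid-cell firing.

Membrane dynamics (exponential integrate-and-fire):

    C_m dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T) + I_syn

with I_syn = -sum_i g_i(t) (V - E_rev,i) and conductances following the
beta function (difference of exponentials) normalised so a single event
peaks at the synaptic weight w. Spikes are emitted when V crosses V_peak,
the potential resets to V_reset (default E_L) and is clamped for the
refractory period. E units receive independent Poisson drive.

Perineuronal-net removal is modelled either as a scaling down of the
E-to-I synaptic weight (``reduced_EI``) or as an increase of the
inhibitory membrane capacitance (``increased_Cm``).

Internal units: pF, nS, mV, ms (so conductance*voltage = pA and
pA*ms/pF = mV, no conversion factors).
"""
from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse

from .gridness import GridnessResult, gridness_score
from .ratemaps import Autocorrelogram

__all__ = [
    "EIFParams",
    "SynapseParams",
    "ConnectivitySpec",
    "AttractorConfig",
    "SimResult",
    "build_connectivity",
    "simulate_network",
    "apply_pnn_manipulation",
    "population_rate_summary",
    "sheet_activity_map",
    "sheet_pattern_gridness",
]


@dataclass
class EIFParams:
    c_m: float = 200.0  # pF
    g_l: float = 10.0  # nS
    e_l: float = -70.0  # mV
    v_t: float = -50.0  # mV
    delta_t: float = 2.0  # mV
    v_reset: float = -70.0  # mV
    v_peak: float = 0.0  # mV, numerical spike cutoff
    t_ref: float = 2.0  # ms

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.v_peak <= self.v_t:
            raise ValueError("v_peak must exceed v_t")
        if self.v_reset > self.v_t:
            raise ValueError("v_reset must not exceed v_t")


@dataclass
class SynapseParams:
    tau_rise: float = 1.0  # ms
    tau_decay: float = 5.0  # ms
    e_rev: float = 0.0  # mV
    delay: float = 1.0  # ms

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")

    @property
    def t_peak(self) -> float:
        """Time to peak of the beta-function conductance."""
        td, tr = self.tau_decay, self.tau_rise
        return td * tr / (td - tr) * np.log(td / tr)

    @property
    def k_norm(self) -> float:
        """Normalisation so the peak conductance equals the weight w."""
        tp = self.t_peak
        return 1.0 / (np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))


@dataclass
class ConnectivitySpec:
    g_ei: float = 8.0  # nS, E->I weight
    r_ei_inner: float = 0.7  # sheet units
    r_ei_outer: float = 1.1
    g_ie: float = 30.0  # nS, I->E weight
    r_ie_outer: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.r_ei_inner < self.r_ei_outer:
            raise ValueError("need 0 <= r_ei_inner < r_ei_outer")
        if self.r_ie_outer <= 0:
            raise ValueError("r_ie_outer must be positive")


@dataclass
class AttractorConfig:
    n_side: int = 100  # units per side, each population
    eif_e: EIFParams = field(default_factory=EIFParams)
    eif_i: EIFParams = field(default_factory=lambda: EIFParams(c_m=100.0))
    syn_ei: SynapseParams = field(default_factory=lambda: SynapseParams(e_rev=0.0))
    syn_ie: SynapseParams = field(default_factory=lambda: SynapseParams(e_rev=-80.0))
    syn_ext: SynapseParams = field(default_factory=lambda: SynapseParams(e_rev=0.0, delay=0.0))
    conn: ConnectivitySpec = field(default_factory=ConnectivitySpec)
    p_rate: float = 2000.0  # Hz, Poisson drive per E unit
    w_ext: float = 0.35  # nS
    dt: float = 0.1  # ms
    duration: float = 4.0  # s
    settle: float = 1.0  # s, excluded from rate statistics
    seed: int = 0

    @property
    def n_per_pop(self) -> int:
        return self.n_side ** 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AttractorConfig":
        d = dict(d)
        for key, typ in (("eif_e", EIFParams), ("eif_i", EIFParams),
                         ("syn_ei", SynapseParams), ("syn_ie", SynapseParams),
                         ("syn_ext", SynapseParams), ("conn", ConnectivitySpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


@dataclass
class SimResult:
    spike_times: List[np.ndarray]  # s, per neuron (E block then I block)
    n_e: int
    n_i: int
    duration: float  # s
    settle: float  # s
    config: AttractorConfig

    def rates(self, population: str = "E",
              window: Optional[Tuple[float, float]] = None) -> np.ndarray:
        """Per-neuron mean firing rate (Hz) over the analysis window."""
        if window is None:
            window = (self.settle, self.duration)
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("zero-duration analysis window")
        sl = slice(0, self.n_e) if population == "E" else \
            slice(self.n_e, self.n_e + self.n_i)
        counts = np.array([np.sum((st >= t0) & (st < t1))
                           for st in self.spike_times[sl]])
        return counts / (t1 - t0)


def sheet_positions(n_side: int) -> np.ndarray:
    """Neuron coordinates on the [0, 2*pi)^2 sheet, row-major (x fast)."""
    step = 2 * np.pi / n_side
    ax = np.arange(n_side) * step
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def _torus_distance_sq(pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
    """Pairwise squared torus distance, periodic with period 2*pi."""
    d = np.abs(pos_a[:, None, :] - pos_b[None, :, :])
    d = np.minimum(d, 2 * np.pi - d)
    return (d ** 2).sum(axis=-1)


def build_connectivity(config: AttractorConfig) -> Tuple[sparse.csr_matrix,
                                                         sparse.csr_matrix]:
    """Weighted adjacency (W_ei: n_E x n_I, W_ie: n_I x n_E).

    ``W_ei[e, i] = g_ei`` when the torus distance between E unit e and I
    unit i lies strictly inside the annulus ``(r_ei_inner, r_ei_outer)``;
    ``W_ie[i, e] = g_ie`` when the distance is strictly below
    ``r_ie_outer``. Both populations share the same lattice coordinates.
    """
    c = config.conn
    pos = sheet_positions(config.n_side)
    d2 = _torus_distance_sq(pos, pos)
    ei = (d2 > c.r_ei_inner ** 2) & (d2 < c.r_ei_outer ** 2)
    if not ei.any():
        raise ValueError("empty E->I annulus")
    # disc r < r_outer. The usual formulation writes the open interval
    # 0 < r, but that is continuum notation: on the discrete lattice the
    # co-located E unit (r = 0 to its paired I) is the nearest "close by"
    # target and is included, matching the disc-mask semantics of
    # grid-based network simulators.
    ie = d2 < c.r_ie_outer ** 2
    w_ei = sparse.csr_matrix(ei.astype(float) * c.g_ei)
    w_ie = sparse.csr_matrix(ie.T.astype(float) * c.g_ie)
    return w_ei, w_ie


def simulate_network(config: AttractorConfig,
                     record_vm: bool = False) -> SimResult:
    """Fixed-step (forward Euler) integration of the full E/I network.

    Conductances follow beta-function kinetics implemented as two
    exponentially decaying state variables per synapse type; a spike
    arriving at time t0 with weight w adds ``w*K`` to both, so the
    difference peaks at exactly w after ``t_peak``. Spikes are delivered
    after the synaptic delay through a ring buffer. The exponential
    spike-initiation term is evaluated with V clamped at V_peak to avoid
    overflow. Fully reproducible under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_pop
    dt = config.dt
    n_steps = int(round(config.duration * 1000.0 / dt))
    w_ei, w_ie = build_connectivity(config)
    # pre-scale by the beta normalisation so deliveries add w*K directly
    w_ei = w_ei * config.syn_ei.k_norm
    w_ie = w_ie * config.syn_ie.k_norm

    pe, pi = config.eif_e, config.eif_i
    ve = np.full(n, pe.e_l) + rng.uniform(0.0, 5.0, n)  # small jitter breaks symmetry
    vi = np.full(n, pi.e_l)
    ref_e = np.zeros(n)
    ref_i = np.zeros(n)

    # conductance state: decay/rise pairs per synapse type
    g_ext_d = np.zeros(n); g_ext_r = np.zeros(n)
    g_ie_d = np.zeros(n); g_ie_r = np.zeros(n)  # onto E
    g_ei_d = np.zeros(n); g_ei_r = np.zeros(n)  # onto I

    dec = {}
    for name, syn in (("ext", config.syn_ext), ("ie", config.syn_ie),
                      ("ei", config.syn_ei)):
        dec[name] = (np.exp(-dt / syn.tau_decay), np.exp(-dt / syn.tau_rise))
    d_ei = max(1, int(round(config.syn_ei.delay / dt)))
    d_ie = max(1, int(round(config.syn_ie.delay / dt)))
    buf_len = max(d_ei, d_ie) + 1
    buf_ei = np.zeros((buf_len, n))  # pending increments onto I
    buf_ie = np.zeros((buf_len, n))  # pending increments onto E

    p_ext = config.p_rate * dt / 1000.0
    wk_ext = config.w_ext * config.syn_ext.k_norm
    e_rev_ext = config.syn_ext.e_rev
    e_rev_ie = config.syn_ie.e_rev
    e_rev_ei = config.syn_ei.e_rev

    spikes_e: List[List[float]] = [[] for _ in range(n)]
    spikes_i: List[List[float]] = [[] for _ in range(n)]
    exp_cap_e = (pe.v_peak - pe.v_t) / pe.delta_t
    exp_cap_i = (pi.v_peak - pi.v_t) / pi.delta_t

    for step in range(n_steps):
        t_ms = step * dt
        slot = step % buf_len
        # deliver pending increments
        inc_i = buf_ei[slot]
        g_ei_d += inc_i; g_ei_r += inc_i
        inc_e = buf_ie[slot]
        g_ie_d += inc_e; g_ie_r += inc_e
        buf_ei[slot] = 0.0
        buf_ie[slot] = 0.0
        # Poisson drive onto E (no delay)
        drive = rng.poisson(p_ext, n) * wk_ext
        g_ext_d += drive; g_ext_r += drive

        g_exc_e = g_ext_d - g_ext_r
        g_inh_e = g_ie_d - g_ie_r
        g_exc_i = g_ei_d - g_ei_r

        # E membrane
        exp_e = pe.g_l * pe.delta_t * np.exp(
            np.minimum((ve - pe.v_t) / pe.delta_t, exp_cap_e))
        i_syn_e = -g_exc_e * (ve - e_rev_ext) - g_inh_e * (ve - e_rev_ie)
        ve += dt / pe.c_m * (-pe.g_l * (ve - pe.e_l) + exp_e + i_syn_e)
        # I membrane
        exp_i = pi.g_l * pi.delta_t * np.exp(
            np.minimum((vi - pi.v_t) / pi.delta_t, exp_cap_i))
        i_syn_i = -g_exc_i * (vi - e_rev_ei)
        vi += dt / pi.c_m * (-pi.g_l * (vi - pi.e_l) + exp_i + i_syn_i)

        in_ref_e = ref_e > 0
        ve[in_ref_e] = pe.v_reset
        ref_e[in_ref_e] -= dt
        in_ref_i = ref_i > 0
        vi[in_ref_i] = pi.v_reset
        ref_i[in_ref_i] -= dt

        if not (np.all(np.isfinite(ve)) and np.all(np.isfinite(vi))):
            raise FloatingPointError(
                f"membrane potential diverged at t = {t_ms:.2f} ms")

        sp_e = ve >= pe.v_peak
        sp_i = vi >= pi.v_peak
        if sp_e.any():
            ve[sp_e] = pe.v_reset
            ref_e[sp_e] = pe.t_ref
            t_s = (t_ms + dt) / 1000.0
            for idx in np.where(sp_e)[0]:
                spikes_e[idx].append(t_s)
            buf_ei[(step + d_ei) % buf_len] += w_ei.T @ sp_e.astype(float)
        if sp_i.any():
            vi[sp_i] = pi.v_reset
            ref_i[sp_i] = pi.t_ref
            t_s = (t_ms + dt) / 1000.0
            for idx in np.where(sp_i)[0]:
                spikes_i[idx].append(t_s)
            buf_ie[(step + d_ie) % buf_len] += w_ie.T @ sp_i.astype(float)

        # decay conductance states
        g_ext_d *= dec["ext"][0]; g_ext_r *= dec["ext"][1]
        g_ie_d *= dec["ie"][0]; g_ie_r *= dec["ie"][1]
        g_ei_d *= dec["ei"][0]; g_ei_r *= dec["ei"][1]

    spike_times = [np.array(s) for s in spikes_e] + [np.array(s) for s in spikes_i]
    return SimResult(spike_times=spike_times, n_e=n, n_i=n,
                     duration=config.duration, settle=config.settle,
                     config=config)


REDUCED_EI_FACTOR = 0.7  # default E->I weight scaling for PNN removal
INCREASED_CM_FACTOR = 1.5  # default inhibitory capacitance scaling


def desk_config(seed: int = 1, n_side: int = 40, duration: float = 4.0,
                settle: float = 1.5) -> AttractorConfig:
    """Calibrated desk-scale configuration (40 x 40 per population).

    Same connectivity and drive as the full-scale default; the smaller
    sheet holds ~14 activity bumps and a few seconds of simulated time
    suffice for the pattern and rate statistics, keeping a run well under
    a minute on one core.
    """
    return AttractorConfig(n_side=n_side, duration=duration, settle=settle,
                           seed=seed)


def apply_pnn_manipulation(config: AttractorConfig, kind: str,
                           factor: float) -> AttractorConfig:
    """Return a config with the PNN-removal manipulation applied.

    ``reduced_EI`` scales the E->I weight by ``factor`` (expected < 1);
    ``increased_Cm`` scales the inhibitory membrane capacitance
    (expected > 1). A factor in the unexpected direction only warns.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    new = copy.deepcopy(config)
    if kind == "reduced_EI":
        if factor > 1:
            warnings.warn("reduced_EI with factor > 1 increases the weight")
        new.conn.g_ei *= factor
    elif kind == "increased_Cm":
        if factor < 1:
            warnings.warn("increased_Cm with factor < 1 decreases capacitance")
        new.eif_i.c_m *= factor
    else:
        raise ValueError("kind must be 'reduced_EI' or 'increased_Cm'")
    return new


def population_rate_summary(result: SimResult,
                            window: Optional[Tuple[float, float]] = None) -> Dict:
    """Median and distribution of per-neuron rates, per population.

    Reports medians over all units and over active units (at least one
    spike in the window) separately, since the appropriate inclusion rule
    depends on the question asked.
    """
    out: Dict[str, Dict] = {}
    for pop in ("E", "I"):
        r = result.rates(pop, window)
        active = r[r > 0]
        out[pop] = {
            "rates": r,
            "median_all": float(np.median(r)),
            "median_active": float(np.median(active)) if len(active) else 0.0,
            "mean_all": float(np.mean(r)),
            "n_active": int(len(active)),
        }
    return out


def sheet_activity_map(result: SimResult, population: str = "E",
                       window: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Per-neuron rates arranged as the (n_side, n_side) sheet image."""
    n_side = result.config.n_side
    return result.rates(population, window).reshape(n_side, n_side)


def sheet_field_peak(result: SimResult, sigma: float = 1.5,
                     window: Optional[Tuple[float, float]] = None) -> float:
    """Peak of the smoothed E-population sheet map (Hz).

    Single-unit spike counts over a few seconds are Poisson-noisy, so the
    field-level peak — the maximum of the sheet image after a small
    wrap-around Gaussian smoothing (``sigma`` in lattice units) — is the
    read-out used to compare within-field activity across conditions.
    """
    from scipy import ndimage as _ndi
    img = sheet_activity_map(result, "E", window)
    return float(_ndi.gaussian_filter(img, sigma, mode="wrap").max())


def _wrap_autocorrelogram(img: np.ndarray) -> Autocorrelogram:
    """Periodic autocorrelation of the sheet image, peak at the center."""
    z = img - img.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd
    f = np.fft.fft2(z)
    ac = np.fft.ifft2(f * np.conj(f)).real / z.size
    ac = np.roll(ac, (img.shape[0] // 2, img.shape[1] // 2), axis=(0, 1))
    return Autocorrelogram(values=ac, bin_size=2 * np.pi / img.shape[0])


def sheet_pattern_gridness(result: SimResult,
                           window: Optional[Tuple[float, float]] = None
                           ) -> Tuple[np.ndarray, GridnessResult]:
    """Hexagonality of the population pattern on the neuronal sheet.

    The E-population rate image over the window is autocorrelated with
    periodic (torus) boundaries and scored with the standard rotational
    gridness; returns ``(sheet_image, GridnessResult)``.
    """
    if window is not None:
        if window[1] <= window[0] or window[1] > result.duration + 1e-9:
            raise ValueError("window must be non-empty and inside the simulation")
    img = sheet_activity_map(result, "E", window)
    ac = _wrap_autocorrelogram(img)
    return img, gridness_score(ac)
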