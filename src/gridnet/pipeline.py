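"""End-to-end per-unit analysis used by the command-line interface.

``analyze_unit`` runs the full single-unit chain — rate map,
autocorrelogram, gridness and spacing, firing fields, in/out-field rates,
spatial specificity and information, ISI variability, bursting, speed and
head-direction scores — and returns one tidy record per unit.
"""
from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import fields, gridness, ratemaps, spike_metrics, tuning
from .types import SpikeTrain, Trajectory

__all__ = ["analyze_unit", "analyze_session"]


def analyze_unit(
    spk: SpikeTrain,
    traj: Trajectory,
    bin_size: float = 0.02,
    sigma: float = 0.03,
) -> Dict[str, float]:
    """All per-unit metrics of one session as a flat record."""
    rm = ratemaps.compute_rate_map(spk, traj, bin_size, sigma)
    ac = ratemaps.compute_autocorrelogram(rm)
    ac_n = ratemaps.compute_autocorrelogram(rm, normalize=True)
    g = gridness.gridness_score(ac)
    g_n = gridness.gridness_score(ac_n)
    fm = fields.identify_fields(rm, ac_n) if np.isfinite(g_n.score) else \
        fields.FieldMap(labels=np.zeros_like(rm.values, dtype=int))
    rec: Dict[str, float] = {
        "unit_id": spk.unit_id,
        "n_spikes": len(spk),
        "mean_rate": spk.mean_rate,
        "max_rate": float(rm.values.max()),
        "gridness": g.score,
        "spacing": g_n.spacing,
        "spatial_information": fields.spatial_information(rm),
        "n_fields": fm.n_fields,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fm.n_fields:
            io_rates = fields.in_out_field_rates(spk, traj, fm, bin_size)
            rec["fr_in_field"] = io_rates.fr_in_field
            rec["fr_out_field"] = io_rates.fr_out_field
            rec["spatial_specificity"] = fields.spatial_specificity(io_rates)
            rec["cv_isi_field_pass"] = spike_metrics.cv_isi(
                spk, traj, fm, method="in_field_pass", bin_size=bin_size).cv
        else:
            rec["fr_in_field"] = np.nan
            rec["fr_out_field"] = np.nan
            rec["spatial_specificity"] = np.nan
            rec["cv_isi_field_pass"] = np.nan
        rec["cv_isi"] = spike_metrics.cv_isi(spk, method="whole_session").cv
        rec["burst_ratio"] = (spike_metrics.bursting_ratio(spk).ratio
                              if len(spk) >= 2 else np.nan)
        rec["within_trial_stability"] = ratemaps.within_trial_stability(
            spk, traj, bin_size, sigma)
        rec["speed_score"] = tuning.speed_score(spk, traj)
        if traj.hd is not None:
            vl, pref = tuning.head_direction_tuning(spk, traj)
            rec["hd_vector_length"] = vl
            rec["hd_preferred"] = pref
    return rec


def analyze_session(
    session: dict,
    label: Optional[str] = None,
    bin_size: float = 0.02,
    sigma: float = 0.03,
) -> pd.DataFrame:
    """Per-unit metrics for one session bundle (one row per unit)."""
    traj = session["trajectory"]
    rows = []
    for spk in session["spikes"]:
        rec = analyze_unit(spk, traj, bin_size, sigma)
        rec["session"] = label if label is not None else session.get("label", "")
        rows.append(rec)
    return pd.DataFrame(rows)
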