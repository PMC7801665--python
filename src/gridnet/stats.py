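"""Group-level statistics: Mann-Whitney U, animal-level permutation, bootstrap.

Per-unit metrics are compared between experimental groups with the
two-sided Mann-Whitney U test. Because units recorded from one animal
are not independent, a complementary permutation test shuffles the
*animal-to-group* assignment (units travel with their animal), testing
whether the group difference could arise from between-animal variation
alone. Confidence intervals for recording-level quantities use a
percentile bootstrap over recordings.
"""
from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "mann_whitney_u",
    "permutation_group_test",
    "bootstrap_ci",
    "deduplicate_first_recording",
]


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    Exact distribution for small tie-free samples, normal approximation
    with tie correction otherwise (scipy's 'auto' policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def permutation_group_test(
    values: pd.DataFrame,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> float:
    """Animal-level permutation test of a group difference in unit medians.

    ``values`` must have columns ``value``, ``animal``, ``group`` (two
    groups). The statistic is the absolute difference of group medians of
    the unit values. The null is built by permuting which animals belong
    to which group, keeping each animal's units together; the p value is
    ``(1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    required = {"value", "animal", "group"}
    if not required <= set(values.columns):
        raise ValueError(f"need columns {sorted(required)}")
    groups = values["group"].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    animals = values.groupby("animal")["group"].first()
    sizes = animals.value_counts()
    if (sizes < 2).any():
        raise ValueError("need at least two animals per group")
    rng = np.random.default_rng(seed)

    def stat(animal_to_group: pd.Series) -> float:
        g = values["animal"].map(animal_to_group)
        med = values.groupby(g)["value"].median()
        return float(abs(med.iloc[0] - med.iloc[1]))

    observed = stat(animals)
    n_a = int(sizes[groups[0]])
    animal_ids = animals.index.to_numpy()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(animal_ids)
        assign = pd.Series(
            np.where(np.isin(animal_ids, perm[:n_a]), groups[0], groups[1]),
            index=animal_ids)
        if stat(assign) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def bootstrap_ci(
    values_by_recording: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap CI of the mean over recordings.

    Recordings (one summary value each) are resampled with replacement;
    returns the (lo, hi) percentile interval of the resampled mean at the
    requested level.
    """
    vals = np.asarray([np.mean(v) for v in values_by_recording], dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two recordings")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1 - level) / 2
    return (float(np.percentile(means, 100 * alpha)),
            float(np.percentile(means, 100 * (1 - alpha))))


def deduplicate_first_recording(
    df: pd.DataFrame,
    unit_col: str = "unit_id",
    order_col: str = "recording_index",
) -> pd.DataFrame:
    """Keep only the first recording of units tracked across sessions."""
    return (df.sort_values(order_col)
              .drop_duplicates(subset=unit_col, keep="first")
              .reset_index(drop=True))
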