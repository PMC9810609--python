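"""Crossover-frequency estimation from fluorescent seed counts.

In a two-reporter interval line, F2 seeds expressing exactly one of the two
seed-fluorescent reporters derive from a recombinant gamete, so the
recombination frequency of the interval is estimated directly from seed
tallies as RF = 100 x (N_G + N_R) / N_T centimorgans, where N_G and N_R are
the green-only and red-only seed counts and N_T the total seed count of the
plant.  No map-function correction is applied: the intervals measured this
way are tens of kilobases, with r far below 0.01, where Haldane/Kosambi
corrections are negligible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .regions import IntervalSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedCounts:
    """Fluorescent seed-class tallies for one plant."""

    plant_id: str
    group: str
    n_green: int
    n_red: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_green, self.n_red, self.n_total) < 0:
            raise InputError(f"plant {self.plant_id!r}: negative seed counts")
        if self.n_green + self.n_red > self.n_total:
            raise InputError(
                f"plant {self.plant_id!r}: single-color seeds ({self.n_green}+{self.n_red}) "
                f"exceed total ({self.n_total})"
            )


def recombination_frequency(counts: SeedCounts) -> float:
    """RF in centimorgans: 100 x (N_G + N_R) / N_T."""
    if counts.n_total == 0:
        raise InputError(f"plant {counts.plant_id!r}: no seeds scored")
    return 100.0 * (counts.n_green + counts.n_red) / counts.n_total


def cm_per_mb(rf_cm: float, interval: IntervalSpec) -> float:
    """Normalize a genetic length to the interval's physical length."""
    if interval.length_bp <= 0:
        raise InputError("zero-length interval")
    return rf_cm / interval.length_mb


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_test(a, b) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    Uses the Welch-Satterthwaite degrees of freedom; this is the standard
    comparison for per-plant RF measurements between groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("welch_test requires at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise InputError("welch_test requires non-zero variance in at least one group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def summarize_groups(seed_table: list[SeedCounts], interval: IntervalSpec | None = None) -> pd.DataFrame:
    """Per-group summary of per-plant RF measurements.

    Returns one row per group with n, mean RF (cM), 25th/75th percentiles
    (linear interpolation between order statistics), and — when an interval
    is supplied — the mean normalized rate in cM/Mb.
    """
    if not seed_table:
        raise InputError("empty seed table")
    rows = []
    df = pd.DataFrame(
        {
            "group": [c.group for c in seed_table],
            "rf_cm": [recombination_frequency(c) for c in seed_table],
        }
    )
    for group, sub in df.groupby("group", sort=True):
        vals = sub.rf_cm.to_numpy()
        if vals.size == 0:  # pragma: no cover - groupby never yields empty groups
            log.warning("group %s has no plants; omitted", group)
            continue
        row = {
            "group": group,
            "n": int(vals.size),
            "mean_rf_cm": float(vals.mean()),
            "pct25_rf_cm": float(np.percentile(vals, 25)),
            "pct75_rf_cm": float(np.percentile(vals, 75)),
        }
        if interval is not None:
            row["mean_cm_per_mb"] = cm_per_mb(float(vals.mean()), interval)
        rows.append(row)
    return pd.DataFrame(rows)
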