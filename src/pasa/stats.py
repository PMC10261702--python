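"""Group comparisons of band-averaged relative APSD across tissue classes.

Two-sided unpaired t-tests (pooled-variance Student by default, Welch
selectable) with the usual significance-star annotation.  No
multiple-testing correction is applied: each band/pair comparison is
reported at its own per-comparison level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = ["GroupComparison", "unpaired_ttest", "stars_for", "compare_groups"]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for(p_value: float) -> str:
    for thr, stars in _STAR_THRESHOLDS:
        if p_value < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    band: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    stars: str
    degenerate: bool = False  # zero pooled variance with equal means

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def unpaired_ttest(values_a: Sequence[float], values_b: Sequence[float],
                   band: str = "", group_a: str = "a", group_b: str = "b",
                   welch: bool = False) -> GroupComparison:
    """Two-sided unpaired t-test between two groups of band features."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups contain non-finite values")
    degenerate = False
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        # zero pooled variance, equal means: no evidence either way
        t, p, degenerate = 0.0, 1.0, True
    else:
        t, p = _stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return GroupComparison(band=band, group_a=group_a, group_b=group_b,
                           n_a=a.size, n_b=b.size, t_statistic=t, p_value=p,
                           stars=stars_for(p), degenerate=degenerate)


def compare_groups(band_values: Mapping[str, Mapping[str, Sequence[float]]],
                   welch: bool = False) -> pd.DataFrame:
    """All pairwise class comparisons per band as a tidy table.

    ``band_values`` maps band -> class label -> feature values.
    """
    rows = []
    for band, groups in band_values.items():
        for ga, gb in combinations(groups, 2):
            c = unpaired_ttest(groups[ga], groups[gb], band=band,
                               group_a=ga, group_b=gb, welch=welch)
            rows.append({"band": c.band, "group_a": c.group_a, "group_b": c.group_b,
                         "n_a": c.n_a, "n_b": c.n_b, "t": c.t_statistic,
                         "p": c.p_value, "stars": c.stars})
    return pd.DataFrame(rows)
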