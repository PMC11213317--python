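"""Group comparisons of per-larva response rates.

Pairwise two-sided t tests over all group pairs with Bonferroni correction.
The default mode pools a common residual SD across *all* groups (degrees of
freedom N - k), matching the behaviour of the classical pairwise-t procedure
in standard statistical environments; Welch's unequal-variance test and a
paired test are available as alternatives.  Excluded larvae (fewer than
three valid trials) carry no rate and must not be passed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "pairwise_t_bonferroni", "comparisons_to_dataframe"]


@dataclass(frozen=True)
class ComparisonResult:
    group1: str
    group2: str
    n1: int
    n2: int
    t_statistic: float
    p_raw: float
    p_adjusted: float


def _pooled_sd(groups: Mapping[str, np.ndarray]) -> tuple[float, int]:
    """Common residual SD across all groups and its degrees of freedom."""
    ss = 0.0
    df = 0
    for x in groups.values():
        ss += float(np.sum((x - x.mean()) ** 2))
        df += len(x) - 1
    if df <= 0:
        raise ValueError("pooled SD needs at least one group with >= 2 values")
    return float(np.sqrt(ss / df)), df


def pairwise_t_bonferroni(
    groups: Mapping[str, Sequence[float]],
    pooled_sd: bool = True,
    paired: bool = False,
) -> list[ComparisonResult]:
    """All pairwise two-sided t tests, Bonferroni-corrected over the pairs.

    ``pooled_sd=True`` (default) uses the common SD of all groups; with
    ``pooled_sd=False`` each pair is tested with Welch's t.  ``paired``
    switches to a paired t test (equal group sizes required) and ignores
    ``pooled_sd``.  A pair with zero variance everywhere yields NaN
    statistics, reported as such.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, x in arrays.items():
        if len(x) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if np.isnan(x).any():
            raise ValueError(
                f"group {name!r} contains NaN rates; drop excluded larvae first"
            )
    pairs = list(combinations(arrays, 2))
    m = len(pairs)
    if pooled_sd and not paired:
        sd, df = _pooled_sd(arrays)
    out = []
    for a, b in pairs:
        x, y = arrays[a], arrays[b]
        if paired:
            if len(x) != len(y):
                raise ValueError(f"paired test needs equal sizes for {a!r}/{b!r}")
            t, p = sps.ttest_rel(x, y)
        elif pooled_sd:
            se = sd * np.sqrt(1.0 / len(x) + 1.0 / len(y))
            if se == 0:
                t, p = float("nan"), float("nan")
            else:
                t = (x.mean() - y.mean()) / se
                p = 2.0 * sps.t.sf(abs(t), df)
        else:
            t, p = sps.ttest_ind(x, y, equal_var=False)
        t, p = float(t), float(p)
        p_adj = min(1.0, p * m) if np.isfinite(p) else float("nan")
        out.append(
            ComparisonResult(
                group1=a,
                group2=b,
                n1=len(x),
                n2=len(y),
                t_statistic=t,
                p_raw=p,
                p_adjusted=p_adj,
            )
        )
    return out


def comparisons_to_dataframe(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
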