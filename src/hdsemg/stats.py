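"""Group-level statistics for feature tables.

Thin wrappers around the standard tests — Shapiro-Wilk normality checks,
paired t-tests across speed conditions with Bonferroni control of the
family-wise error, and Pearson product-moment correlation for the agreement
of the two CoG estimators.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = ["shapiro_wilk", "pairwise_t_bonferroni", "pearson_r"]


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for a sample of >= 3 scalars."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sst.shapiro(x)
    return float(w), float(p)


def pairwise_t_bonferroni(
    by_condition: Union[Mapping, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests between every pair of conditions, Bonferroni-adjusted.

    ``by_condition`` maps each condition label to its per-subject values
    (same subject order in every condition; a wide DataFrame with one column
    per condition works directly).  Adjusted p is ``min(1, p_raw * n_pairs)``;
    significance is judged at ``alpha`` on the adjusted p, so the family-wise
    error rate is controlled at ``alpha``.
    """
    if isinstance(by_condition, pd.DataFrame):
        data = {c: by_condition[c].to_numpy(dtype=float) for c in by_condition.columns}
    else:
        data = {k: np.asarray(v, dtype=float) for k, v in by_condition.items()}
    if len(data) < 2:
        raise ValueError("need at least 2 conditions")
    sizes = {k: v.size for k, v in data.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"conditions are not equally paired: {sizes}")
    n = next(iter(sizes.values()))
    if n < 3:
        raise ValueError(f"need at least 3 paired subjects, got {n}")
    pairs = list(combinations(data.keys(), 2))
    rows = []
    for a, b in pairs:
        diff = data[a] - data[b]
        if np.ptp(diff) == 0:
            # zero-variance difference: identical pairs carry no evidence,
            # a constant nonzero shift is a perfect one
            t = 0.0 if diff[0] == 0 else np.sign(diff[0]) * np.inf
            p = 1.0 if diff[0] == 0 else 0.0
        else:
            t, p = sst.ttest_rel(data[a], data[b])
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "n": n,
                "t": float(t),
                "p_raw": float(p),
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def pearson_r(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson product-moment correlation: (r, r², two-sided p).

    Zero variance in either series makes the correlation undefined; that is
    reported explicitly as an error rather than silently returning NaN.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y are not matched")
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance in a series")
    r, p = sst.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)
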