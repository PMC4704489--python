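"""Grubbs' test for outliers in approximately normal samples.

Used in three places in the pipeline: flagging failed cDNA samples by their
failure-of-expression score (upper outliers), finding the qPCR limit of
detection (lower outliers of per-assay Et distributions), and pruning
residual outliers from the variance-model fit (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GrubbsResult", "grubbs_critical_value", "grubbs_test", "iterative_grubbs"]

_ALTERNATIVES = ("max", "min", "two-sided")


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of a single Grubbs test."""

    statistic: float
    critical_value: float
    index: int  # position of the suspect value in the input
    is_outlier: bool


def grubbs_critical_value(n: int, alpha: float = 0.05, two_sided: bool = False) -> float:
    """Critical value of the Grubbs statistic for sample size ``n``.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    a/n (one-sided) or a/(2n) (two-sided) quantile of Student's t on n-2 df.
    """
    if n < 3:
        raise ValueError("Grubbs' test requires at least 3 observations")
    a = alpha / (2 * n) if two_sided else alpha / n
    t = stats.t.ppf(1.0 - a, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(
    values, alpha: float = 0.05, alternative: str = "max"
) -> GrubbsResult:
    """Test the most extreme value of ``values`` for being an outlier.

    alternative: 'max' (upper outlier), 'min' (lower outlier) or 'two-sided'.
    A sample with zero variance never yields an outlier (degenerate guard).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs' test requires at least 3 observations")
    mean = x.mean()
    sd = x.std(ddof=1)
    if alternative == "max":
        idx = int(np.argmax(x))
        dev = x[idx] - mean
    elif alternative == "min":
        idx = int(np.argmin(x))
        dev = mean - x[idx]
    else:
        idx = int(np.argmax(np.abs(x - mean)))
        dev = abs(x[idx] - mean)
    if sd == 0.0:
        return GrubbsResult(0.0, np.inf, idx, False)
    g = dev / sd
    crit = grubbs_critical_value(n, alpha, two_sided=(alternative == "two-sided"))
    return GrubbsResult(float(g), float(crit), idx, bool(g > crit))


def iterative_grubbs(
    values, alpha: float = 0.05, alternative: str = "max", max_iter: int = 50
):
    """Repeatedly remove the most extreme outlier until none is flagged.

    Returns the indices (into the original array) of removed values, in
    removal order. Stops when fewer than 3 values remain.
    """
    x = np.asarray(values, dtype=float)
    live = np.arange(x.size)
    removed: list[int] = []
    for _ in range(max_iter):
        if live.size < 3:
            break
        res = grubbs_test(x[live], alpha=alpha, alternative=alternative)
        if not res.is_outlier:
            break
        removed.append(int(live[res.index]))
        live = np.delete(live, res.index)
    return removed
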