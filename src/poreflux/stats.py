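"""Rank and summary statistics used across both analysis arms.

The Brunner–Munzel test is implemented here from its defining formulas
(midranks over the pooled sample, rank-based variance estimates, a
studentized statistic referred to a t distribution with Satterthwaite
degrees of freedom).  It tests the relative effect

    p = P(X < Y) + 1/2 P(X = Y)

against p = 1/2 and is robust to unequal variances and ties, which is why
it suits heavily skewed event-duration distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, t as t_dist


@dataclass(frozen=True)
class BMTestResult:
    """Brunner–Munzel test outcome."""

    statistic: float
    df: float
    relative_effect: float  # p̂ = P(X<Y) + 0.5 P(X=Y)
    pvalue: float
    n_x: int
    n_y: int
    degenerate: bool = False  # both rank variances zero (separation / all equal)


def brunner_munzel(
    x, y, alternative: str = "two-sided"
) -> BMTestResult:
    """Brunner–Munzel test of the relative effect P(X<Y) + 0.5 P(X=Y) = 1/2.

    Midranks handle ties exactly.  ``alternative='greater'`` tests for a
    relative effect above 1/2 (Y stochastically larger than X).  Degenerate
    inputs — zero rank variance in both groups, as with complete separation
    or two constant equal samples — are flagged, with the statistic at its
    documented limit (±inf, or 0 when the samples are indistinguishable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    n = nx + ny
    rank_all = rankdata(np.concatenate([x, y]))  # midranks
    rx, ry = rank_all[:nx], rank_all[nx:]
    rx_mean, ry_mean = rx.mean(), ry.mean()
    rx_within = rankdata(x)
    ry_within = rankdata(y)
    sx2 = np.sum((rx - rx_within - rx_mean + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - ry_within - ry_mean + (ny + 1) / 2.0) ** 2) / (ny - 1)
    p_hat = (ry_mean - (ny + 1) / 2.0) / nx

    pooled = nx * sx2 + ny * sy2
    if pooled <= 0.0:
        if p_hat == 0.5:
            stat, p_two = 0.0, 1.0
        else:
            stat = np.inf if p_hat > 0.5 else -np.inf
            p_two = 0.0
        df = float("nan")
        degenerate = True
    else:
        stat = nx * ny * (ry_mean - rx_mean) / (n * np.sqrt(pooled))
        df = pooled**2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
        p_two = 2.0 * float(t_dist.sf(abs(stat), df))
        degenerate = False

    if alternative == "two-sided":
        pvalue = p_two
    else:
        if degenerate:
            one = 0.5 if p_hat == 0.5 else (0.0 if p_hat > 0.5 else 1.0)
        else:
            one = float(t_dist.sf(stat, df))  # P(T > stat): evidence p̂ > 1/2
        pvalue = one if alternative == "greater" else 1.0 - one
    return BMTestResult(
        statistic=float(stat),
        df=float(df),
        relative_effect=float(p_hat),
        pvalue=float(min(max(pvalue, 0.0), 1.0)),
        n_x=nx,
        n_y=ny,
        degenerate=degenerate,
    )


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) under the linear-interpolation quantile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median/IQR of an empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class MeanSdSem:
    mean: float
    sd: float
    sem: float
    n: int
    sd_defined: bool  # False when n == 1 (SD reported 0 by convention)

    def __iter__(self):
        yield self.mean
        yield self.sd
        yield self.sem


def mean_sd_sem(values) -> MeanSdSem:
    """Mean, sample SD (n-1 denominator) and SEM = SD/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean/SD of an empty sample")
    n = int(v.size)
    if n == 1:
        return MeanSdSem(float(v[0]), 0.0, 0.0, 1, sd_defined=False)
    sd = float(np.std(v, ddof=1))
    return MeanSdSem(float(np.mean(v)), sd, sd / np.sqrt(n), n, sd_defined=True)
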