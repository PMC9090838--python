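"""Mann–Kendall trend detection and Sen's slope estimation for annual series.

The Mann–Kendall S statistic counts concordant minus discordant year pairs;
its large-sample normal approximation with a ±1 continuity correction gives
the Z score, classified against two-sided normal quantiles at the 0.1, 0.05
and 0.01 levels (the significance-class convention of the MAKESENS
workbook).  The trend magnitude is Sen's slope — the median of all pairwise
slopes — with a median-based (Conover) intercept.

Two variance modes are provided: ``tie_adjusted`` (default) subtracts the
standard tie term Σ tₖ(tₖ−1)(2tₖ+5)/18 from the variance of S, while
``as_printed`` uses the plain n(n−1)(2n+5)/18 form with no tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrendResult", "mk_statistic", "mk_variance", "mk_test", "sen_slope", "trend_test", "trend_table"]

#: marker symbols for significance classes (trend-figure convention:
#: ``+``, ``×`` and ``*`` for the 0.1, 0.05 and 0.01 levels).
CLASS_MARKERS = {"p<0.01": "*", "p<0.05": "x", "p<0.1": "+", "n.s.": "-"}

_Z10 = float(stats.norm.ppf(1 - 0.10 / 2))
_Z05 = float(stats.norm.ppf(1 - 0.05 / 2))
_Z01 = float(stats.norm.ppf(1 - 0.01 / 2))


@dataclass(frozen=True)
class TrendResult:
    """Mann–Kendall + Sen's slope summary of one annual series."""

    n: int
    s: int
    sigma: float
    z: float
    slope: float          # units per year
    intercept: float      # units, at t = 0 of the time axis supplied
    per_decade: float     # 10 × slope
    significance_class: str

    @property
    def marker(self) -> str:
        return CLASS_MARKERS[self.significance_class]


def mk_statistic(values: np.ndarray) -> int:
    """Mann–Kendall S: sum over all i<j of sgn(x_j − x_i)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    diff = np.sign(x[:, None] - x[None, :])
    return int(np.triu(diff.T, k=1).sum())


def mk_variance(values: np.ndarray, tie_correction: bool = True) -> float:
    """Variance of S under the no-trend null; optionally tie-adjusted."""
    x = np.asarray(values, dtype=float)
    n = x.size
    var = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_correction:
        _, counts = np.unique(x, return_counts=True)
        t = counts[counts > 1]
        var -= float(np.sum(t * (t - 1) * (2 * t + 5))) / 18.0
    return var


def _classify(z: float) -> str:
    a = abs(z)
    if a >= _Z01:
        return "p<0.01"
    if a >= _Z05:
        return "p<0.05"
    if a >= _Z10:
        return "p<0.1"
    return "n.s."


def mk_test(values: np.ndarray, mode: str = "tie_adjusted") -> tuple[float, str]:
    """Continuity-corrected Mann–Kendall Z and its significance class.

    ``Z = (S−1)/σ`` for S>0, 0 for S=0, ``(S+1)/σ`` for S<0.  ``mode`` is
    ``"tie_adjusted"`` or ``"as_printed"`` (plain variance, no tie term).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(
            f"Mann-Kendall normal approximation needs n >= 4, got n = {x.size}"
        )
    if mode not in ("tie_adjusted", "as_printed"):
        raise ValueError(f"unknown variance mode {mode!r}")
    s = mk_statistic(x)
    var = mk_variance(x, tie_correction=(mode == "tie_adjusted"))
    if var <= 0:  # fully tied series
        return 0.0, "n.s."
    sigma = float(np.sqrt(var))
    if s > 0:
        z = (s - 1) / sigma
    elif s < 0:
        z = (s + 1) / sigma
    else:
        z = 0.0
    return z, _classify(z)


def sen_slope(values: np.ndarray, times: np.ndarray | None = None) -> tuple[float, float]:
    """Sen's slope and Conover intercept of a series.

    The slope is the median of all pairwise slopes (y_j − y_k)/(t_j − t_k)
    for t_j > t_k — the middle element of the sorted slope list when their
    count is odd, the mean of the central two when even.  The intercept is
    ``median(y − slope·t)``.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least two values")
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    jj, kk = np.triu_indices(n, k=1)
    dt = t[jj] - t[kk]
    keep = dt != 0
    if not np.any(keep):
        raise ValueError("no pair of distinct time points")
    slopes = np.sort((y[jj] - y[kk])[keep] / dt[keep])
    m = slopes.size
    if m % 2 == 1:
        slope = float(slopes[(m - 1) // 2])
    else:
        slope = float(0.5 * (slopes[m // 2 - 1] + slopes[m // 2]))
    intercept = float(np.median(y - slope * t))
    return slope, intercept


def trend_test(
    values: np.ndarray,
    times: np.ndarray | None = None,
    mode: str = "tie_adjusted",
) -> TrendResult:
    """Full Mann–Kendall + Sen's slope analysis of one annual series."""
    y = np.asarray(values, dtype=float)
    z, sig = mk_test(y, mode=mode)
    s = mk_statistic(y)
    sigma = float(np.sqrt(max(mk_variance(y, mode == "tie_adjusted"), 0.0)))
    slope, intercept = sen_slope(y, times)
    return TrendResult(
        n=y.size, s=s, sigma=sigma, z=z, slope=slope,
        intercept=intercept, per_decade=10.0 * slope, significance_class=sig,
    )


def trend_table(
    tidy: pd.DataFrame,
    mode: str = "tie_adjusted",
    min_years: int = 4,
) -> pd.DataFrame:
    """Per-(station, variable) trend results from a tidy annual table.

    ``tidy`` has columns station_id, variable, year, value.  Series shorter
    than ``min_years`` are skipped.
    """
    rows = []
    for (sid, var), grp in tidy.groupby(["station_id", "variable"]):
        grp = grp.sort_values("year")
        if len(grp) < min_years:
            continue
        res = trend_test(grp["value"].to_numpy(), grp["year"].to_numpy(), mode=mode)
        rows.append({
            "station_id": sid, "variable": var, "n": res.n, "S": res.s,
            "Z": res.z, "slope": res.slope, "intercept": res.intercept,
            "per_decade": res.per_decade, "class": res.significance_class,
            "marker": res.marker,
        })
    return pd.DataFrame(rows)
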