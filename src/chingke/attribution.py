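"""First-difference attribution of potential-yield change to climate drivers.

Station-year series of potential yield and growing-season climate factors
(Tave, Tmax, Tmin, EAT, TDR, RA) are first-differenced year over year —
which removes each variable's long-term trend — then pooled into panels per
accumulated-temperature zone.  Within each zone the climate influence is
quantified two ways: pairwise Pearson correlation of each Δ-factor with
ΔYp, and a bidirectional stepwise multiple linear regression that keeps
only the predictors with significant partial effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ZONE_BOUNDS",
    "RegressionResult",
    "first_difference",
    "classify_zone",
    "build_zone_panels",
    "pearson_matrix",
    "stepwise_mlr",
]

#: Left-closed accumulated-temperature intervals (°C·day) defining the five
#: temperature zones: (<2000), [2000, 2500), [2500, 3000), [3000, 3500), [3500, ∞).
ZONE_BOUNDS = (2000.0, 2500.0, 3000.0, 3500.0)

PREDICTORS = ["dTave", "dTmax", "dTmin", "dEAT", "dTDR", "dRA"]


def first_difference(values, years=None) -> pd.DataFrame:
    """Year-over-year differences Δx_t = x_t − x_{t−1}.

    Returns a frame with columns ``year`` (the later year of each pair) and
    ``diff``.  A gap in the year sequence splits the series: no difference
    is taken across it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to difference")
    t = np.arange(x.size) if years is None else np.asarray(years, dtype=int)
    consec = np.diff(t) == 1
    return pd.DataFrame({"year": t[1:][consec], "diff": np.diff(x)[consec]})


def classify_zone(annual_at0: float) -> str:
    """Map an annual base-0 accumulated temperature (°C·day) to its zone."""
    if not annual_at0 > 0:
        raise ValueError(f"accumulated temperature must be positive, got {annual_at0}")
    for i, bound in enumerate(ZONE_BOUNDS):
        if annual_at0 < bound:
            return f"TZ-{i + 1}"
    return f"TZ-{len(ZONE_BOUNDS) + 1}"


def build_zone_panels(station_years: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pool first-differenced station-years into per-zone panels.

    ``station_years`` carries one row per station-year with columns
    station_id, year, yield_kg_ha, tave, tmax, tmin, eat, tdr, ra_total and
    annual_at0.  Each station is assigned to the zone of its long-term mean
    annual accumulated temperature; its yield and climate series are
    differenced within consecutive-year runs and pooled.
    """
    panels: dict[str, list[pd.DataFrame]] = {}
    cols = {
        "dYp": "yield_kg_ha", "dTave": "tave", "dTmax": "tmax", "dTmin": "tmin",
        "dEAT": "eat", "dTDR": "tdr", "dRA": "ra_total",
    }
    for sid, grp in station_years.groupby("station_id"):
        grp = grp.sort_values("year")
        if len(grp) < 2:
            continue  # nothing to difference
        zone = classify_zone(float(grp["annual_at0"].mean()))
        years = grp["year"].to_numpy(int)
        out = None
        for name, src in cols.items():
            d = first_difference(grp[src].to_numpy(), years).rename(columns={"diff": name})
            out = d if out is None else out.merge(d, on="year")
        out.insert(0, "station_id", sid)
        panels.setdefault(zone, []).append(out)
    return {z: pd.concat(parts, ignore_index=True) for z, parts in sorted(panels.items())}


def pearson_matrix(panel: pd.DataFrame, target: str = "dYp") -> pd.DataFrame:
    """Pearson correlation of each Δ-climate factor with Δ-yield.

    Returns one row per predictor with r, the two-sided t-test p-value and
    a significance class at the 0.1 / 0.05 / 0.01 levels (``*``, ``**``,
    ``***``; ``-`` when not significant).
    """
    if len(panel) < 3:
        raise ValueError("need at least three panel rows")
    rows = []
    y = panel[target].to_numpy(float)
    for p in PREDICTORS:
        if p not in panel.columns:
            continue
        x = panel[p].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, pval = float("nan"), float("nan")
        else:
            r, pval = stats.pearsonr(x, y)
        if np.isnan(pval):
            cls = "undefined"
        elif pval < 0.01:
            cls = "***"
        elif pval < 0.05:
            cls = "**"
        elif pval < 0.1:
            cls = "*"
        else:
            cls = "-"
        rows.append({"predictor": p, "r": r, "p": pval, "class": cls, "n": len(panel)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    """Stepwise regression summary for one zone panel."""

    zone: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    f_statistic: float
    p_value: float
    r2: float
    rmse: float
    n: int

    def equation(self, target: str = "dYp") -> str:
        terms = " ".join(
            f"{'+' if c >= 0 else '-'} {abs(c):.2f}*{p}"
            for p, c in self.coefficients.items()
        ).lstrip("+ ")
        sign = "+" if self.intercept >= 0 else "-"
        return f"{target} = {terms} {sign} {abs(self.intercept):.2f}" if terms else (
            f"{target} = {self.intercept:.2f}"
        )


def stepwise_mlr(
    panel: pd.DataFrame,
    target: str = "dYp",
    predictors: list[str] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    zone: str = "",
) -> RegressionResult:
    """Bidirectional p-value stepwise ordinary least squares.

    Starting from the intercept-only model, repeatedly add the candidate
    whose partial t-test p-value is smallest if it is ≤ ``p_enter``, then
    drop any included predictor whose p-value is ≥ ``p_remove``; iterate to
    a fixed point.  Rank-deficient additions (exact collinearity) are never
    accepted.
    """
    preds = [p for p in (predictors or PREDICTORS) if p in panel.columns]
    if len(panel) < 10:
        raise ValueError("need at least ten panel rows for stepwise regression")
    y = panel[target].to_numpy(float)
    selected: list[str] = []
    sst = float(np.sum((y - y.mean()) ** 2))
    while True:
        changed = False
        # degenerate-fit guard: once the fit is numerically perfect, further
        # candidates would only chase rounding noise
        if selected:
            X = sm.add_constant(panel[selected].to_numpy(float))
            if float(sm.OLS(y, X).fit().ssr) <= 1e-10 * max(sst, 1e-300):
                break
        # forward step
        candidates = {}
        for p in preds:
            if p in selected:
                continue
            X = sm.add_constant(panel[selected + [p]].to_numpy(float))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            fit = sm.OLS(y, X).fit()
            candidates[p] = fit.pvalues[-1]
        if candidates:
            best = min(candidates, key=candidates.get)
            if candidates[best] <= p_enter:
                selected.append(best)
                changed = True
        # backward step
        while len(selected) > 0:
            X = sm.add_constant(panel[selected].to_numpy(float))
            fit = sm.OLS(y, X).fit()
            pv = dict(zip(selected, fit.pvalues[1:]))
            worst = max(pv, key=pv.get)
            if pv[worst] >= p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        X = sm.add_constant(panel[selected].to_numpy(float))
        fit = sm.OLS(y, X).fit()
        coefs = dict(zip(selected, fit.params[1:]))
        intercept = float(fit.params[0])
        f_stat, p_val, r2 = float(fit.fvalue), float(fit.f_pvalue), float(fit.rsquared)
        rmse = float(np.sqrt(np.mean(fit.resid**2)))
    else:
        intercept = float(y.mean())
        coefs, f_stat, p_val, r2 = {}, float("nan"), float("nan"), 0.0
        rmse = float(np.sqrt(np.mean((y - intercept) ** 2)))
    return RegressionResult(
        zone=zone, predictors=tuple(selected), coefficients=coefs,
        intercept=intercept, f_statistic=f_stat, p_value=p_val,
        r2=r2, rmse=rmse, n=len(panel),
    )
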