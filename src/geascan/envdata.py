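"""Environmental time-series summarisation and predictor pruning.

Raw water-quality series (temperature, salinity, pH, turbidity, rainfall)
are restricted to the warm-season sampling window (October-April) and
daylight hours, collapsed to daily averages, and summarised to the
mean/min/max/range statistics used as predictors.  Annual rates of change
come from Gaussian identity-link fits of monthly means on time.  Predictor
sets are pruned by pairwise Pearson correlation and variance inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WARM_MONTHS = (10, 11, 12, 1, 2, 3, 4)
DAYLIGHT_HOURS = (6, 18)  # 06:00 inclusive to 18:00 exclusive, local clock


def _filtered_daily_means(
    series: pd.DataFrame,
    months: tuple[int, ...],
    daylight_only: bool,
    daylight_hours: tuple[int, int],
) -> pd.Series:
    if not {"datetime", "value"}.issubset(series.columns):
        raise ValueError("series needs 'datetime' and 'value' columns")
    ts = series.copy()
    ts["datetime"] = pd.to_datetime(ts["datetime"])
    ts = ts.sort_values("datetime")
    if not np.isfinite(ts["value"]).all():
        raise ValueError("series values must be finite")
    keep = ts["datetime"].dt.month.isin(months)
    if daylight_only:
        hours = ts["datetime"].dt.hour
        keep &= (hours >= daylight_hours[0]) & (hours < daylight_hours[1])
    ts = ts[keep]
    if ts.empty:
        raise ValueError("no measurements left after month/daylight filtering")
    return ts.groupby(ts["datetime"].dt.normalize())["value"].mean()


def summarize_series(
    series: pd.DataFrame,
    months: tuple[int, ...] = WARM_MONTHS,
    daylight_only: bool = True,
    daylight_hours: tuple[int, int] = DAYLIGHT_HOURS,
) -> dict[str, float]:
    """Mean/min/max/range of daily averages within the sampling window."""
    daily = _filtered_daily_means(series, months, daylight_only, daylight_hours)
    return {
        "mean": float(daily.mean()),
        "min": float(daily.min()),
        "max": float(daily.max()),
        "range": float(daily.max() - daily.min()),
    }


def annual_rate(series: pd.DataFrame) -> float:
    """Rate of change per year from monthly means.

    Monthly averages are regressed on time (in years) with an ordinary
    Gaussian identity-link fit; the slope is the per-year rate.  Requires
    at least 3 monthly means spanning more than one year.
    """
    ts = series.copy()
    ts["datetime"] = pd.to_datetime(ts["datetime"])
    monthly = ts.groupby(ts["datetime"].dt.to_period("M"))["value"].mean()
    if len(monthly) < 3:
        raise ValueError("need at least 3 monthly means")
    t = monthly.index.to_timestamp()
    years = (t - t[0]).days / 365.25
    if years.max() <= 1.0:
        raise ValueError("series must span more than one year")
    slope = np.polyfit(years, monthly.to_numpy(), 1)[0]
    return float(slope)


@dataclass
class PruneResult:
    retained: list[str]
    dropped: list[str]
    correlation: pd.DataFrame


def prune_correlated(table: pd.DataFrame, r_threshold: float = 0.7) -> PruneResult:
    """Greedily drop one member of each predictor pair with |r| > threshold.

    Within an offending pair the variable with the larger mean absolute
    correlation to all other variables is dropped (a deterministic rule).
    Constant (zero-variance) columns are excluded up front with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    work = table.copy()
    constant = [c for c in work.columns if work[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping zero-variance variables: {constant}", stacklevel=2)
        work = work.drop(columns=constant)
    corr_full = work.corr()
    dropped = list(constant)
    while True:
        corr = work.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        pair = [corr.index[i], corr.columns[j]]
        mean_abs = corr.mean()
        victim = max(pair, key=lambda v: (mean_abs[v], v))
        work = work.drop(columns=victim)
        dropped.append(victim)
        if work.shape[1] == 1:
            break
    return PruneResult(list(work.columns), dropped, corr_full)


@dataclass
class VifResult:
    vif: pd.Series
    retained: list[str]
    dropped: list[str]


def vif_prune(table: pd.DataFrame, vif_threshold: float = 10.0) -> VifResult:
    """Iteratively drop the largest-VIF variable above the threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing variable j on all other
    variables (with intercept).  A single remaining variable has no
    defined VIF and is returned unchanged.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    import statsmodels.api as sm

    work = table.copy()
    if work.shape[1] < 2:
        return VifResult(pd.Series(dtype=float), list(work.columns), [])
    if work.shape[0] <= work.shape[1]:
        raise ValueError("need more sites than variables for exact VIF")
    dropped: list[str] = []
    while work.shape[1] >= 2:
        X = sm.add_constant(work.to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "singular design; prune correlated predictors first"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vifs = pd.Series(
                [variance_inflation_factor(X, k + 1) for k in range(work.shape[1])],
                index=work.columns,
            )
        if vifs.max() <= vif_threshold:
            break
        work = work.drop(columns=vifs.idxmax())
        dropped.append(vifs.idxmax())
    else:
        vifs = pd.Series(dtype=float)
    return VifResult(vifs, list(work.columns), dropped)
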