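"""Evaluation and exposure-driver statistics.

Covers the statistical surface of the modeling system: flow-weighted monthly
aggregation of concentrations, Pearson correlation with a two-tailed t-test,
sequential variance decomposition of the annual maximum toxic unit onto
late-season insecticide use and rainfall-season precipitation, correlation-
based goodness of fit (with Nash-Sutcliffe efficiency as a secondary
diagnostic), and grid-search calibration of the USLE crop factor against
observed suspended-solid concentrations.

The sequential decomposition is order-dependent by construction: the first
predictor receives its marginal R-squared, the second the increment to the
joint R-squared, so the shares sum to the total exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceDecomposition",
    "flow_weighted_monthly",
    "pearson_r_p",
    "sequential_variance_decomposition",
    "coefficient_of_determination",
    "nash_sutcliffe",
    "calibrate_usle_c",
    "exposure_driver_report",
]


def flow_weighted_monthly(conc: pd.Series, flow: pd.Series) -> pd.Series:
    """Monthly flow-weighted mean concentration, sum(c*q)/sum(q) per month.

    Both series must share a DatetimeIndex; months with zero total flow are
    returned as NaN.
    """
    if not conc.index.equals(flow.index):
        raise ValueError("concentration and flow series must share the same index")
    if (flow < 0).any():
        raise ValueError("flow must be non-negative")
    period = conc.index.to_period("M")
    weighted = (conc * flow).groupby(period).sum()
    total = flow.groupby(period).sum()
    out = weighted / total
    out[total == 0] = np.nan
    return out


def pearson_r_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and two-tailed p from the t-distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("degenerate (zero-variance) input")
    result = sps.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class VarianceDecomposition:
    r2_total: float
    share_x1: float
    share_x2: float


def sequential_variance_decomposition(
    y: Sequence[float], x1: Sequence[float], x2: Sequence[float]
) -> VarianceDecomposition:
    """Sequential OLS variance shares of y on (x1, x2), x1 entered first.

    share_x1 is the R-squared of y ~ x1 alone; share_x2 the increment of the
    joint fit over it; the shares sum to the joint R-squared exactly.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = y.size
    if not (x1.size == x2.size == n):
        raise ValueError("inputs must have equal length")
    if n <= 3:
        raise ValueError("need more than 3 observations")
    design = sm.add_constant(np.column_stack([x1, x2]))
    if np.linalg.cond(design) > 1e10:
        raise ValueError("predictors are collinear (ill-conditioned design)")
    joint = sm.OLS(y, design).fit()
    first = sm.OLS(y, sm.add_constant(x1)).fit()
    r2_total = float(joint.rsquared)
    share_x1 = float(first.rsquared)
    return VarianceDecomposition(
        r2_total=r2_total, share_x1=share_x1, share_x2=r2_total - share_x1)


def coefficient_of_determination(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted values.

    Note this convention rewards any linear association (pred = -obs scores
    1); report alongside :func:`nash_sutcliffe` when bias matters.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("need >= 2 paired values of equal length")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def nash_sutcliffe(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Nash-Sutcliffe model efficiency, 1 - SS_res/SS_tot (1 is perfect)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def calibrate_usle_c(
    observed_monthly_ssc: pd.Series,
    simulate: Callable[[float], pd.Series],
    grid: Iterable[float],
) -> tuple[float, pd.DataFrame]:
    """Grid-search the USLE crop factor minimizing monthly SSC squared error.

    ``simulate`` maps a candidate usle_c to the predicted monthly
    flow-weighted SSC series (aligned with the observations). Candidates that
    raise are logged and skipped; ties (a flat objective) resolve to the
    smallest candidate with a warning. Returns (best_c, results table).
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("empty calibration grid")
    rows = []
    for candidate in grid:
        try:
            pred = simulate(candidate)
        except Exception as exc:
            logger.warning("calibration candidate %g failed: %s", candidate, exc)
            continue
        aligned = pd.concat(
            {"obs": observed_monthly_ssc, "pred": pred}, axis=1).dropna()
        sse = float(((aligned["obs"] - aligned["pred"]) ** 2).sum())
        rows.append({"usle_c": candidate, "sse": sse})
    if not rows:
        raise RuntimeError("all calibration candidates failed")
    table = pd.DataFrame(rows)
    best = table.loc[table["sse"].idxmin()]
    n_best = int((table["sse"] == best["sse"]).sum())
    if n_best > 1:
        logger.warning(
            "flat calibration objective: %d candidates tie at SSE=%g; "
            "returning the smallest", n_best, best["sse"])
        return float(table.loc[table["sse"] == best["sse"], "usle_c"].min()), table
    return float(best["usle_c"]), table


def exposure_driver_report(
    exposure: pd.DataFrame,
    use_column: str = "bifenthrin_sep_oct_kg",
    precip_column: str = "precip_nov_dec_cm",
    tu_column: str = "max_tu",
) -> dict:
    """Driver statistics for the annual maximum TU.

    Restricts to years with nonzero late-season (Sep-Oct) bifenthrin use,
    correlates prior use with the annual maximum TU, and sequentially
    decomposes TU variance onto use (first) and rainfall-season
    precipitation (second). Returns a plain dict of the statistics.
    """
    subset = exposure[exposure[use_column] > 0]
    r, p = pearson_r_p(subset[use_column], subset[tu_column])
    decomp = sequential_variance_decomposition(
        subset[tu_column], subset[use_column], subset[precip_column])
    return {
        "n_years": int(len(subset)),
        "pearson_r": r,
        "pearson_p": p,
        "r2_total": decomp.r2_total,
        "share_use": decomp.share_x1,
        "share_precip": decomp.share_x2,
    }
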