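"""Organic-carbon normalized toxic units and the toxicity-mortality curve.

Sediment pesticide concentrations are converted to toxic units (TU) for the
amphipod *Hyalella azteca* under the additivity assumption: each compound's
concentration is normalized by its 10-day sediment LC50 on an organic-carbon
basis and the ratios are summed. Concentrations below a study's method
detection limit are censored to zero before normalization. TU is related to
observed cumulative mortality through a two-parameter logistic curve on
log10(TU) with fixed 0/100% asymptotes.

LC50 convention: the tabulated LC50 values are dry-weight concentrations in
sediment containing 1% organic carbon. The default ``lc50_basis``
("dw_at_1pct_oc") rescales a sample's dry-weight concentration to that 1%-OC
reference (conc * 0.01 / f_oc) before dividing by the tabulated LC50; the
alternative ("per_g_oc") treats the tabulated values as directly per gram of
organic carbon. Both are exposed because the two conventions appear in the
sediment-toxicity literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import curve_fit

from .chemistry import PesticideProperties

__all__ = [
    "SedimentSample",
    "ToxicityResult",
    "apply_mdl_censoring",
    "toxic_unit",
    "plotting_floor",
    "logistic_mortality_fit",
    "logistic_mortality",
]

PLOTTING_FLOOR_TU = 0.01


@dataclass(frozen=True)
class SedimentSample:
    """One sediment sample: dry-weight concentrations (ng/g) per compound."""

    site: str
    date: str
    conc_ng_g: Mapping[str, float]
    f_oc: float
    mdl_ng_g: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.f_oc <= 1.0):
            raise ValueError(f"f_oc must lie in (0, 1], got {self.f_oc}")
        if any(v < 0 for v in self.conc_ng_g.values()):
            raise ValueError("concentrations must be non-negative")
        if any(v < 0 for v in self.mdl_ng_g.values()):
            raise ValueError("MDLs must be non-negative")


@dataclass(frozen=True)
class ToxicityResult:
    tu: float
    per_compound_share: Mapping[str, float]
    censored: bool


def apply_mdl_censoring(sample: SedimentSample) -> SedimentSample:
    """Report concentrations below the method detection limit as zero.

    A concentration exactly at the MDL is a detection and is kept.
    """
    censored = {
        compound: (0.0 if conc < sample.mdl_ng_g.get(compound, 0.0) else conc)
        for compound, conc in sample.conc_ng_g.items()
    }
    return replace(sample, conc_ng_g=censored)


def toxic_unit(
    sample: SedimentSample,
    properties: Mapping[str, PesticideProperties],
    lc50_basis: Literal["dw_at_1pct_oc", "per_g_oc"] = "dw_at_1pct_oc",
) -> ToxicityResult:
    """Sum of per-compound concentration/LC50 ratios on the OC-normalized scale.

    Raises if a compound with nonzero concentration lacks an LC50.
    """
    contributions: dict[str, float] = {}
    for compound, conc in sample.conc_ng_g.items():
        if conc == 0.0:
            contributions[compound] = 0.0
            continue
        if compound not in properties:
            raise KeyError(f"no LC50 available for detected compound {compound!r}")
        lc50 = properties[compound].lc50_oc
        if lc50_basis == "dw_at_1pct_oc":
            contributions[compound] = conc * 0.01 / sample.f_oc / lc50
        elif lc50_basis == "per_g_oc":
            contributions[compound] = conc / sample.f_oc / lc50
        else:
            raise ValueError(f"unknown lc50_basis {lc50_basis!r}")
    tu = float(sum(contributions.values()))
    shares = ({c: v / tu for c, v in contributions.items()} if tu > 0
              else {c: 0.0 for c in contributions})
    return ToxicityResult(tu=tu, per_compound_share=shares, censored=(tu == 0.0))


def plotting_floor(tu: float, floor: float = PLOTTING_FLOOR_TU) -> float:
    """Display value for a TU: exact non-detects (TU = 0) plot at the floor."""
    if tu < 0:
        raise ValueError("tu must be non-negative")
    return floor if tu == 0.0 else tu


def logistic_mortality(tu, a: float, b: float):
    """Mortality (%) as a logistic function of log10(TU)."""
    return 100.0 / (1.0 + np.exp(-(a + b * np.log10(tu))))


def logistic_mortality_fit(
    tu_values,
    mortality_percent,
    p0: tuple[float, float] = (0.0, 1.0),
) -> tuple[tuple[float, float], float]:
    """Least-squares fit of M(TU) = 100/(1+exp(-(a + b*log10 TU))), b >= 0.

    Returns ((a, b), r_squared) with R^2 = 1 - SS_res/SS_tot of fitted versus
    observed mortality (0 when the observations have no variance).
    """
    tu = np.asarray(tu_values, dtype=float)
    y = np.asarray(mortality_percent, dtype=float)
    if tu.size != y.size:
        raise ValueError("tu_values and mortality_percent lengths differ")
    if tu.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.any(tu <= 0):
        raise ValueError("tu values must be positive (apply the plotting floor first)")
    try:
        params, _ = curve_fit(
            logistic_mortality, tu, y, p0=p0,
            bounds=([-np.inf, 0.0], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"logistic fit did not converge (n={tu.size}, "
            f"tu range [{tu.min():.3g}, {tu.max():.3g}]): {exc}") from exc
    fitted = logistic_mortality(tu, *params)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (float(params[0]), float(params[1])), r2
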