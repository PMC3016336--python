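"""Chemical property bookkeeping, sorption partitioning, and first-order decay.

All compartment models in the package (soil column, water column, bed
sediment) share the same three primitives defined here:

* a linear sorption isotherm, ``Kd = Koc * f_oc`` (L/kg), linking the
  organic-carbon normalized partition coefficient to the bulk soil or
  sediment partition coefficient;
* closed-form dissolved fractions for the water column (``F_wd``) and for
  the bed-sediment pore system (``F_dd``);
* first-order decay parameterized by compartment-specific half-lives.

Unit conventions: Kd is carried in L/kg as tabulated; suspended-solid
concentration in kg/m^3; particle density in g/m^3. Conversions to a common
basis happen once inside each function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "PesticideProperties",
    "PhaseFractions",
    "kd_from_koc",
    "fraction_dissolved_water",
    "fraction_dissolved_sediment",
    "first_order_decay",
    "decay_factor",
    "load_properties",
    "DEFAULT_PARTICLE_DENSITY_G_M3",
]

#: Standard mineral particle density (quartz), g/m^3.
DEFAULT_PARTICLE_DENSITY_G_M3 = 2.65e6

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PesticideProperties:
    """Physicochemical and toxicological constants for one active ingredient.

    LC50 is the 10-day median lethal concentration for *Hyalella azteca* in
    sediment containing 1% organic carbon (ng/g dry weight on that basis).
    ``mdl_ng_g`` maps a study/survey key to its method detection limit.
    """

    name: str
    molecular_weight: float  # g/mol
    kow: float  # dimensionless
    vapor_pressure: float  # Pa
    henry_constant: float  # Pa*m^3/mol
    koc: float  # L/kg-OC
    half_life_soil: float  # day
    half_life_water: float  # day
    half_life_sediment: float  # day
    lc50_oc: float  # ng/g dw, 10-day, sediment at 1% OC
    mdl_ng_g: Mapping[str, float]

    def __post_init__(self) -> None:
        for field_name in (
            "molecular_weight", "kow", "vapor_pressure", "henry_constant",
            "koc", "half_life_soil", "half_life_water", "half_life_sediment",
            "lc50_oc",
        ):
            value = getattr(self, field_name)
            if not value > 0:
                raise ValueError(f"{self.name}: {field_name} must be positive, got {value!r}")
        if any(v < 0 for v in self.mdl_ng_g.values()):
            raise ValueError(f"{self.name}: MDLs must be non-negative")

    def kd(self, f_oc: float) -> float:
        """Bulk partition coefficient (L/kg) at organic-carbon fraction ``f_oc``."""
        return kd_from_koc(self.koc, f_oc)


@dataclass(frozen=True)
class PhaseFractions:
    """Dissolved/adsorbed split of total pesticide in one compartment."""

    f_dissolved: float
    f_adsorbed: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_dissolved <= 1.0):
            raise ValueError(f"f_dissolved out of [0,1]: {self.f_dissolved}")
        if abs(self.f_dissolved + self.f_adsorbed - 1.0) > 2**-50:
            raise ValueError("phase fractions must sum to 1")

    @classmethod
    def from_dissolved(cls, f_dissolved: float) -> "PhaseFractions":
        return cls(f_dissolved=f_dissolved, f_adsorbed=1.0 - f_dissolved)


def kd_from_koc(koc: float, f_oc: float) -> float:
    """Linear-isotherm partition coefficient Kd = Koc * f_oc (L/kg)."""
    if koc < 0:
        raise ValueError(f"koc must be non-negative, got {koc}")
    if not (0.0 <= f_oc <= 1.0):
        raise ValueError(f"f_oc must lie in [0,1], got {f_oc}")
    return koc * f_oc


def fraction_dissolved_water(kd: float, c_ss: float) -> PhaseFractions:
    """Dissolved fraction F_wd of water-column pesticide at suspended-solid
    concentration ``c_ss`` (kg/m^3) and partition coefficient ``kd`` (L/kg).

    F_wd = 1 / (1 + Kd * C_ss * 1e-3), the 1e-3 converting L/kg * kg/m^3 to a
    dimensionless sorbed/dissolved mass ratio.
    """
    if kd < 0 or c_ss < 0:
        raise ValueError("kd and c_ss must be non-negative")
    f_wd = 1.0 / (1.0 + kd * c_ss * 1e-3)
    return PhaseFractions.from_dissolved(f_wd)


def fraction_dissolved_sediment(
    kd: float,
    porosity: float,
    rho_s: float = DEFAULT_PARTICLE_DENSITY_G_M3,
) -> PhaseFractions:
    """Dissolved (pore-water) fraction F_dd of total bed-sediment pesticide.

    F_dd = phi / (phi + (1 - phi) * rho_s' * Kd) with particle density
    ``rho_s`` supplied in g/m^3 and converted to kg/L (1 g/m^3 = 1e-6 kg/L).
    """
    if not (0.0 < porosity < 1.0):
        raise ValueError(f"porosity must lie in (0,1), got {porosity}")
    if kd < 0 or rho_s <= 0:
        raise ValueError("kd must be >= 0 and rho_s > 0")
    rho_kg_per_l = rho_s * 1e-6
    f_dd = porosity / (porosity + (1.0 - porosity) * rho_kg_per_l * kd)
    return PhaseFractions.from_dissolved(f_dd)


def decay_factor(half_life: float, dt: float) -> float:
    """Surviving mass fraction after ``dt`` days at the given half-life."""
    if half_life <= 0:
        raise ValueError(f"half_life must be positive, got {half_life}")
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    return math.exp(-LN2 * dt / half_life)


def first_order_decay(mass: float, half_life: float, dt: float) -> float:
    """Mass remaining after first-order decay over ``dt`` days."""
    return mass * decay_factor(half_life, dt)


_REQUIRED_COLUMNS = [
    "compound", "molecular_weight_g_mol", "kow", "vapor_pressure_pa",
    "henry_constant_pa_m3_mol", "koc_l_kg", "half_life_soil_d",
    "half_life_water_d", "half_life_sediment_d", "lc50_10d_ng_g",
]


def load_properties(path=None) -> dict[str, PesticideProperties]:
    """Load pesticide properties from a delimited table.

    Without arguments, returns the packaged property table for the four
    simulated pyrethroids (bifenthrin, lambda-cyhalothrin, esfenvalerate,
    permethrin). Columns beginning ``mdl_`` are collected into the per-study
    MDL mapping; all other required columns must be present and complete.
    """
    if path is None:
        with resources.files("pyresed.data").joinpath("table2_chemicals.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing columns: {missing}")
    if df[_REQUIRED_COLUMNS].isna().any().any():
        raise ValueError("property table has missing values")
    mdl_cols = [c for c in df.columns if c.startswith("mdl_")]
    out: dict[str, PesticideProperties] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict()
        out[rec["compound"]] = PesticideProperties(
            name=rec["compound"],
            molecular_weight=rec["molecular_weight_g_mol"],
            kow=rec["kow"],
            vapor_pressure=rec["vapor_pressure_pa"],
            henry_constant=rec["henry_constant_pa_m3_mol"],
            koc=rec["koc_l_kg"],
            half_life_soil=rec["half_life_soil_d"],
            half_life_water=rec["half_life_water_d"],
            half_life_sediment=rec["half_life_sediment_d"],
            lc50_oc=rec["lc50_10d_ng_g"],
            mdl_ng_g={c[len("mdl_"):-len("_ng_g")] if c.endswith("_ng_g") else c[4:]: rec[c]
                      for c in mdl_cols},
        )
    return out
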