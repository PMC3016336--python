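"""Synthetic watershed scenarios and packaged reference fixtures.

The generator emulates a Mediterranean-climate agricultural watershed of the
kind the model targets: winter-dominant precipitation (the bulk of annual
rainfall between November and March), irrigation-season pyrethroid use with
about half the annual mass applied in July-August and 70% in June-September,
an optional late-season (Sep-Oct) share emulating the post-2000 shift in
bifenthrin timing, and a tree-structured channel network draining to a single
outlet. All generators are pure functions of their seed and parameters.

``load_fixture`` returns the packaged reference tables: per-compound
chemical/toxicity properties ("table2") and the year-by-year exposure table
of annual maximum TU, precipitation, and bifenthrin use ("table3").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .channel_model import ReachParameters
from .chemistry import PesticideProperties, load_properties
from .field_model import ErosionConfig, FieldConfig
from .routing import FlowPath

__all__ = [
    "WatershedScenario",
    "ReachSpec",
    "generate_weather",
    "generate_applications",
    "generate_watershed",
    "load_fixture",
    "BASE_MONTHLY_USE_WEIGHTS",
]

#: Climatological monthly application-mass weights (Jan..Dec): 50% of annual
#: use in July-August, 70% June-September.
BASE_MONTHLY_USE_WEIGHTS = np.array(
    [0.02, 0.02, 0.03, 0.05, 0.08, 0.10, 0.25, 0.25, 0.10, 0.05, 0.03, 0.02])

#: Wet-day probability and mean wet-day depth (cm) by month, winter-dominant.
_WET_PROB = np.array([0.30, 0.28, 0.25, 0.15, 0.10, 0.02, 0.02, 0.02, 0.03, 0.12, 0.32, 0.33])
_WET_MEAN_CM = np.array([0.8, 0.8, 0.7, 0.4, 0.3, 0.2, 0.2, 0.2, 0.2, 0.4, 0.9, 0.9])

#: Default annual application mass (kg) per compound across the watershed.
DEFAULT_ANNUAL_USE_KG = {
    "bifenthrin": 30.0,
    "lambda-cyhalothrin": 60.0,
    "esfenvalerate": 40.0,
    "permethrin": 80.0,
}


def load_fixture(name: str) -> pd.DataFrame:
    """Return a packaged reference table ("table2" or "table3")."""
    files = {
        "table2": "table2_chemicals.csv",
        "table3": "table3_exposure.csv",
    }
    if name not in files:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(files)}")
    with resources.files("pyresed.data").joinpath(files[name]).open() as fh:
        return pd.read_csv(fh)


def generate_weather(
    seed: int,
    n_years: int,
    annual_precip_cm_range: tuple[float, float] = (6.4, 47.4),
    start_year: int = 1990,
) -> pd.DataFrame:
    """Daily weather with winter-dominant rainfall; reproducible per seed.

    Wet days follow monthly occurrence probabilities; wet-day depths are
    gamma-distributed; each calendar year is rescaled to an annual total
    drawn uniformly from ``annual_precip_cm_range``. Temperature is a
    sinusoidal annual cycle with daily noise.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    lo, hi = annual_precip_cm_range
    if not (0 <= lo <= hi):
        raise ValueError("invalid annual precipitation range")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    months = dates.month.to_numpy() - 1
    doy = dates.dayofyear.to_numpy()

    wet = rng.random(dates.size) < _WET_PROB[months]
    depth = rng.gamma(shape=0.8, scale=_WET_MEAN_CM[months] / 0.8) * wet
    years = dates.year.to_numpy()
    precip = depth.copy()
    for year in np.unique(years):
        mask = years == year
        total = precip[mask].sum()
        target = rng.uniform(lo, hi)
        if total > 0:
            precip[mask] *= target / total
    tmean = 16.0 + 9.0 * np.sin(2 * np.pi * (doy - 105) / 365.25)
    tmin = tmean - 6.0 + rng.normal(0, 1.5, dates.size)
    tmax = tmean + 6.0 + rng.normal(0, 1.5, dates.size)
    return pd.DataFrame({
        "date": dates.date, "precip_cm": precip,
        "tmin_c": tmin, "tmax_c": tmax,
    })


def monthly_use_weights(sep_oct_fraction: float | None = None) -> np.ndarray:
    """Monthly application weights, optionally forcing the Sep+Oct share.

    When ``sep_oct_fraction`` is given, September and October jointly receive
    that share (keeping their 2:1 ratio) and the other months are rescaled to
    the remainder, preserving their relative pattern.
    """
    w = BASE_MONTHLY_USE_WEIGHTS.copy()
    if sep_oct_fraction is None:
        return w
    if not (0.0 <= sep_oct_fraction < 1.0):
        raise ValueError("sep_oct_fraction must lie in [0, 1)")
    others = np.ones(12, dtype=bool)
    others[8] = others[9] = False
    w[8] = sep_oct_fraction * (w[8] / (w[8] + w[9]))
    w[9] = sep_oct_fraction * (BASE_MONTHLY_USE_WEIGHTS[9]
                               / (BASE_MONTHLY_USE_WEIGHTS[8] + BASE_MONTHLY_USE_WEIGHTS[9]))
    w[others] = BASE_MONTHLY_USE_WEIGHTS[others] * (
        (1.0 - sep_oct_fraction) / BASE_MONTHLY_USE_WEIGHTS[others].sum())
    return w


def generate_applications(
    seed: int,
    field_ids: Sequence[str],
    compounds: Sequence[str],
    annual_kg: Mapping[str, float] | float,
    n_years: int = 1,
    start_year: int = 1990,
    sep_oct_fraction: float | None = None,
    events_per_year: int = 20,
) -> pd.DataFrame:
    """Application records (date, field_id, compound, mass_kg).

    Each compound-year's mass is split equally over ``events_per_year``
    events whose months follow the configured monthly weights (multinomial),
    with uniform days within the month and uniform field assignment, so
    long-run aggregate monthly shares converge to the weights.
    """
    if isinstance(annual_kg, (int, float)):
        annual_kg = {c: float(annual_kg) for c in compounds}
    if any(annual_kg.get(c, 0.0) < 0 for c in compounds):
        raise ValueError("annual_kg must be non-negative")
    rng = np.random.default_rng(seed)
    weights = monthly_use_weights(sep_oct_fraction)
    days_in_month = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    records = []
    for year in range(start_year, start_year + n_years):
        for compound in compounds:
            total = annual_kg.get(compound, 0.0)
            if total <= 0:
                continue
            counts = rng.multinomial(events_per_year, weights)
            mass = total / events_per_year
            for month_idx, count in enumerate(counts):
                for _ in range(count):
                    day = rng.integers(1, days_in_month[month_idx] + 1)
                    records.append({
                        "date": pd.Timestamp(year, month_idx + 1, int(day)).date(),
                        "field_id": field_ids[rng.integers(len(field_ids))],
                        "compound": compound,
                        "mass_kg": mass,
                    })
    df = pd.DataFrame(records, columns=["date", "field_id", "compound", "mass_kg"])
    return df.sort_values("date", kind="stable").reset_index(drop=True)


@dataclass
class ReachSpec:
    """One reach of the tree-structured network.

    ``downstream`` is the reach_id this reach drains into (None at the
    outlet). The lateral ``path`` routes the reach's zone inputs (field
    runoff and eroded solids) to the reach head; ``baseflow_m3_d`` is a
    clean-water boundary inflow.
    """

    reach_id: str
    downstream: str | None
    params: ReachParameters
    path: FlowPath
    water_volume_m3: float = 8000.0
    baseflow_m3_d: float = 500.0


@dataclass
class WatershedScenario:
    """A complete, runnable synthetic watershed."""

    seed: int
    fields: list[FieldConfig]
    reaches: list[ReachSpec]
    weather: pd.DataFrame
    applications: pd.DataFrame
    chemicals: dict[str, PesticideProperties] = field(default_factory=load_properties)
    soil_depth_cm: float = 10.0
    compartment_thickness_cm: float = 0.5
    bulk_density_g_cm3: float = 1.5
    soil_f_oc: float = 0.01
    theta: float = 0.3

    def validate(self) -> None:
        zone_ids = {r.reach_id for r in self.reaches}
        for f in self.fields:
            if f.zone_id not in zone_ids:
                raise ValueError(f"field {f.field_id} maps to unknown zone {f.zone_id}")
        downstream_ids = {r.downstream for r in self.reaches if r.downstream is not None}
        if not downstream_ids <= zone_ids:
            raise ValueError(f"unknown downstream reaches: {downstream_ids - zone_ids}")
        outlets = [r for r in self.reaches if r.downstream is None]
        if len(outlets) != 1:
            raise ValueError(f"expected exactly one outlet reach, found {len(outlets)}")
        # acyclicity: walking downstream must terminate
        by_id = {r.reach_id: r for r in self.reaches}
        for r in self.reaches:
            seen = set()
            node = r
            while node.downstream is not None:
                if node.reach_id in seen:
                    raise ValueError("cycle in reach network")
                seen.add(node.reach_id)
                node = by_id[node.downstream]
        dates = set(self.weather["date"])
        bad = [d for d in self.applications["date"] if d not in dates]
        if bad:
            raise ValueError(f"{len(bad)} application dates outside weather coverage")

    @property
    def outlet_id(self) -> str:
        return next(r.reach_id for r in self.reaches if r.downstream is None)

    def save(self, directory) -> None:
        """Serialize to a directory: config.yaml + weather.csv + applications.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        config = {
            "seed": self.seed,
            "soil": {
                "depth_cm": self.soil_depth_cm,
                "compartment_thickness_cm": self.compartment_thickness_cm,
                "bulk_density_g_cm3": self.bulk_density_g_cm3,
                "f_oc": self.soil_f_oc,
                "theta": self.theta,
            },
            "fields": [
                {**{k: v for k, v in vars(f).items() if k != "erosion"},
                 "irrigation_months": list(f.irrigation_months),
                 "erosion": vars(f.erosion)}
                for f in self.fields
            ],
            "reaches": [
                {
                    "reach_id": r.reach_id,
                    "downstream": r.downstream,
                    "water_volume_m3": r.water_volume_m3,
                    "baseflow_m3_d": r.baseflow_m3_d,
                    "params": vars(r.params),
                    "path": vars(r.path),
                }
                for r in self.reaches
            ],
        }
        (directory / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
        self.weather.to_csv(directory / "weather.csv", index=False)
        self.applications.to_csv(directory / "applications.csv", index=False)

    @classmethod
    def load(cls, directory) -> "WatershedScenario":
        directory = Path(directory)
        config = yaml.safe_load((directory / "config.yaml").read_text())
        weather = pd.read_csv(directory / "weather.csv", parse_dates=["date"])
        weather["date"] = weather["date"].dt.date
        applications = pd.read_csv(directory / "applications.csv", parse_dates=["date"])
        applications["date"] = applications["date"].dt.date
        fields = []
        for raw in config["fields"]:
            erosion = ErosionConfig(**raw.pop("erosion"))
            raw["irrigation_months"] = tuple(raw["irrigation_months"])
            fields.append(FieldConfig(erosion=erosion, **raw))
        reaches = [
            ReachSpec(
                reach_id=raw["reach_id"],
                downstream=raw["downstream"],
                water_volume_m3=raw["water_volume_m3"],
                baseflow_m3_d=raw["baseflow_m3_d"],
                params=ReachParameters(**raw["params"]),
                path=FlowPath(**raw["path"]),
            )
            for raw in config["reaches"]
        ]
        soil = config["soil"]
        scenario = cls(
            seed=config["seed"], fields=fields, reaches=reaches,
            weather=weather, applications=applications,
            soil_depth_cm=soil["depth_cm"],
            compartment_thickness_cm=soil["compartment_thickness_cm"],
            bulk_density_g_cm3=soil["bulk_density_g_cm3"],
            soil_f_oc=soil["f_oc"], theta=soil["theta"],
        )
        scenario.validate()
        return scenario


def generate_watershed(
    seed: int,
    n_fields: int = 20,
    n_reaches: int = 5,
    n_years: int = 19,
    start_year: int = 1990,
    compounds: Sequence[str] | None = None,
    annual_kg: Mapping[str, float] | None = None,
    sep_oct_fraction: float | None = 0.1,
    usle_c: float = 0.2,
) -> WatershedScenario:
    """Generate a complete synthetic watershed scenario.

    The channel network is a random tree with one outlet; fields draw soil
    and USLE parameters from plausible agricultural ranges and are assigned
    uniformly to reach drainage zones. Defaults size the scenario so a full
    multi-decade daily run stays fast (about 20 fields, 5 reaches).
    """
    if n_fields < 1 or n_reaches < 1:
        raise ValueError("need at least one field and one reach")
    rng = np.random.default_rng(seed)
    chemicals = load_properties()
    if compounds is None:
        compounds = list(chemicals)
    if annual_kg is None:
        annual_kg = {c: DEFAULT_ANNUAL_USE_KG.get(c, 30.0) for c in compounds}

    reach_ids = [f"reach-{i}" for i in range(n_reaches)]
    reaches = []
    for i, reach_id in enumerate(reach_ids):
        downstream = None if i == 0 else reach_ids[int(rng.integers(0, i))]
        params = ReachParameters(
            spcon=1.0e-4,
            spexp=1.5,
            erodibility=float(rng.uniform(0.3, 0.7)),
            cover=float(rng.uniform(0.3, 0.7)),
            active_layer_depth_m=0.05,
            porosity=0.5,
            bed_foc=0.01,
            water_foc_of_ss=0.01,
            surface_area_m2=float(rng.uniform(3000, 8000)),
            cross_section_m2=float(rng.uniform(2.0, 6.0)),
        )
        path = FlowPath(
            zone_id=reach_id,
            lag_time_s=float(rng.uniform(0.5, 2.0) * 86400),
            shear_storage=float(rng.uniform(0.05, 0.3)),
            loss_factor=float(rng.uniform(0.9, 1.0)),
        )
        reaches.append(ReachSpec(
            reach_id=reach_id, downstream=downstream, params=params, path=path,
            water_volume_m3=float(rng.uniform(5000, 12000)),
            baseflow_m3_d=float(rng.uniform(200, 1000)),
        ))

    field_ids = [f"field-{i}" for i in range(n_fields)]
    fields = [
        FieldConfig(
            field_id=fid,
            area_ha=float(rng.uniform(10, 40)),
            zone_id=reach_ids[int(rng.integers(n_reaches))],
            curve_number=float(rng.uniform(80, 90)),
            usle_k=float(rng.uniform(0.2, 0.4)),
            usle_c=usle_c,
            usle_ls=float(rng.uniform(0.5, 2.0)),
            erosion=ErosionConfig(),
        )
        for fid in field_ids
    ]

    weather = generate_weather(int(rng.integers(2**31)), n_years, start_year=start_year)
    applications = generate_applications(
        int(rng.integers(2**31)), field_ids, list(compounds), annual_kg,
        n_years=n_years, start_year=start_year, sep_oct_fraction=sep_oct_fraction)
    scenario = WatershedScenario(
        seed=seed, fields=fields, reaches=reaches,
        weather=weather, applications=applications,
        chemicals={c: chemicals[c] for c in compounds},
    )
    scenario.validate()
    return scenario
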