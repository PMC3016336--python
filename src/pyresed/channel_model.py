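"""Reach-scale daily mass balance for solids and pesticide in two compartments.

Each reach is a completely mixed water column above a well-mixed active bed
sediment layer. A day proceeds as: inflow mixing -> transport capacity ->
deposition/resuspension of solids and adsorbed pesticide -> dissolved/adsorbed
partitioning -> water/bed diffusive exchange -> first-order decay (water and
bed) -> outflow.

Sediment transport uses a capacity concept: the maximum concentration a reach
can carry is a power function of peak velocity, ``C_ss,max = SPCON * V**SPEXP``.
Suspended load above capacity deposits; below capacity, bed sediment
resuspends, throttled by channel erodibility and cover factors and limited by
the capacity deficit and the available bed mass.

Water/bed diffusion uses the Mackay two-film fugacity formulation: fugacity
capacity Z = 1/H for the aqueous phases, boundary-layer conductances in
series, flux from high to low fugacity. The sediment-side boundary layer
thickness follows the empirical power law 318*Kd^0.683 (isolated in
:func:`sediment_boundary_layer_m` for easy revision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .chemistry import (
    LN2,
    DEFAULT_PARTICLE_DENSITY_G_M3,
    PesticideProperties,
    fraction_dissolved_sediment,
    fraction_dissolved_water,
)

__all__ = [
    "ReachParameters",
    "ReachState",
    "transport_capacity",
    "deposition_resuspension",
    "pesticide_sedimentation_resuspension",
    "sediment_boundary_layer_m",
    "diffusion_flux",
    "equilibrium_water_mass",
    "relax_diffusion",
    "bed_decay_burial",
    "reach_daily_step",
]

#: Molecular diffusivity in free water, m^2/day; the effective sediment-side
#: diffusivity is reduced by a Millington-Quirk porosity factor.
WATER_DIFFUSIVITY_M2_DAY = 4.3e-5


@dataclass
class ReachParameters:
    """Static parameters of one reach segment."""

    spcon: float = 1.0e-4
    spexp: float = 1.5
    erodibility: float = 0.5
    cover: float = 0.5
    active_layer_depth_m: float = 0.05
    porosity: float = 0.5
    particle_density_g_m3: float = DEFAULT_PARTICLE_DENSITY_G_M3
    bed_foc: float = 0.01
    water_foc_of_ss: float = 0.01
    boundary_layer_water_m: float = 0.02
    boundary_layer_sediment_m: float | None = None  # None -> 318*Kd^0.683
    burial_rate_per_day: float = 0.0
    surface_area_m2: float = 5000.0
    cross_section_m2: float = 4.0
    velocity_peakedness: float = 2.0

    def __post_init__(self) -> None:
        if self.spcon <= 0:
            raise ValueError("spcon must be positive")
        if not (1.0 <= self.spexp <= 2.0):
            import warnings
            warnings.warn(f"spexp={self.spexp} outside the usual [1, 2] range")
        if not (0.0 < self.porosity < 1.0):
            raise ValueError("porosity must lie in (0, 1)")
        for name in ("erodibility", "cover"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ReachState:
    """Mutable state of one reach; pesticide arrays are per compound (g)."""

    water_volume_m3: float
    compounds: list[str]
    peak_velocity_m_s: float = 0.0
    c_ss_kg_m3: float = 0.0
    bed_sediment_mass_kg: float = 0.0
    pesticide_water_g: np.ndarray = dc_field(default=None)  # type: ignore[assignment]
    pesticide_bed_g: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = len(self.compounds)
        if self.pesticide_water_g is None:
            self.pesticide_water_g = np.zeros(k)
        if self.pesticide_bed_g is None:
            self.pesticide_bed_g = np.zeros(k)
        if self.water_volume_m3 <= 0:
            raise ValueError("water_volume_m3 must be positive")
        for name in ("c_ss_kg_m3", "bed_sediment_mass_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def suspended_mass_kg(self) -> float:
        return self.c_ss_kg_m3 * self.water_volume_m3

    def copy(self) -> "ReachState":
        return ReachState(
            water_volume_m3=self.water_volume_m3,
            compounds=list(self.compounds),
            peak_velocity_m_s=self.peak_velocity_m_s,
            c_ss_kg_m3=self.c_ss_kg_m3,
            bed_sediment_mass_kg=self.bed_sediment_mass_kg,
            pesticide_water_g=self.pesticide_water_g.copy(),
            pesticide_bed_g=self.pesticide_bed_g.copy(),
        )


def transport_capacity(v_m_s: float, params: ReachParameters) -> float:
    """Maximum transportable suspended-solid concentration (kg/m^3)."""
    if v_m_s < 0:
        raise ValueError("velocity must be non-negative")
    if v_m_s == 0.0:
        return 0.0
    return params.spcon * v_m_s ** params.spexp


def deposition_resuspension(
    state: ReachState, params: ReachParameters
) -> tuple[float, float]:
    """Adjust suspended solids toward transport capacity; mutates state.

    Returns (deposition_kg, resuspension_kg). Excess over capacity deposits;
    deficit resuspends bed sediment scaled by erodibility*cover and limited
    by both the capacity deficit and the available bed mass.
    """
    capacity = transport_capacity(state.peak_velocity_m_s, params)
    volume = state.water_volume_m3
    deposition = 0.0
    resuspension = 0.0
    if state.c_ss_kg_m3 > capacity:
        deposition = (state.c_ss_kg_m3 - capacity) * volume
        state.c_ss_kg_m3 = capacity
        state.bed_sediment_mass_kg += deposition
    elif state.c_ss_kg_m3 < capacity:
        deficit = (capacity - state.c_ss_kg_m3) * volume
        resuspension = min(deficit * params.erodibility * params.cover,
                           state.bed_sediment_mass_kg)
        state.bed_sediment_mass_kg -= resuspension
        state.c_ss_kg_m3 += resuspension / volume
    return deposition, resuspension


def pesticide_sedimentation_resuspension(
    state: ReachState,
    deposition_kg: float,
    resuspension_kg: float,
    adsorbed_water_g: np.ndarray,
    suspended_mass_before_kg: float,
    bed_mass_before_kg: float,
    bed_pesticide_before_g: np.ndarray,
) -> np.ndarray:
    """Move pesticide with the solid fluxes; mutates state.

    Sedimentation flux = solid deposition x (adsorbed water-column pesticide /
    suspended solids); resuspension flux = solid resuspension x (bed pesticide
    / bed sediment). Ratios use pre-exchange masses; fluxes are capped at the
    source-phase mass so total pesticide is conserved. Returns the net
    water->bed pesticide flux per compound (g).
    """
    if deposition_kg < 0 or resuspension_kg < 0:
        raise ValueError("solid fluxes must be non-negative")
    k = len(state.compounds)
    net = np.zeros(k)
    if deposition_kg > 0 and suspended_mass_before_kg > 0:
        moved = np.minimum(
            deposition_kg / suspended_mass_before_kg * adsorbed_water_g,
            np.minimum(adsorbed_water_g, state.pesticide_water_g))
        state.pesticide_water_g -= moved
        state.pesticide_bed_g += moved
        net += moved
    if resuspension_kg > 0 and bed_mass_before_kg > 0:
        moved = np.minimum(
            resuspension_kg / bed_mass_before_kg * bed_pesticide_before_g,
            state.pesticide_bed_g)
        state.pesticide_bed_g -= moved
        state.pesticide_water_g += moved
        net -= moved
    return net


def sediment_boundary_layer_m(kd_l_kg: float) -> float:
    """Sediment-side boundary layer thickness (m), empirical 318*Kd^0.683.

    The power law is applied exactly as printed with Kd in L/kg and the
    result read in meters; callers can override via
    ``ReachParameters.boundary_layer_sediment_m``.
    """
    if kd_l_kg <= 0:
        raise ValueError("kd must be positive")
    return 318.0 * kd_l_kg ** 0.683


def _fugacity_terms(
    state: ReachState,
    props: PesticideProperties,
    params: ReachParameters,
    area_m2: float,
    compound_index: int,
):
    """Common fugacity bookkeeping: (D_wd [mol/Pa/day], f_w [Pa], f_d [Pa],
    water and pore-water volumes [m^3])."""
    if props.henry_constant <= 0:
        raise ValueError("henry_constant must be positive")
    kd_w = props.kd(params.water_foc_of_ss)
    kd_b = props.kd(params.bed_foc)
    f_wd = fraction_dissolved_water(kd_w, state.c_ss_kg_m3).f_dissolved
    f_dd = fraction_dissolved_sediment(
        kd_b, params.porosity, params.particle_density_g_m3).f_dissolved

    z_water = 1.0 / props.henry_constant  # mol/Pa/m^3
    delta_w = params.boundary_layer_water_m
    delta_d = (params.boundary_layer_sediment_m
               if params.boundary_layer_sediment_m is not None
               else sediment_boundary_layer_m(kd_b))
    k_w = WATER_DIFFUSIVITY_M2_DAY
    k_d = WATER_DIFFUSIVITY_M2_DAY * params.porosity ** (4.0 / 3.0)
    conductance_w = k_w * z_water / delta_w  # mol/Pa/m^2/day
    conductance_d = k_d * z_water / delta_d
    d_wd = area_m2 / (1.0 / conductance_w + 1.0 / conductance_d)  # mol/Pa/day

    vol_w = state.water_volume_m3
    vol_pore = area_m2 * params.active_layer_depth_m * params.porosity
    i = compound_index
    # dissolved concentrations (mol/m^3) -> fugacity f = C/Z
    c_w = state.pesticide_water_g[i] * f_wd / props.molecular_weight / vol_w
    c_d = (state.pesticide_bed_g[i] * f_dd / props.molecular_weight / vol_pore
           if vol_pore > 0 else 0.0)
    return d_wd, c_w / z_water, c_d / z_water, f_wd, f_dd, vol_w, vol_pore


def diffusion_flux(
    state: ReachState,
    props: PesticideProperties,
    params: ReachParameters,
    area_m2: float,
) -> float:
    """Instantaneous diffusive exchange rate J (g/day, positive water->bed).

    Two-film series resistance with Mackay D-values; flux is proportional to
    the water/bed fugacity difference and vanishes at equal fugacities.
    """
    i = state.compounds.index(props.name)
    d_wd, f_w, f_d, *_ = _fugacity_terms(state, props, params, area_m2, i)
    return d_wd * (f_w - f_d) * props.molecular_weight


def equilibrium_water_mass(
    total_g: float,
    f_wd: float,
    f_dd: float,
    vol_w: float,
    vol_pore: float,
) -> float:
    """Water-column mass at two-box fugacity equilibrium (equal dissolved
    concentrations in water column and pore water)."""
    if vol_pore <= 0:
        return total_g
    a = f_wd / vol_w
    b = f_dd / vol_pore
    if a + b == 0:
        return total_g
    return total_g * b / (a + b)


def relax_diffusion(
    state: ReachState,
    props: PesticideProperties,
    params: ReachParameters,
    area_m2: float,
    dt_days: float = 1.0,
) -> float:
    """Advance diffusive exchange one step; returns realized flux (g, +w->b).

    The explicit flux J*dt is capped at the distance to the two-box fugacity
    equilibrium, making the update unconditionally stable and monotone in the
    fugacity difference. Mutates state.
    """
    i = state.compounds.index(props.name)
    d_wd, f_w, f_d, f_wd, f_dd, vol_w, vol_pore = _fugacity_terms(
        state, props, params, area_m2, i)
    j = d_wd * (f_w - f_d) * props.molecular_weight  # g/day
    total = state.pesticide_water_g[i] + state.pesticide_bed_g[i]
    w_eq = equilibrium_water_mass(total, f_wd, f_dd, vol_w, vol_pore)
    to_equilibrium = state.pesticide_water_g[i] - w_eq  # g that should move w->b
    moved = j * dt_days
    if to_equilibrium >= 0:
        moved = min(max(moved, 0.0), to_equilibrium)
    else:
        moved = max(min(moved, 0.0), to_equilibrium)
    state.pesticide_water_g[i] -= moved
    state.pesticide_bed_g[i] += moved
    return moved


def bed_decay_burial(
    state: ReachState,
    properties: Mapping[str, PesticideProperties],
    params: ReachParameters,
    dt_days: float = 1.0,
) -> np.ndarray:
    """First-order decay+burial of bed pesticide; returns lost mass (g)."""
    if dt_days < 0:
        raise ValueError("dt must be non-negative")
    rates = np.array([
        LN2 / properties[c].half_life_sediment + params.burial_rate_per_day
        for c in state.compounds])
    before = state.pesticide_bed_g.copy()
    state.pesticide_bed_g = before * np.exp(-rates * dt_days)
    return before - state.pesticide_bed_g


def reach_daily_step(
    state: ReachState,
    inflow_water_m3: float,
    inflow_solids_kg: float,
    inflow_pesticide_g: np.ndarray | Sequence[float],
    properties: Mapping[str, PesticideProperties],
    params: ReachParameters,
    dt_days: float = 1.0,
) -> dict:
    """Advance one reach by one day; returns outflow and loss terms.

    The reach holds a constant water volume; the day's inflow mixes with
    storage and the same volume leaves carrying the post-update mixed
    concentrations. Returns a dict with outflow_water_m3, outflow_solids_kg,
    outflow_pesticide_g, decayed_water_g, decayed_bed_g, diffusion_g (+w->b),
    deposition_kg, resuspension_kg.
    """
    inflow_pesticide_g = np.asarray(inflow_pesticide_g, dtype=float)
    if inflow_water_m3 < 0 or inflow_solids_kg < 0 or np.any(inflow_pesticide_g < 0):
        raise ValueError("inflows must be non-negative")
    k = len(state.compounds)
    v0 = state.water_volume_m3
    total_vol = v0 + inflow_water_m3

    # inflow mixing
    ss_mass = state.suspended_mass_kg + inflow_solids_kg
    state.pesticide_water_g = state.pesticide_water_g + inflow_pesticide_g
    state.peak_velocity_m_s = (
        params.velocity_peakedness * (inflow_water_m3 / 86400.0) / params.cross_section_m2)
    # work on the mixed volume for the in-day processes
    state.water_volume_m3 = total_vol
    state.c_ss_kg_m3 = ss_mass / total_vol

    suspended_before = ss_mass
    bed_before = state.bed_sediment_mass_kg
    bed_pest_before = state.pesticide_bed_g.copy()
    kd_w = {c: properties[c].kd(params.water_foc_of_ss) for c in state.compounds}
    f_wd_before = np.array([
        fraction_dissolved_water(kd_w[c], state.c_ss_kg_m3).f_dissolved
        for c in state.compounds])
    adsorbed_water = state.pesticide_water_g * (1.0 - f_wd_before)

    deposition, resuspension = deposition_resuspension(state, params)
    pesticide_sedimentation_resuspension(
        state, deposition, resuspension, adsorbed_water,
        suspended_before, bed_before, bed_pest_before)

    # diffusive exchange at post-exchange partitioning
    diffusion = np.zeros(k)
    for i, c in enumerate(state.compounds):
        diffusion[i] = relax_diffusion(
            state, properties[c], params, params.surface_area_m2, dt_days)

    # first-order decay: water column (aquatic half-life) and bed
    decay_w_factor = np.array([
        math.exp(-LN2 * dt_days / properties[c].half_life_water)
        for c in state.compounds])
    before_w = state.pesticide_water_g.copy()
    state.pesticide_water_g = before_w * decay_w_factor
    decayed_water = before_w - state.pesticide_water_g
    decayed_bed = bed_decay_burial(state, properties, params, dt_days)

    # outflow carries the mixed post-update concentrations
    out_frac = inflow_water_m3 / total_vol
    out_solids = state.c_ss_kg_m3 * inflow_water_m3
    out_pesticide = state.pesticide_water_g * out_frac
    state.pesticide_water_g = state.pesticide_water_g - out_pesticide
    ss_remaining = state.c_ss_kg_m3 * total_vol - out_solids
    state.water_volume_m3 = v0
    state.c_ss_kg_m3 = ss_remaining / v0

    return {
        "outflow_water_m3": inflow_water_m3,
        "outflow_solids_kg": out_solids,
        "outflow_pesticide_g": out_pesticide,
        "decayed_water_g": decayed_water,
        "decayed_bed_g": decayed_bed,
        "diffusion_g": diffusion,
        "deposition_kg": deposition,
        "resuspension_kg": resuspension,
    }
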