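"""End-to-end watershed simulation: fields -> routing -> channel network.

Daily pipeline over the scenario's weather record:

1. every field runs its daily soil/pesticide mass balance, yielding
   edge-of-field runoff, soil loss, and dissolved/eroded pesticide fluxes;
2. per drainage zone, edge fluxes are routed to the reach head by
   convolution with the zone's first-passage-time kernel (pesticide kernels
   carry in-transit first-order decay at the aquatic half-life);
3. reaches step daily in upstream-to-downstream order, exchanging solids and
   pesticide with their bed sediment and passing outflow to the next reach.

Every mass term (applications, soil decay and storage, routing losses and
mass still in transit at the end of the run, in-reach decay, bed and water
storage, outlet export) is accumulated independently so the run closes a
global audit for water, solids, and each compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import routing
from .channel_model import ReachState, reach_daily_step
from .field_model import FieldState, SoilColumn, run_field
from .routing import discretize_kernel
from .scenario import WatershedScenario

__all__ = ["SimulationResult", "run_simulation"]

LN2 = math.log(2.0)


@dataclass
class SimulationResult:
    """Outputs of one watershed run."""

    node_daily: dict[str, pd.DataFrame]
    outlet_id: str
    compounds: list[str]
    audit: dict
    soil_loss_kg_total: float

    @property
    def outlet(self) -> pd.DataFrame:
        return self.node_daily[self.outlet_id]

    def monthly_tu(self, node: str | None = None) -> pd.Series:
        df = self.node_daily[node or self.outlet_id]
        idx = pd.DatetimeIndex(pd.to_datetime(df["date"]))
        return pd.Series(df["tu"].to_numpy(), index=idx).groupby(
            idx.to_period("M")).mean()

    def annual_max_tu(self, node: str | None = None) -> pd.Series:
        df = self.node_daily[node or self.outlet_id]
        idx = pd.DatetimeIndex(pd.to_datetime(df["date"]))
        return pd.Series(df["tu"].to_numpy(), index=idx).groupby(idx.year).max()


def _topological_reaches(scenario: WatershedScenario) -> list:
    """Reaches ordered upstream-to-downstream."""
    remaining = {r.reach_id: r for r in scenario.reaches}
    children: dict[str, list[str]] = {rid: [] for rid in remaining}
    for r in scenario.reaches:
        if r.downstream is not None:
            children[r.downstream].append(r.reach_id)
    order: list = []
    def visit(rid: str) -> None:
        for child in children[rid]:
            visit(child)
        order.append(remaining[rid])
    visit(scenario.outlet_id)
    return order  # headwater reaches first, outlet last


def run_simulation(scenario: WatershedScenario) -> SimulationResult:
    """Run the coupled field/watershed simulation over the scenario window."""
    scenario.validate()
    compounds = list(scenario.chemicals)
    properties = scenario.chemicals
    weather = scenario.weather
    n_days = len(weather)
    dates = weather["date"].tolist()
    k = len(compounds)

    # ------------------------------------------------------------------ fields
    apps = scenario.applications
    n_comp = max(1, round(scenario.soil_depth_cm / scenario.compartment_thickness_cm))
    thickness = np.full(n_comp, scenario.soil_depth_cm / n_comp)

    zone_water = {r.reach_id: np.zeros(n_days) for r in scenario.reaches}
    zone_solids = {r.reach_id: np.zeros(n_days) for r in scenario.reaches}
    zone_pesticide = {r.reach_id: np.zeros((n_days, k)) for r in scenario.reaches}

    applied_total = np.zeros(k)
    soil_decayed = np.zeros(k)
    soil_storage = np.zeros(k)
    edge_dissolved = np.zeros(k)
    edge_eroded = np.zeros(k)
    runoff_total = 0.0
    soil_loss_total_kg = 0.0

    for field_cfg in scenario.fields:
        column = SoilColumn(
            thickness, scenario.bulk_density_g_cm3, scenario.soil_f_oc,
            field_cfg.area_ha, compounds, scenario.theta)
        state = FieldState(config=field_cfg, column=column)
        field_apps = apps[apps["field_id"] == field_cfg.field_id]
        by_date: dict = {}
        for row in field_apps.itertuples(index=False):
            by_date.setdefault(row.date, []).append((row.compound, row.mass_kg))
        daily = run_field(state, weather, by_date, properties)

        zone = field_cfg.zone_id
        zone_water[zone] += daily["runoff_m3"]
        zone_solids[zone] += daily["soil_loss_ton"] * 1000.0
        zone_pesticide[zone] += daily["dissolved_g"] + daily["eroded_g"]

        applied_total += daily["applied_g"].sum(axis=0)
        soil_decayed += daily["decayed_g"].sum(axis=0)
        soil_storage += column.total_mass_g()
        edge_dissolved += daily["dissolved_g"].sum(axis=0)
        edge_eroded += daily["eroded_g"].sum(axis=0)
        runoff_total += daily["runoff_m3"].sum()
        soil_loss_total_kg += daily["soil_loss_ton"].sum() * 1000.0

    # ----------------------------------------------------------------- routing
    # lateral inputs delivered to each reach head; kernels per zone, the
    # pesticide kernel attenuated by the aquatic half-life in transit
    lateral_water = {}
    lateral_solids = {}
    lateral_pesticide = {}
    routing_loss_water = 0.0
    routing_loss_solids = 0.0
    transit_water = 0.0
    transit_solids = 0.0
    routing_sink_pesticide = np.zeros(k)
    transit_pesticide = np.zeros(k)

    for spec in scenario.reaches:
        rid = spec.reach_id
        kernel = discretize_kernel(spec.path)
        kernel_sum = float(kernel.sum())
        routed_w = routing.convolve_flux(zone_water[rid], kernel)
        routed_s = routing.convolve_flux(zone_solids[rid], kernel)
        lateral_water[rid] = routed_w[:n_days]
        lateral_solids[rid] = routed_s[:n_days]
        routing_loss_water += zone_water[rid].sum() * (1.0 - kernel_sum)
        routing_loss_solids += zone_solids[rid].sum() * (1.0 - kernel_sum)
        transit_water += routed_w[n_days:].sum()
        transit_solids += routed_s[n_days:].sum()

        pest = np.zeros((n_days, k))
        for i, compound in enumerate(compounds):
            pk = discretize_kernel(
                spec.path,
                decay_rate_per_day=LN2 / properties[compound].half_life_water)
            routed_p = routing.convolve_flux(zone_pesticide[rid][:, i], pk)
            pest[:, i] = routed_p[:n_days]
            total_in = zone_pesticide[rid][:, i].sum()
            routing_sink_pesticide[i] += total_in * (1.0 - float(pk.sum()))
            transit_pesticide[i] += routed_p[n_days:].sum()
        lateral_pesticide[rid] = pest

    # ----------------------------------------------------------------- reaches
    ordered = _topological_reaches(scenario)
    states: dict[str, ReachState] = {}
    bed_mass0 = {}
    for spec in scenario.reaches:
        p = spec.params
        bed0 = (p.surface_area_m2 * p.active_layer_depth_m
                * (1.0 - p.porosity) * p.particle_density_g_m3 * 1e-3)  # kg
        bed_mass0[spec.reach_id] = bed0
        states[spec.reach_id] = ReachState(
            water_volume_m3=spec.water_volume_m3,
            compounds=compounds,
            bed_sediment_mass_kg=bed0,
        )

    outputs = {
        r.reach_id: {
            "flow_m3_d": np.zeros(n_days),
            "ssc_kg_m3": np.zeros(n_days),
            "bed_conc_ng_g": np.zeros((n_days, k)),
            "water_conc_g_m3": np.zeros((n_days, k)),
            "tu": np.zeros(n_days),
        }
        for r in scenario.reaches
    }
    decayed_water = np.zeros(k)
    decayed_bed = np.zeros(k)
    outlet_export = np.zeros(k)
    outlet_water = 0.0
    outlet_solids = 0.0
    baseflow_total = sum(spec.baseflow_m3_d for spec in scenario.reaches) * n_days

    upstream_of: dict[str, list[str]] = {r.reach_id: [] for r in scenario.reaches}
    for r in scenario.reaches:
        if r.downstream is not None:
            upstream_of[r.downstream].append(r.reach_id)

    lc50 = np.array([properties[c].lc50_oc for c in compounds])
    outlet_id = scenario.outlet_id
    day_out: dict[str, dict] = {}

    for t in range(n_days):
        day_out.clear()
        for spec in ordered:
            rid = spec.reach_id
            state = states[rid]
            in_w = spec.baseflow_m3_d + lateral_water[rid][t]
            in_s = lateral_solids[rid][t]
            in_p = lateral_pesticide[rid][t].copy()
            for up in upstream_of[rid]:
                in_w += day_out[up]["outflow_water_m3"]
                in_s += day_out[up]["outflow_solids_kg"]
                in_p += day_out[up]["outflow_pesticide_g"]
            result = reach_daily_step(state, in_w, in_s, in_p, properties, spec.params)
            day_out[rid] = result
            decayed_water += result["decayed_water_g"]
            decayed_bed += result["decayed_bed_g"]
            if rid == outlet_id:
                outlet_export += result["outflow_pesticide_g"]
                outlet_water += result["outflow_water_m3"]
                outlet_solids += result["outflow_solids_kg"]

            out = outputs[rid]
            out["flow_m3_d"][t] = result["outflow_water_m3"]
            out["ssc_kg_m3"][t] = (result["outflow_solids_kg"] / in_w) if in_w > 0 else 0.0
            bed_conc = (state.pesticide_bed_g * 1e9
                        / (state.bed_sediment_mass_kg * 1000.0)
                        if state.bed_sediment_mass_kg > 0 else np.zeros(k))
            out["bed_conc_ng_g"][t] = bed_conc
            out["water_conc_g_m3"][t] = state.pesticide_water_g / state.water_volume_m3
            # TU on the dry-weight-at-1%-OC LC50 basis
            out["tu"][t] = float(
                (bed_conc * 0.01 / spec.params.bed_foc / lc50).sum())

    # ------------------------------------------------------------------- audit
    reach_water_pest = sum(s.pesticide_water_g for s in states.values())
    reach_bed_pest = sum(s.pesticide_bed_g for s in states.values())
    suspended_final = sum(s.suspended_mass_kg for s in states.values())
    bed_final = sum(s.bed_sediment_mass_kg for s in states.values())
    bed_initial = sum(bed_mass0.values())

    water_in = runoff_total + baseflow_total
    water_closure = water_in - routing_loss_water - transit_water - outlet_water
    solids_in = soil_loss_total_kg + bed_initial
    solids_closure = (solids_in - routing_loss_solids - transit_solids
                      - outlet_solids - suspended_final - bed_final)
    pest_closure = (applied_total - soil_decayed - soil_storage
                    - routing_sink_pesticide - transit_pesticide
                    - decayed_water - decayed_bed
                    - reach_water_pest - reach_bed_pest - outlet_export)
    audit = {
        "water": {
            "inputs_m3": water_in,
            "routing_loss_m3": routing_loss_water,
            "in_transit_m3": transit_water,
            "outlet_m3": outlet_water,
            "relative_error": abs(water_closure) / water_in if water_in else 0.0,
        },
        "solids": {
            "inputs_kg": solids_in,
            "routing_loss_kg": routing_loss_solids,
            "in_transit_kg": transit_solids,
            "outlet_kg": outlet_solids,
            "storage_kg": suspended_final + bed_final,
            "relative_error": abs(solids_closure) / solids_in if solids_in else 0.0,
        },
        "pesticide": {
            compounds[i]: {
                "applied_g": float(applied_total[i]),
                "soil_decay_g": float(soil_decayed[i]),
                "soil_storage_g": float(soil_storage[i]),
                "edge_dissolved_g": float(edge_dissolved[i]),
                "edge_eroded_g": float(edge_eroded[i]),
                "routing_sink_g": float(routing_sink_pesticide[i]),
                "in_transit_g": float(transit_pesticide[i]),
                "water_decay_g": float(decayed_water[i]),
                "bed_decay_g": float(decayed_bed[i]),
                "reach_storage_g": float(reach_water_pest[i] + reach_bed_pest[i]),
                "outlet_export_g": float(outlet_export[i]),
                "relative_error": (abs(float(pest_closure[i])) / float(applied_total[i])
                                   if applied_total[i] > 0 else 0.0),
            }
            for i in range(k)
        },
    }

    node_daily = {}
    for spec in scenario.reaches:
        rid = spec.reach_id
        out = outputs[rid]
        frame = {"date": dates, "flow_m3_d": out["flow_m3_d"],
                 "ssc_kg_m3": out["ssc_kg_m3"], "tu": out["tu"]}
        for i, compound in enumerate(compounds):
            frame[f"water_{compound}_g_m3"] = out["water_conc_g_m3"][:, i]
            frame[f"bed_{compound}_ng_g"] = out["bed_conc_ng_g"][:, i]
        node_daily[rid] = pd.DataFrame(frame)

    return SimulationResult(
        node_daily=node_daily,
        outlet_id=outlet_id,
        compounds=compounds,
        audit=audit,
        soil_loss_kg_total=soil_loss_total_kg,
    )
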