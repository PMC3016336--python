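import numpy as np
import pytest

from pyresed import channel_model as cm
from pyresed.chemistry import (
    fraction_dissolved_sediment,
    fraction_dissolved_water,
)


def make_state(**kwargs):
    defaults = dict(
        water_volume_m3=1000.0,
        compounds=["esfenvalerate"],
        c_ss_kg_m3=0.0,
        bed_sediment_mass_kg=0.0,
    )
    defaults.update(kwargs)
    return cm.ReachState(**defaults)


class TestTransportCapacity:
    @pytest.mark.parametrize(
        "spcon, spexp, v, expected",
        [
            (0.02, 1.5, 1.0, 0.02),
            (0.5, 1.0, 2.0, 1.0),
            (0.0001, 1.5, 0.8, 0.0001 * 0.8 ** 1.5),
        ],
    )
    def test_power_law(self, spcon, spexp, v, expected):
        params = cm.ReachParameters(spcon=spcon, spexp=spexp)
        assert cm.transport_capacity(v, params) == pytest.approx(expected)

    def test_zero_velocity_zero_capacity(self):
        assert cm.transport_capacity(0.0, cm.ReachParameters()) == 0.0


class TestDepositionResuspension:
    def test_at_capacity_no_flux(self):
        params = cm.ReachParameters(spcon=0.1, spexp=1.0)
        state = make_state(c_ss_kg_m3=0.05, peak_velocity_m_s=0.5,
                           bed_sediment_mass_kg=100.0)
        dep, res = cm.deposition_resuspension(state, params)
        assert dep == 0.0 and res == 0.0

    def test_excess_deposits(self):
        params = cm.ReachParameters(spcon=0.05, spexp=1.0)
        state = make_state(c_ss_kg_m3=0.2, peak_velocity_m_s=1.0)
        dep, res = cm.deposition_resuspension(state, params)
        assert dep == pytest.approx(150.0)
        assert res == 0.0
        assert state.c_ss_kg_m3 == pytest.approx(0.05)
        assert state.bed_sediment_mass_kg == pytest.approx(150.0)

    def test_resuspension_limited_by_bed_mass(self):
        params = cm.ReachParameters(spcon=0.05, spexp=1.0,
                                    erodibility=1.0, cover=1.0)
        state = make_state(c_ss_kg_m3=0.0, peak_velocity_m_s=1.0,
                           bed_sediment_mass_kg=10.0)
        dep, res = cm.deposition_resuspension(state, params)
        assert res == pytest.approx(10.0)
        assert state.bed_sediment_mass_kg == 0.0
        assert state.c_ss_kg_m3 <= cm.transport_capacity(1.0, params) + 1e-12

    def test_capacity_and_resuspension_increase_with_velocity(self):
        params = cm.ReachParameters(spcon=0.05, spexp=1.5,
                                    erodibility=0.5, cover=0.5)
        results = []
        for v in (0.2, 0.5, 1.0):
            state = make_state(c_ss_kg_m3=0.0, peak_velocity_m_s=v,
                               bed_sediment_mass_kg=1e9)
            _, res = cm.deposition_resuspension(state, params)
            results.append(res)
        assert results[0] < results[1] < results[2]


class TestPesticideSolidFluxes:
    def test_zero_solid_flux_zero_pesticide_flux(self):
        state = make_state(pesticide_water_g=np.array([5.0]),
                           pesticide_bed_g=np.array([2.0]))
        net = cm.pesticide_sedimentation_resuspension(
            state, 0.0, 0.0, np.array([3.0]), 100.0, 50.0, np.array([2.0]))
        assert net[0] == 0.0

    def test_full_deposition_moves_all_adsorbed(self):
        state = make_state(pesticide_water_g=np.array([5.0]),
                           pesticide_bed_g=np.array([0.0]))
        adsorbed = np.array([3.0])
        net = cm.pesticide_sedimentation_resuspension(
            state, 100.0, 0.0, adsorbed, 100.0, 0.0, np.array([0.0]))
        assert net[0] == pytest.approx(3.0)
        assert state.pesticide_water_g[0] == pytest.approx(2.0)
        assert state.pesticide_bed_g[0] == pytest.approx(3.0)

    def test_half_deposition_moves_half(self):
        state = make_state(pesticide_water_g=np.array([5.0]))
        net = cm.pesticide_sedimentation_resuspension(
            state, 50.0, 0.0, np.array([3.0]), 100.0, 0.0, np.array([0.0]))
        assert net[0] == pytest.approx(1.5)

    def test_exchange_conserves_total(self):
        state = make_state(pesticide_water_g=np.array([5.0]),
                           pesticide_bed_g=np.array([4.0]),
                           bed_sediment_mass_kg=200.0)
        total_before = state.pesticide_water_g[0] + state.pesticide_bed_g[0]
        cm.pesticide_sedimentation_resuspension(
            state, 20.0, 0.0, np.array([3.0]), 100.0, 200.0, np.array([4.0]))
        assert (state.pesticide_water_g[0] + state.pesticide_bed_g[0]
                == pytest.approx(total_before))


class TestDiffusion:
    def fast_params(self):
        return cm.ReachParameters(boundary_layer_sediment_m=0.002,
                                  boundary_layer_water_m=0.002,
                                  active_layer_depth_m=0.02,
                                  surface_area_m2=1000.0)

    def test_zero_flux_at_equal_fugacity(self, props):
        p = props["esfenvalerate"]
        params = self.fast_params()
        state = make_state(compounds=["esfenvalerate"], water_volume_m3=10.0)
        # distribute total mass at the two-box equilibrium
        f_wd = fraction_dissolved_water(p.kd(params.water_foc_of_ss), 0.0).f_dissolved
        f_dd = fraction_dissolved_sediment(p.kd(params.bed_foc), params.porosity).f_dissolved
        vol_pore = params.surface_area_m2 * params.active_layer_depth_m * params.porosity
        w_eq = cm.equilibrium_water_mass(10.0, f_wd, f_dd, 10.0, vol_pore)
        state.pesticide_water_g = np.array([w_eq])
        state.pesticide_bed_g = np.array([10.0 - w_eq])
        j = cm.diffusion_flux(state, p, params, params.surface_area_m2)
        assert j == pytest.approx(0.0, abs=1e-12)

    def test_empty_bed_flux_toward_bed(self, props):
        state = make_state(pesticide_water_g=np.array([10.0]))
        j = cm.diffusion_flux(state, props["esfenvalerate"],
                              self.fast_params(), 1000.0)
        assert j > 0.0

    def test_halving_boundary_layers_doubles_flux(self, props):
        p = props["esfenvalerate"]
        state = make_state(pesticide_water_g=np.array([10.0]))
        thick = cm.ReachParameters(boundary_layer_water_m=0.02,
                                   boundary_layer_sediment_m=0.02)
        thin = cm.ReachParameters(boundary_layer_water_m=0.01,
                                  boundary_layer_sediment_m=0.01)
        j_thick = cm.diffusion_flux(state, p, thick, 100.0)
        j_thin = cm.diffusion_flux(state, p, thin, 100.0)
        assert j_thin == pytest.approx(2 * j_thick, rel=1e-9)

    def test_two_box_relaxes_to_equilibrium_partitioning(self, props):
        # isolated boxes: no flows, no decay; fugacity difference must shrink
        # monotonically toward equal dissolved concentrations
        p = props["esfenvalerate"]
        params = self.fast_params()
        state = make_state(compounds=["esfenvalerate"], water_volume_m3=10.0,
                           c_ss_kg_m3=0.05, bed_sediment_mass_kg=100.0,
                           pesticide_water_g=np.array([10.0]))
        moved = []
        for _ in range(800):
            moved.append(cm.relax_diffusion(state, p, params,
                                            params.surface_area_m2, 1.0))
        assert all(m >= -1e-12 for m in moved)  # monotone, never reverses
        f_wd = fraction_dissolved_water(p.kd(params.water_foc_of_ss),
                                        state.c_ss_kg_m3).f_dissolved
        f_dd = fraction_dissolved_sediment(p.kd(params.bed_foc),
                                           params.porosity).f_dissolved
        vol_pore = params.surface_area_m2 * params.active_layer_depth_m * params.porosity
        conc_water = state.pesticide_water_g[0] * f_wd / 10.0
        conc_pore = state.pesticide_bed_g[0] * f_dd / vol_pore
        assert conc_water == pytest.approx(conc_pore, rel=1e-3)
        assert (state.pesticide_water_g[0] + state.pesticide_bed_g[0]
                == pytest.approx(10.0))

    def test_sediment_boundary_layer_power_law(self):
        assert cm.sediment_boundary_layer_m(1.0) == pytest.approx(318.0)
        assert cm.sediment_boundary_layer_m(100.0) == pytest.approx(
            318.0 * 100.0 ** 0.683)


class TestReachDailyStep:
    def test_daily_balance_closes(self, props):
        compounds = list(props)
        params = cm.ReachParameters(surface_area_m2=2000.0, cross_section_m2=3.0)
        state = cm.ReachState(water_volume_m3=5000.0, compounds=compounds,
                              bed_sediment_mass_kg=1e5)
        rng = np.random.default_rng(11)
        total_in = np.zeros(len(compounds))
        total_out = np.zeros(len(compounds))
        decayed = np.zeros(len(compounds))
        for day in range(200):
            inflow_p = rng.random(len(compounds)) * 5.0
            result = cm.reach_daily_step(
                state, float(rng.uniform(0, 20000)), float(rng.uniform(0, 500)),
                inflow_p, props, params)
            total_in += inflow_p
            total_out += result["outflow_pesticide_g"]
            decayed += result["decayed_water_g"] + result["decayed_bed_g"]
        storage = state.pesticide_water_g + state.pesticide_bed_g
        closure = total_in - total_out - decayed - storage
        assert np.all(np.abs(closure) / total_in < 1e-9)

    def test_negative_inflow_rejected(self, props):
        state = cm.ReachState(water_volume_m3=100.0, compounds=list(props))
        with pytest.raises(ValueError):
            cm.reach_daily_step(state, -1.0, 0.0, np.zeros(4), props,
                                cm.ReachParameters())

    def test_bed_decay_uses_sediment_half_life(self, props):
        state = cm.ReachState(water_volume_m3=100.0, compounds=["lambda-cyhalothrin"],
                              pesticide_bed_g=np.array([8.0]))
        lost = cm.bed_decay_burial(state, props, cm.ReachParameters(), dt_days=12.0)
        assert state.pesticide_bed_g[0] == pytest.approx(4.0)  # 12 d half-life
        assert lost[0] == pytest.approx(4.0)
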