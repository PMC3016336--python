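import datetime

import numpy as np
import pytest

from pyresed import field_model as fm
from conftest import cumulative_eroded_concentration, make_field_state


def column_with(thicknesses, compounds=("bifenthrin",), area_ha=1.0):
    col = fm.SoilColumn(np.asarray(thicknesses, dtype=float), 1.5, 0.01,
                        area_ha, list(compounds))
    return col


class TestComputeWeights:
    def test_equal_compartments_uniform(self):
        col = column_with([0.25] * 8)
        w = fm.compute_weights(fm.ErosionConfig(soil_interaction_depth_cm=1.0), col)
        assert np.allclose(w[:4], 0.25)
        assert np.allclose(w[4:], 0.0)

    def test_single_compartment(self):
        col = column_with([1.0])
        w = fm.compute_weights(fm.ErosionConfig(), col)
        assert np.allclose(w, [1.0])

    def test_straddling_compartment_partial_weight(self):
        col = column_with([0.6, 0.8])
        w = fm.compute_weights(fm.ErosionConfig(soil_interaction_depth_cm=1.0), col)
        assert np.allclose(w, [0.6, 0.4])

    def test_weights_sum_to_one(self):
        col = column_with([0.3, 0.45, 0.7, 1.0])
        for curve in ("uniform", "exponential"):
            w = fm.compute_weights(
                fm.ErosionConfig(soil_interaction_depth_cm=1.3,
                                 weighting_curve=curve), col)
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)

    def test_interaction_depth_deeper_than_column_rejected(self):
        col = column_with([0.5, 0.5])
        with pytest.raises(ValueError):
            fm.compute_weights(fm.ErosionConfig(soil_interaction_depth_cm=2.0), col)


class TestErodedConcentration:
    def test_constant_concentration_recovered(self):
        col = column_with([0.5, 0.5])
        soil = col.soil_mass_g
        col.adsorbed_g[:, 0] = 3e-6 * soil
        c = fm.eroded_concentration(col, np.array([0.5, 0.5]))
        assert c[0] == pytest.approx(3e-6)

    def test_arithmetic_mean_of_two(self):
        col = column_with([0.5, 0.5])
        soil = col.soil_mass_g
        col.adsorbed_g[:, 0] = np.array([2e-6, 4e-6]) * soil
        c = fm.eroded_concentration(col, np.array([0.5, 0.5]))
        assert c[0] == pytest.approx(3e-6)

    def test_weighted_dot_product(self):
        col = column_with([0.6, 0.4])
        soil = col.soil_mass_g
        col.adsorbed_g[:, 0] = np.array([1e-6, 0.0]) * soil
        c = fm.eroded_concentration(col, np.array([0.6, 0.4]))
        assert c[0] == pytest.approx(6e-7)

    def test_bounded_by_extremes(self):
        col = column_with([0.5, 0.3, 0.2])
        soil = col.soil_mass_g
        conc = np.array([1e-6, 5e-6, 2e-6])
        col.adsorbed_g[:, 0] = conc * soil
        w = fm.compute_weights(fm.ErosionConfig(), col)
        c = fm.eroded_concentration(col, w)[0]
        assert conc.min() <= c <= conc.max()


class TestErosionFlux:
    @pytest.mark.parametrize(
        "c_se, x_e, r_om, expected",
        [
            (1e-6, 1.0, 1.0, 1.0),
            (3e-6, 0.0, 2.0, 0.0),
            (2e-6, 0.5, 2.0, 2.0),
        ],
    )
    def test_flux_arithmetic(self, c_se, x_e, r_om, expected):
        assert fm.erosion_pesticide_flux(c_se, x_e, r_om) == pytest.approx(expected)


class TestApplyErosionLoss:
    def test_cap_at_available_mass(self):
        col = column_with([0.5, 0.5])
        col.adsorbed_g[:, 0] = [0.3, 0.2]
        w = np.array([0.5, 0.5])
        removed = fm.apply_erosion_loss(col, w, np.array([10.0]), dt=1.0)
        assert removed[0] == pytest.approx(0.5)
        assert np.allclose(col.adsorbed_g[:, 0], 0.0)

    def test_proportional_split_in_uniform_column(self):
        col = column_with([0.25] * 4)
        col.adsorbed_g[:, 0] = 1.0
        w = np.full(4, 0.25)
        removed = fm.apply_erosion_loss(col, w, np.array([2.0]), dt=1.0)
        assert removed[0] == pytest.approx(2.0)
        assert np.allclose(col.adsorbed_g[:, 0], 0.5)

    def test_total_matches_demand_with_unequal_concentrations(self):
        col = column_with([0.25] * 4)
        col.adsorbed_g[:, 0] = [4.0, 2.0, 1.0, 1.0]
        w = np.full(4, 0.25)
        removed = fm.apply_erosion_loss(col, w, np.array([1.0]), dt=1.0)
        assert removed[0] == pytest.approx(1.0)
        # removal proportional to w_j * C_s,j: equal thickness, so to mass
        assert col.adsorbed_g[0, 0] < 4.0
        assert col.adsorbed_g[2, 0] > 0.5


class TestRunoffExtraction:
    def test_zero_runoff_no_flux(self):
        col = column_with([1.0, 1.0])
        col.dissolved_g[:, 0] = 1.0
        before = col.dissolved_g.copy()
        flux = fm.runoff_extraction(col, 0.0)
        assert flux[0] == 0.0
        assert np.array_equal(col.dissolved_g, before)

    def test_mass_below_extraction_zone_untouched(self):
        col = column_with([1.0, 1.0, 2.0])
        col.dissolved_g[2, 0] = 5.0  # below 2 cm
        flux = fm.runoff_extraction(col, 1.0, extraction_depth_cm=2.0)
        assert flux[0] == 0.0
        assert col.dissolved_g[2, 0] == 5.0

    def test_single_compartment_is_volume_times_concentration(self):
        col = column_with([2.0], area_ha=1.0)
        col.dissolved_g[0, 0] = 10.0
        conc_g_per_l = 10.0 / col.water_volume_l[0]
        runoff_cm = 0.5
        runoff_l = runoff_cm * 1.0 * fm.CM2_PER_HA / 1000.0
        flux = fm.runoff_extraction(col, runoff_cm)
        assert flux[0] == pytest.approx(runoff_l * conc_g_per_l)


class TestMusle:
    def test_zero_runoff_zero_loss(self):
        assert fm.musle_event_soil_loss(0.0, 0.5, 0.3, 0.2, 1.2) == 0.0

    def test_linear_in_crop_factor(self):
        base = fm.musle_event_soil_loss(100.0, 0.5, 0.3, 0.2, 1.2)
        doubled = fm.musle_event_soil_loss(100.0, 0.5, 0.3, 0.4, 1.2)
        assert doubled == pytest.approx(2 * base)

    def test_hand_evaluation(self):
        expected = 11.8 * (100.0 * 0.5) ** 0.56 * 0.3 * 0.2 * 1.2 * 1.0
        got = fm.musle_event_soil_loss(100.0, 0.5, 0.3, 0.2, 1.2, 1.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(7.6, abs=0.1)


class TestDailyStep:
    def test_mass_balance_closes(self, props, three_year_weather):
        from conftest import melon_field_applications

        state = make_field_state(0.5)
        apps = melon_field_applications(3)
        out = fm.run_field(state, three_year_weather, apps, props)
        applied = out["applied_g"].sum()
        decayed = out["decayed_g"].sum()
        runoff = out["dissolved_g"].sum()
        eroded = out["eroded_g"].sum()
        storage = state.column.total_mass_g().sum()
        assert applied > 0 and eroded > 0
        closure = applied - decayed - runoff - eroded - storage
        assert abs(closure) / applied < 1e-9

    def test_malformed_application_rejected(self, props):
        state = make_field_state(0.5)
        with pytest.raises(ValueError, match="unknown compound"):
            fm.daily_field_step(state, 0.0, datetime.date(1990, 1, 15),
                                [("not-a-pesticide", 1.0)], props)
        with pytest.raises(ValueError, match="invalid application mass"):
            fm.daily_field_step(state, 0.0, datetime.date(1990, 1, 15),
                                [("bifenthrin", -1.0)], props)


class TestErosionAlgorithmBehaviour:
    """Discretization behaviour of the soil-interaction-depth algorithm."""

    def test_improved_mode_invariant_to_compartment_depth(
            self, props, three_year_weather):
        concs = [
            cumulative_eroded_concentration(th, "improved", three_year_weather, props)
            for th in (0.1, 0.2, 0.5, 1.0)
        ]
        spread = (max(concs) - min(concs)) / min(concs)
        assert spread < 0.01

    def test_original_matches_improved_at_interaction_depth(
            self, props, three_year_weather):
        improved = cumulative_eroded_concentration(
            1.0, "improved", three_year_weather, props)
        original = cumulative_eroded_concentration(
            1.0, "original", three_year_weather, props)
        assert original == pytest.approx(improved, rel=0.01)

    def test_original_underestimates_with_thin_compartments(
            self, props, three_year_weather):
        improved = cumulative_eroded_concentration(
            0.1, "improved", three_year_weather, props)
        original = cumulative_eroded_concentration(
            0.1, "original", three_year_weather, props)
        assert original < improved
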