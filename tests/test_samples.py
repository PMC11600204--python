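"""Constitutive models, activation dynamics, condition maps."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibermech.samples import (
    PlantParams,
    activation_from_stimulus,
    complex_modulus_closed_form,
    condition_grid,
    condition_to_params,
    plant_preset,
    pulse_train,
    total_force,
)

OMEGA_01 = 2 * math.pi * 0.1


class TestComplexModulus:
    def test_kelvin_voigt_limit(self):
        """E' = 3 kPa with a pure viscous loss of 1.2 kPa at 0.1 Hz gives
        |E*| = 3.2311 kPa and tan delta = 0.4 exactly (drag as dashpot)."""
        params = PlantParams(
            equilibrium_modulus=3000.0,
            drag_coefficient=1200.0 / OMEGA_01,
        )
        e_star, tan_d = complex_modulus_closed_form(params, 0.1, "solution")
        assert tan_d == pytest.approx(0.4)
        assert e_star == pytest.approx(3231.1, rel=1e-4)

    def test_pure_elastic(self, elastic_plant):
        _, tan_d = complex_modulus_closed_form(elastic_plant, 0.1, "solution")
        assert tan_d == 0.0

    def test_air_lowers_loss_only(self, core):
        es_sol, td_sol = complex_modulus_closed_form(core, 0.1, "solution")
        es_air, td_air = complex_modulus_closed_form(core, 0.1, "air")
        assert td_air < td_sol
        # storage is medium-independent: E' = |E*| cos(atan(tan d))
        assert es_sol / math.hypot(1, td_sol) == pytest.approx(
            es_air / math.hypot(1, td_air)
        )

    def test_fluid_like_rejected(self):
        with pytest.raises(ValueError):
            complex_modulus_closed_form(
                PlantParams(equilibrium_modulus=0.0), 0.1
            )

    @given(scale=st.floats(min_value=1e-2, max_value=1e2))
    @settings(max_examples=50, deadline=None)
    def test_tan_delta_scale_invariant(self, core, scale):
        scaled = replace(
            core,
            equilibrium_modulus=core.equilibrium_modulus * scale,
            arm_modulus=core.arm_modulus * scale,
            arm_viscosity=core.arm_viscosity * scale,
            drag_coefficient=core.drag_coefficient * scale,
        )
        _, td0 = complex_modulus_closed_form(core, 0.1)
        _, td1 = complex_modulus_closed_form(scaled, 0.1)
        assert td1 == pytest.approx(td0)

    @given(gamma=st.floats(min_value=0.0, max_value=5e3),
           f=st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_solution_never_below_air(self, core, gamma, f):
        p = replace(core, drag_coefficient=gamma)
        _, td_sol = complex_modulus_closed_form(p, f, "solution")
        _, td_air = complex_modulus_closed_form(p, f, "air")
        assert td_sol >= td_air
        if gamma == 0.0:
            assert td_sol == td_air


class TestTotalForce:
    def test_rest_state(self, myobundle):
        assert total_force(myobundle, 0.0, 0.0, 0.0) == 0.0

    def test_active_peak_definition(self, myobundle):
        on = total_force(myobundle, myobundle.optimal_strain, 0.0, 1.0)
        off = total_force(myobundle, myobundle.optimal_strain, 0.0, 0.0)
        assert on - off == pytest.approx(myobundle.active_peak)

    def test_optimal_strain_in_window(self, myobundle):
        strains = np.linspace(0.0, 0.15, 1501)
        active = [
            total_force(myobundle, s, 0.0, 1.0)
            - total_force(myobundle, s, 0.0, 0.0)
            for s in strains
        ]
        s_opt = strains[int(np.argmax(active))]
        assert 0.04 <= s_opt <= 0.07

    def test_continuous_in_strain(self, myobundle):
        s = np.linspace(-0.05, 0.2, 2000)
        f = np.array([total_force(myobundle, si, 0.0, 0.5) for si in s])
        assert np.all(np.abs(np.diff(f)) < 5e-7)


class TestActivation:
    def test_single_pulse_peaks_at_tau(self):
        t = np.linspace(0.0, 2.0, 4001)
        act = activation_from_stimulus([0.2], t, twitch_time=0.15)
        assert t[int(np.argmax(act))] == pytest.approx(0.35, abs=2e-3)

    def test_fusion_at_five_hertz(self):
        t = np.linspace(0.0, 6.0, 6001)
        slow = activation_from_stimulus(pulse_train(1.0, 6.0), t, 0.15)
        fast = activation_from_stimulus(pulse_train(5.0, 6.0), t, 0.15)
        plateau = fast[(t > 3.0) & (t < 5.5)]
        assert plateau.min() > slow.max()

    def test_empty_train(self):
        t = np.linspace(0.0, 1.0, 100)
        assert not activation_from_stimulus([], t, 0.15).any()

    def test_bounded(self):
        t = np.linspace(0.0, 10.0, 5001)
        act = activation_from_stimulus(pulse_train(20.0, 10.0), t, 0.15)
        assert act.max() <= 1.0

    def test_non_increasing_pulses_rejected(self):
        with pytest.raises(ValueError):
            activation_from_stimulus([0.5, 0.4], np.linspace(0, 1, 10), 0.15)


class TestConditionMaps:
    def test_combination_eight_is_pure_bundle(self):
        state = condition_to_params({"combination": 8})
        assert state.label == "c_bundle"
        assert state.params.drag_coefficient == 0.0
        _, td = complex_modulus_closed_form(state.params, 0.1, "solution")
        assert 0.1 <= td <= 0.4

    def test_sphere_conditions_not_measurable(self):
        for combo in (1, 2, 3, 5, 6):
            assert not condition_to_params({"combination": combo}).measurable
        for combo in (4, 8, 7, 9, 10, 11, 12):
            assert condition_to_params({"combination": combo}).measurable

    def test_cocl2_reference_condition(self):
        state = condition_to_params({"cocl2_uM": 0.0})
        assert state.params.active_peak > 3e-6
        _, td = complex_modulus_closed_form(state.params, 0.1, "solution")
        assert td < 0.4

    def test_cocl2_saturating_dose(self):
        state = condition_to_params({"cocl2_uM": 200.0})
        assert state.params.active_peak < 0.05 * plant_preset(
            "myobundle"
        ).active_peak

    def test_cf_monotone_in_dose(self):
        doses = [0, 40, 80, 120, 160, 200]
        peaks = [condition_to_params({"cocl2_uM": d}).params.active_peak
                 for d in doses]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_unknown_levels_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            condition_to_params({"combination": 13})
        with pytest.raises(ValueError, match="valid"):
            condition_to_params(
                {"alginate": 0.65, "cacl2": 1.0, "diameter_um": 200.0}
            )
        with pytest.raises(ValueError):
            condition_to_params({"frobnicate": 1})

    def test_seeded_replicates_bit_reproducible(self):
        cond = {"alginate": 0.7, "cacl2": 1.0, "diameter_um": 200.0}
        a = condition_to_params(cond, seed=42, replicate=3)
        b = condition_to_params(cond, seed=42, replicate=3)
        assert a == b
        c = condition_to_params(cond, seed=42, replicate=4)
        assert c.params != a.params

    def test_grids_have_documented_sizes(self):
        assert len(condition_grid("gelma12")) == 12
        assert len(condition_grid("cocl2_11")) == 11
        assert len(condition_grid("cocl2_14")) == 14
        assert len(condition_grid("bioink54")) == 54
        with pytest.raises(KeyError):
            condition_grid("nope")
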