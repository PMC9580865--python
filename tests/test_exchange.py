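import dataclasses
import math

import numpy as np
import pytest

from alvgas import (BindingParameters, membrane_diffusing_capacity, oxygen_flow,
                    parcel_trajectory, solve_profile)
from alvgas.exchange import (KO2_DEFAULT, CapillaryDiscretization, ParameterError,
                             SectionState, step_section)

B = BindingParameters()


class TestMembraneDiffusingCapacity:
    def test_default_morphology(self):
        """s = 121,000 um^2 and tau = 1.11 um give 6e-9 ml/(s x mmHg)."""
        assert membrane_diffusing_capacity(121_000.0, 1.11) == pytest.approx(6e-9)

    def test_linear_in_surface_inverse_in_thickness(self):
        base = membrane_diffusing_capacity(100_000.0, 1.0)
        assert membrane_diffusing_capacity(200_000.0, 1.0) == pytest.approx(2 * base)
        assert membrane_diffusing_capacity(100_000.0, 2.0) == pytest.approx(base / 2)
        assert membrane_diffusing_capacity(0.0, 1.0) == 0.0

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            membrane_diffusing_capacity(121_000.0, 0.0)


class TestOxygenFlow:
    def test_values_and_antisymmetry(self):
        assert oxygen_flow(6e-9, 0.0) == 0.0
        assert oxygen_flow(6e-9, 60.0) == pytest.approx(3.6e-7)
        assert oxygen_flow(6e-9, -60.0) == -oxygen_flow(6e-9, 60.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            oxygen_flow(math.nan, 1.0)


class TestDiscretization:
    def test_totals_reassemble(self, defaults):
        disc = CapillaryDiscretization.from_parameters(defaults, 100)
        assert disc.n_sections * disc.section_surface == pytest.approx(defaults.surface_area)
        assert disc.n_sections * disc.section_blood_volume == pytest.approx(defaults.blood_volume)
        transit = defaults.capillary_length / (defaults.blood_flow_velocity * 1000.0)
        assert disc.n_sections * disc.residence_time == pytest.approx(transit)

    def test_too_few_sections(self, defaults):
        with pytest.raises(ValueError):
            CapillaryDiscretization.from_parameters(defaults, 1)

    def test_zero_velocity_rejected(self, defaults):
        frozen = dataclasses.replace(defaults, blood_flow_velocity=0.0)
        with pytest.raises(ValueError, match="velocity"):
            CapillaryDiscretization.from_parameters(frozen, 100)


class TestStepSection:
    def test_equilibrium_is_fixed_point(self, defaults, binding):
        disc = CapillaryDiscretization.from_parameters(defaults, 100)
        from alvgas.binding import BloodContext, o2_content, saturation_at

        ctx = BloodContext(pCO2=defaults.alveolar_pCO2)
        state = SectionState(0, defaults.alveolar_pO2, defaults.alveolar_pCO2,
                             float(saturation_at(defaults.alveolar_pO2, ctx, binding)),
                             float(o2_content(defaults.alveolar_pO2, ctx, binding)), 0.0, 0.0)
        after = step_section(state, disc, defaults, binding, dm_effective=3e-9)
        assert after.pO2 == pytest.approx(state.pO2, abs=1e-9)
        assert after.pCO2 == pytest.approx(state.pCO2, abs=1e-12)

    def test_one_step_moves_gases_toward_alveolar(self, defaults, binding):
        profile = solve_profile(defaults, binding, 100)
        first, second = profile.states[0], profile.states[1]
        assert second.pO2 > first.pO2
        assert second.pCO2 < first.pCO2


class TestSolveProfile:
    def test_conservation_bookkeeping_identity(self, defaults, binding):
        """Total uptake equals the sum of section fluxes to float precision."""
        profile = solve_profile(defaults, binding, 150)
        flux_sum = sum(s.o2_flux for s in profile.sections)
        assert profile.total_o2_uptake_rate == pytest.approx(flux_sum, rel=1e-12)

    def test_rer_coupling_exact(self, defaults, binding):
        profile = solve_profile(defaults, binding, 100)
        assert profile.total_co2_output_rate == 0.82 * profile.total_o2_uptake_rate

    def test_monotone_profiles(self, defaults, binding):
        profile = solve_profile(defaults, binding, 100)
        po2 = np.array([s.pO2 for s in profile.states])
        pco2 = np.array([s.pCO2 for s in profile.states])
        sat = np.array([s.saturation for s in profile.states])
        assert np.all(np.diff(po2) >= 0)
        assert np.all(np.diff(pco2) <= 0)
        assert np.all(np.diff(sat) >= 0)
        assert po2[-1] <= defaults.alveolar_pO2 + 1e-9
        # CO2 is bookkept through the respiratory exchange ratio; with the
        # physiological CO2 capacitance the outlet lands at the alveolar
        # tension to within a small residual rather than exactly above it
        assert pco2[-1] >= defaults.alveolar_pCO2 - 0.2

    def test_saturation_consistent_with_binding(self, defaults, binding):
        from alvgas.binding import BloodContext, saturation_at

        profile = solve_profile(defaults, binding, 50)
        for s in profile.states:
            ctx = BloodContext(pCO2=s.pCO2, temperature=defaults.blood_temperature,
                               ph_rbc=defaults.ph_rbc, dpg=defaults.dpg_concentration)
            assert s.saturation == pytest.approx(float(saturation_at(s.pO2, ctx, binding)),
                                                 abs=1e-9)

    def test_discretization_convergence(self, defaults, binding):
        p100 = solve_profile(defaults, binding, 100)
        p200 = solve_profile(defaults, binding, 200)
        assert p100.outlet_state.pO2 == pytest.approx(p200.outlet_state.pO2, rel=1e-3)
        assert p100.total_o2_uptake_rate == pytest.approx(p200.total_o2_uptake_rate, rel=1e-3)

    def test_slow_transit_reaches_equilibrium(self, defaults, binding):
        slow = dataclasses.replace(defaults, blood_flow_velocity=0.01)
        profile = solve_profile(slow, binding, 100)
        assert profile.outlet_state.pO2 == pytest.approx(defaults.alveolar_pO2, abs=0.5)

    def test_outlet_saturation_exceeds_inlet(self, defaults, binding):
        profile = solve_profile(defaults, binding, 100)
        assert profile.outlet_state.saturation > profile.states[0].saturation

    def test_zero_gradient_zero_uptake(self, defaults, binding):
        flat = dataclasses.replace(defaults, alveolar_pO2=100.0, blood_pO2_in=100.0)
        profile = solve_profile(flat, binding, 100)
        assert profile.total_o2_uptake_rate == pytest.approx(0.0, abs=1e-20)
        assert all(s.o2_flux == pytest.approx(0.0, abs=1e-20) for s in profile.sections)

    def test_zero_blood_volume_degenerate(self, defaults, binding):
        empty = dataclasses.replace(defaults, blood_volume=0.0)
        profile = solve_profile(empty, binding, 100)
        assert profile.sections == ()
        assert profile.total_o2_uptake_rate == 0.0

    def test_invalid_parameters_propagate(self, defaults, binding):
        bad = dataclasses.replace(defaults, barrier_thickness=50.0)
        with pytest.raises(ParameterError, match="barrier_thickness"):
            solve_profile(bad, binding, 100)

    def test_determinism_bit_identical(self, defaults, binding):
        a = solve_profile(defaults, binding, 100)
        b = solve_profile(defaults, binding, 100)
        assert a == b

    def test_linearized_carriage_matches_closed_form(self, defaults, binding):
        """With constant capacitance beta the profile is exponential:
        p(t) = pA - (pA - p0) exp(-DM_eff t / (V_b beta))."""
        beta = 2e-3  # ml O2 / (ml blood x mmHg)
        n = 400
        profile = solve_profile(
            defaults, binding, n,
            content=lambda p, ctx: beta * p,
            inverse_content=lambda c, ctx: c / beta,
        )
        vb_ml = defaults.blood_volume * 1e-12
        rate = profile.dm_effective / (vb_ml * beta)
        t = np.array([s.entry_time for s in profile.states])
        expected = defaults.alveolar_pO2 - (
            defaults.alveolar_pO2 - defaults.blood_pO2_in) * np.exp(-rate * t)
        actual = np.array([s.pO2 for s in profile.states])
        assert np.max(np.abs(actual - expected) / expected) < 5e-3


class TestParcelTrajectory:
    def test_endpoints_and_transit_time(self, defaults, binding):
        traj = parcel_trajectory(defaults, binding, 100)
        profile = solve_profile(defaults, binding, 100)
        assert traj[0, 0] == 0.0
        assert traj[-1, 0] == pytest.approx(0.5)  # L/v = 500 um / 1 mm/s
        assert traj[0, 2] == profile.states[0].saturation
        assert traj[-1, 2] == profile.outlet_state.saturation

    def test_saturation_rises_81_to_97(self, halftime_scenario, binding):
        traj = parcel_trajectory(halftime_scenario, binding, 100)
        assert traj[0, 2] == pytest.approx(0.81, abs=0.02)
        assert traj[-1, 2] == pytest.approx(0.97, abs=0.01)
        assert np.all(np.diff(traj[:, 2]) >= 0)

    def test_recruitment_does_not_change_parcel_kinetics(self, defaults, binding):
        """Each parcel sees its own capillary wall: the oxygenation time
        course is independent of how many other capillaries are perfused."""
        half = parcel_trajectory(defaults, binding, 100)
        full = parcel_trajectory(
            dataclasses.replace(defaults, blood_volume=808_000.0), binding, 100)
        assert np.allclose(half[:, 1], full[:, 1], rtol=1e-12)


def test_ko2_calibration_constant():
    """KO2 is the one calibrated constant: DMO2(default morphology) = 6e-9."""
    assert KO2_DEFAULT * 121_000.0 / 1.11 == pytest.approx(6e-9, rel=1e-12)
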