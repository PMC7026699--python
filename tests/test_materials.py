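"""Material physics: scattering terms, stopping powers, catalogue, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pctpath import (
    ELEMENTS,
    WATER,
    Material,
    bethe_bloch,
    element_scatter_term,
    fit_calibration,
    mean_excitation_bragg,
    nominated_rstp,
    relative_scattering_power,
    rscp_from_rstp,
    scattering_length,
)
from pctpath.materials import ELEMENT_I, WATER_SUM, CalibrationCurve, rstp_curve


def water_like(density=1.0, I=75.0):
    return Material.from_mass_fractions(
        "w", {"H": 0.1119, "O": 0.8881}, density, mean_excitation=I
    )


class TestElementScatterTerm:
    @pytest.mark.parametrize(
        "Z,A,expected",
        [(1, 1.008, 19.659), (8, 15.999, 66.35)],
    )
    def test_closed_form_values(self, Z, A, expected):
        assert element_scatter_term(Z, A) == pytest.approx(expected, rel=1e-3)

    def test_unit_mass_reduces_to_log_constant(self):
        # Z = A = 1 collapses the (AZ)^(-1/3) factor to unity
        assert element_scatter_term(1, 1.0) == pytest.approx(
            2 * math.log(33219.0) - 1.0, abs=1e-12
        )

    @pytest.mark.parametrize("Z,A", [(0, 12.0), (6, -1.0), (6, 0.0)])
    def test_rejects_unphysical_input(self, Z, A):
        with pytest.raises(ValueError):
            element_scatter_term(Z, A)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 92), st.floats(1.0, 250.0))
    def test_positive_for_physical_nuclei(self, Z, A):
        assert element_scatter_term(Z, A) > 0


class TestRelativeScatteringPower:
    def test_water_is_unity_and_reciprocal_prints_0_01636(self):
        assert relative_scattering_power(WATER) == pytest.approx(1.0, abs=1e-12)
        assert 1.0 / WATER_SUM == pytest.approx(0.01636, abs=5e-6)

    def test_linear_in_density(self):
        assert relative_scattering_power(water_like(2.0)) == pytest.approx(
            2.0 * relative_scattering_power(water_like(1.0)), rel=1e-12
        )

    def test_air_value_from_its_composition(self):
        air = Material.from_mass_fractions(
            "air", {"N": 0.79, "O": 0.21}, 0.001225, mean_excitation=85.7
        )
        # oracle: rho times the air/water summation ratio
        expected = 0.001225 * air.scatter_sum() / WATER_SUM
        got = relative_scattering_power(air)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0012, abs=2e-4)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            Material("empty", [], 1.0)


class TestScatteringLength:
    def test_water_scattering_length_near_47_cm(self):
        assert 1.0 / scattering_length(WATER) == pytest.approx(46.9, rel=2e-3)

    def test_inverse_length_linear_in_density(self):
        assert scattering_length(water_like(2.0)) == pytest.approx(
            2.0 * scattering_length(water_like(1.0)), rel=1e-12
        )

    def test_single_element_reduces_to_elemental_form(self):
        from pctpath.constants import ALPHA, N_AVOGADRO, R_E

        carbon = Material.from_mass_fractions("C", {"C": 1.0}, 2.0)
        el = ELEMENTS["C"]
        expected = (
            ALPHA * N_AVOGADRO * R_E**2 * 2.0 * element_scatter_term(el.Z, el.A)
        )
        assert scattering_length(carbon) == pytest.approx(expected, rel=1e-12)


class TestBetheBloch:
    @pytest.mark.parametrize("E,expected", [(200.0, 4.49), (100.0, 7.29)])
    def test_water_values_against_published_tables(self, E, expected):
        # PSTAR water: 4.492 MeV/cm at 200 MeV, 7.289 at 100 MeV
        assert bethe_bloch(WATER, E) == pytest.approx(expected, rel=0.01)

    def test_strictly_decreasing_on_plateau(self):
        E = np.arange(10.0, 301.0, 5.0)
        S = bethe_bloch(WATER, E)
        assert np.all(np.diff(S) < 0)

    def test_energy_window_enforced(self):
        with pytest.raises(ValueError):
            bethe_bloch(WATER, 0.5)
        with pytest.raises(ValueError):
            bethe_bloch(WATER, 400.0)


class TestBraggRule:
    def test_single_element_returns_that_value(self):
        m = Material.from_mass_fractions("C", {"C": 1.0}, 2.0)
        assert mean_excitation_bragg(m) == pytest.approx(ELEMENT_I["C"], rel=1e-12)

    def test_identical_constituents_any_weights(self):
        m = Material(
            "split", [(ELEMENTS["O"], 0.3), (ELEMENTS["O"], 0.7)], 1.0
        )
        assert mean_excitation_bragg(m) == pytest.approx(ELEMENT_I["O"], rel=1e-12)

    def test_water_near_75_eV(self):
        m = Material.from_mass_fractions("w", {"H": 0.1119, "O": 0.8881}, 1.0)
        assert mean_excitation_bragg(m) == pytest.approx(75.0, rel=0.03)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            mean_excitation_bragg(WATER, [75.0])


class TestNominatedRStP:
    def test_water_is_exactly_one(self):
        assert nominated_rstp(WATER) == 1.0

    def test_density_scaled_water(self):
        # electron-density scaling: same composition at rho = 1.05
        assert nominated_rstp(water_like(1.05)) == pytest.approx(1.05, rel=2e-3)

    def test_invariant_under_fraction_renormalization(self):
        a = Material.from_mass_fractions(
            "a", {"H": 0.1119, "O": 0.8881}, 1.05, mean_excitation=75.0
        )
        b = Material.from_mass_fractions(
            "b", {"H": 0.1119 * 1.005, "O": 0.8881 * 1.005}, 1.05, mean_excitation=75.0
        )  # same ratios, sum 1.005 -> renormalized on load
        assert nominated_rstp(a) == pytest.approx(nominated_rstp(b), rel=1e-6)

    def test_cortical_bone_energy_independence(self, catalogue):
        bone = catalogue.material("skeleton_cortical_bone")
        shat = catalogue["skeleton_cortical_bone"].rstp
        E = np.arange(10.0, 301.0, 1.0)
        rel = np.abs(rstp_curve(bone, E) - shat) / shat
        assert np.all(rel[E >= 30.0] < 0.01)
        assert np.all(rel < 0.02)


class TestCalibration:
    def test_catalogue_sanity(self, catalogue):
        df = catalogue.to_frame()
        assert {"water", "air"} <= set(df["name"])
        assert (df["rstp"] > 0).all() and (df["rscp"] > 0).all()
        assert len(df) == 48  # 46 tissues + air + water

    def test_group_sizes_match_published_counts(self, calibration):
        assert calibration.n_solid == 45
        assert calibration.n_low == 4
        assert calibration.p2_low == 0.0

    def test_fit_close_to_published_parameters(self, calibration):
        # published: solid 0.3905 / 0.6448 (r2 0.9945); low 1.2127 (r2 0.9958)
        assert calibration.p1_solid == pytest.approx(0.3905, abs=0.02)
        assert calibration.p2_solid == pytest.approx(0.6448, abs=0.03)
        assert calibration.r2_solid > 0.99
        assert calibration.p1_low == pytest.approx(1.2127, abs=0.02)
        assert calibration.r2_low > 0.99

    def test_intersection_anchored_near_lowest_adipose(self, calibration):
        t_star, s_star = calibration.intersection
        ta, sa = calibration.anchor_point
        assert t_star == pytest.approx(ta, abs=0.05)
        assert s_star == pytest.approx(sa, abs=0.05)

    def test_exact_two_segment_recovery(self):
        # synthetic points exactly on a two-segment line
        rng = np.random.default_rng(7)
        t_s = np.sort(rng.uniform(0.8, 2.5, 12))
        t_l = np.sort(rng.uniform(0.01, 0.8, 5))
        p1s, p2s, p1l = 0.4, 0.65, 1.2

        class FakeCat:
            def group_points(self, group):
                if group == "solid":
                    return t_s, p1s * t_s + p2s, []
                return t_l, p1l * t_l, []

            entries = {}

        c = fit_calibration(FakeCat())
        assert c.p1_solid == pytest.approx(p1s, abs=1e-12)
        assert c.p2_solid == pytest.approx(p2s, abs=1e-12)
        assert c.p1_low == pytest.approx(p1l, abs=1e-12)
        assert c.r2_solid == pytest.approx(1.0, abs=1e-12)

    def test_inverse_map_water_and_continuity(self, calibration):
        # water: solid-branch inverse of rstp = 1 lands near rscp = 1
        assert rscp_from_rstp(calibration, 1.0) == pytest.approx(1.0, abs=0.12)
        t_star, s_star = calibration.intersection
        assert rscp_from_rstp(calibration, s_star) == pytest.approx(t_star, rel=1e-9)
        # low branch is linear through the origin
        small = 0.1 * calibration.p1_low
        assert rscp_from_rstp(calibration, small) == pytest.approx(0.1, rel=1e-9)
        with pytest.raises(ValueError):
            rscp_from_rstp(calibration, -1.0)

    def test_forward_inverse_roundtrip(self, calibration):
        s = np.array([0.05, 0.3, 0.9, 1.2, 1.7])
        t = calibration.rscp_from_rstp(s)
        assert calibration.rstp_from_rscp(t) == pytest.approx(s, rel=1e-9)
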