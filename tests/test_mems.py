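"""Torsion-beam mechanics: shape factor, stiffness composition, Hooke's law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clotforce import (
    BeamGeometry,
    CalibrationSeries,
    Material,
    SensorChip,
    SuspensionDesign,
    beam_torsion_stiffness,
    beta_factor,
    design_report,
    displacement_from_force,
    effective_spring_constant,
    force_from_displacement,
    linearity_score,
    restoring_force_exact,
    solve_arm_length,
    torsional_constant,
)
from clotforce.errors import (
    DomainError,
    InsufficientDataError,
    InvalidDesignError,
    InvalidGeometryError,
    OverStrokeWarning,
    PlatformFitWarning,
)
from clotforce.mems import torsional_strain_energy, twist_state


def beta_series(aspect_ratio: float, terms: int = 60) -> float:
    """Classical infinite-series solution for rectangular-section torsion.

    J = a b^3 [1/3 - (64/pi^5)(b/a) sum_{n odd} tanh(n pi a / (2b)) / n^5],
    the brute-force oracle for the closed-form approximation.
    """
    s = sum(
        math.tanh((2 * k + 1) * math.pi * aspect_ratio / 2.0) / (2 * k + 1) ** 5
        for k in range(terms)
    )
    return 1.0 / 3.0 - (64.0 / math.pi**5) / aspect_ratio * s


class TestBetaFactor:
    def test_production_beam_value(self, paper_beam):
        assert beta_factor(paper_beam) == pytest.approx(0.291, abs=5e-4)

    def test_thin_plate_limit(self):
        geom = BeamGeometry(length_L=100.0, thickness_a=1e7, width_b=1.0)
        assert beta_factor(geom) == pytest.approx(1.0 / 3.0, rel=1e-6)

    def test_square_section_against_series(self):
        geom = BeamGeometry(length_L=100.0, thickness_a=10.0, width_b=10.0)
        assert beta_factor(geom) == pytest.approx(0.1406, abs=1e-3)
        assert beta_factor(geom) == pytest.approx(beta_series(1.0), rel=5e-3)

    @pytest.mark.parametrize("ratio", [1.0, 2.0, 5.0, 10.0])
    def test_matches_series_oracle(self, ratio):
        geom = BeamGeometry(length_L=100.0, thickness_a=10.0 * ratio, width_b=10.0)
        assert beta_factor(geom) == pytest.approx(beta_series(ratio), rel=5e-3)

    @given(
        r1=st.floats(min_value=1.0, max_value=100.0),
        r2=st.floats(min_value=1.0, max_value=100.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_bounded_and_monotone_in_aspect_ratio(self, r1, r2):
        b1 = beta_factor(BeamGeometry(1.0, 10.0 * r1, 10.0))
        b2 = beta_factor(BeamGeometry(1.0, 10.0 * r2, 10.0))
        assert 0.0 < b1 <= 1.0 / 3.0 + 1e-12
        if r1 < r2:
            assert b1 <= b2

    def test_invalid_dimension_rejected(self):
        with pytest.raises(InvalidGeometryError):
            BeamGeometry(length_L=680.0, thickness_a=0.0, width_b=10.0)
        with pytest.raises(InvalidGeometryError):
            BeamGeometry(length_L=-1.0, thickness_a=50.0, width_b=10.0)

    def test_sides_normalized_so_a_dominates(self):
        swapped = BeamGeometry(length_L=680.0, thickness_a=10.0, width_b=50.0)
        assert swapped.thickness_a == 50.0 and swapped.width_b == 10.0


class TestTorsionalConstant:
    def test_production_beam(self, paper_beam):
        # 0.291 * 50 um * (10 um)^3 = 1.455e-20 m^4
        assert torsional_constant(paper_beam) == pytest.approx(1.455e-20, rel=2e-3)

    def test_vanishing_width_limit(self):
        j = torsional_constant(BeamGeometry(680.0, 50.0, 1e-6))
        assert j < 1e-35

    def test_doubling_width_roughly_octuples(self):
        thin = BeamGeometry(680.0, 50.0, 10.0)
        wide = BeamGeometry(680.0, 50.0, 20.0)
        expected = beta_factor(wide) * 50e-6 * (20e-6) ** 3
        assert torsional_constant(wide) == pytest.approx(expected, rel=1e-12)
        ratio = torsional_constant(wide) / torsional_constant(thin)
        assert 6.0 < ratio < 9.0


class TestBeamStiffness:
    def test_production_beam(self, paper_beam, silicon):
        kappa = beam_torsion_stiffness(paper_beam, silicon)
        assert kappa == pytest.approx(1.089e-6, rel=2e-3)

    def test_linear_in_shear_modulus(self, paper_beam, silicon):
        doubled = Material(shear_modulus_G=2 * silicon.shear_modulus_G)
        assert beam_torsion_stiffness(paper_beam, doubled) == pytest.approx(
            2 * beam_torsion_stiffness(paper_beam, silicon), rel=1e-12
        )

    def test_inverse_in_length(self, paper_beam, silicon):
        longer = BeamGeometry(2 * paper_beam.length_L, 50.0, 10.0)
        assert beam_torsion_stiffness(longer, silicon) == pytest.approx(
            0.5 * beam_torsion_stiffness(paper_beam, silicon), rel=1e-12
        )

    def test_twist_state_obeys_angular_hookes_law(self, paper_beam, silicon):
        kappa = beam_torsion_stiffness(paper_beam, silicon)
        state = twist_state(paper_beam, silicon, 0.05)
        assert state.torque_tau == pytest.approx(kappa * 0.05, rel=1e-12)


class TestSuspension:
    def test_production_design_near_100_N_per_m(self, paper_beam, silicon):
        design = SuspensionDesign(beam=paper_beam, material=silicon, arm_length_C=417.4)
        assert effective_spring_constant(design) == pytest.approx(100.0, rel=5e-3)

    def test_quarter_on_doubled_arm(self, paper_design):
        from dataclasses import replace

        doubled = replace(paper_design, arm_length_C=2 * paper_design.arm_length_C)
        assert effective_spring_constant(doubled) == pytest.approx(
            effective_spring_constant(paper_design) / 4.0, rel=1e-12
        )

    def test_halves_with_half_the_beams(self, paper_design):
        from dataclasses import replace

        half = replace(paper_design, beams_total=8, arms=2)
        assert effective_spring_constant(half) == pytest.approx(
            effective_spring_constant(paper_design) / 2.0, rel=1e-12
        )

    def test_beam_count_must_match_arms(self, paper_beam, silicon):
        with pytest.raises(InvalidDesignError):
            SuspensionDesign(beam=paper_beam, material=silicon, arm_length_C=400.0,
                             beams_total=10, arms=4)

    def test_arm_must_fit_platform(self, paper_beam, silicon):
        with pytest.raises(InvalidDesignError):
            SuspensionDesign(beam=paper_beam, material=silicon, arm_length_C=2500.0)

    def test_energy_method_equivalence(self, paper_design):
        """k agrees with the curvature of the torsional strain energy."""
        k = effective_spring_constant(paper_design)
        x, h = 1.0, 0.01  # um
        u = lambda z: torsional_strain_energy(paper_design, z)
        k_num = (u(x + h) - 2 * u(x) + u(x - h)) / (h * 1e-6) ** 2
        assert k_num == pytest.approx(k, rel=1e-6)

    def test_exact_kinematics_converges_to_linear_law(self, paper_design):
        k = effective_spring_constant(paper_design)
        x = 0.01 * paper_design.arm_length_C  # x/C = 0.01
        exact = restoring_force_exact(paper_design, x)
        assert abs(exact - k * x) / (k * x) < 1e-4


class TestSolveArmLength:
    def test_round_trip_to_target(self, paper_beam, silicon):
        sol = solve_arm_length(paper_beam, silicon, k_target=100.0)
        assert sol.arm_length_um == pytest.approx(417.0, rel=5e-3)
        design = SuspensionDesign(beam=paper_beam, material=silicon,
                                  arm_length_C=sol.arm_length_um)
        assert effective_spring_constant(design) == pytest.approx(100.0, rel=1e-9)

    def test_soft_chip_still_fits_platform(self, paper_beam, silicon):
        sol = solve_arm_length(paper_beam, silicon, k_target=5.0)
        assert sol.arm_length_um == pytest.approx(1867.0, rel=1e-2)
        assert sol.fits_platform

    def test_stiff_target_shrinks_arm(self, paper_beam, silicon):
        assert solve_arm_length(paper_beam, silicon, 1e9).arm_length_um < 0.2

    def test_oversized_solution_flagged(self, paper_beam, silicon):
        with pytest.warns(PlatformFitWarning):
            sol = solve_arm_length(paper_beam, silicon, k_target=1.0)
        assert not sol.fits_platform

    def test_nonpositive_target_rejected(self, paper_beam, silicon):
        with pytest.raises(DomainError):
            solve_arm_length(paper_beam, silicon, k_target=0.0)


class TestHookesLaw:
    def test_design_point(self, chip100):
        assert force_from_displacement(chip100, 100.0) == pytest.approx(10000.0)

    def test_zero_displacement(self, chip100):
        assert force_from_displacement(chip100, 0.0) == 0.0

    def test_stiff_chip(self):
        chip = SensorChip(spring_constant_k=300.0)
        assert force_from_displacement(chip, 10.0) == pytest.approx(3000.0)

    def test_negative_displacement_rejected(self, chip100):
        with pytest.raises(DomainError):
            force_from_displacement(chip100, -1.0)

    def test_over_stroke_warns_but_computes(self, chip100):
        with pytest.warns(OverStrokeWarning):
            assert force_from_displacement(chip100, 120.0) == pytest.approx(12000.0)

    @given(
        k=st.floats(min_value=1.0, max_value=1000.0),
        x=st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_displacement_force_round_trip(self, k, x):
        chip = SensorChip(spring_constant_k=k, max_stroke=100.0)
        back = displacement_from_force(chip, force_from_displacement(chip, x))
        assert back == pytest.approx(x, rel=1e-12, abs=1e-12)


class TestLinearityScore:
    def test_exact_series_scores_100(self, chip100):
        x = np.linspace(0, 100, 11)
        cal = CalibrationSeries(deflections=x, forces=100.0 * x)
        assert linearity_score(cal) == pytest.approx(100.0, abs=1e-9)

    def test_constant_force_scores_0(self):
        cal = CalibrationSeries(deflections=np.linspace(0, 100, 11),
                                forces=np.full(11, 5000.0))
        assert linearity_score(cal) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            CalibrationSeries(deflections=np.array([0.0, 1.0]), forces=np.array([0.0, 1.0]))

    def test_non_monotone_deflections_rejected(self):
        with pytest.raises(InvalidDesignError):
            CalibrationSeries(deflections=np.array([0.0, 2.0, 1.0]),
                              forces=np.array([0.0, 1.0, 2.0]))

    def test_default_noise_lands_in_reported_band(self, chip100):
        """Simulated nanoindenter sweeps score >= 96% (5th percentile, 200 seeds)."""
        from clotforce import generate_calibration_series

        scores = [
            linearity_score(generate_calibration_series(chip100, n_points=50, seed=s))
            for s in range(200)
        ]
        assert np.percentile(scores, 5) >= 96.0
        assert np.mean(scores) <= 99.5

    def test_max_residual_metric_perfect_line(self):
        x = np.linspace(0, 100, 11)
        cal = CalibrationSeries(deflections=x, forces=100.0 * x)
        assert linearity_score(cal, metric="max_residual") == pytest.approx(100.0, abs=1e-9)


def test_design_report_echoes_geometry(paper_design):
    report = design_report(paper_design)
    assert report["beam"]["length_L_um"] == 680.0
    assert report["derived"]["beta_factor"] == pytest.approx(0.291, abs=5e-4)
    assert report["derived"]["spring_constant_k_N_per_m"] == pytest.approx(100.0, rel=1e-6)
    assert report["derived"]["full_scale_force_uN"] == pytest.approx(10000.0, rel=1e-6)
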