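"""Scenario experiments: sensitivity statistics, slopes, calibration."""

import dataclasses

import numpy as np
import pytest

from mabrsim import (
    DEFAULT_MATRIX_TARGETS,
    KineticParameterSet,
    Scenario,
    SolverOptions,
    TemperatureRuleSet,
    calibrate_to_matrix,
    diffusivity_sensitivity,
    evaluate_rate_at_bulk,
    limiting_rate_slope,
    run_simulation_matrix,
    scenario_steady_state,
    temperature_sensitivity,
)
from mabrsim.exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedFractionError,
)
from mabrsim import experiments as E


class TestTemperatureSensitivity:
    def test_equal_rates_zero(self):
        assert temperature_sensitivity(3.0, 3.0, 30.0, 8.0) == 0.0

    @pytest.mark.parametrize(
        "hi, lo, expected",
        [
            (5.95, 1.82, 10.314685314685313),
            (4.69, 2.80, 3.0681818181818197),
        ],
    )
    def test_matrix_cell_arithmetic(self, hi, lo, expected):
        assert temperature_sensitivity(hi, lo, 30.0, 8.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_invariant_under_uniform_rescaling(self):
        base = temperature_sensitivity(5.0, 2.0, 30.0, 8.0)
        scaled = temperature_sensitivity(5.0 * 7.3, 2.0 * 7.3, 30.0, 8.0)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            temperature_sensitivity(1.0, 0.0, 30.0, 8.0)
        with pytest.raises(UndefinedFractionError):
            temperature_sensitivity(1.0, 1.0, 20.0, 20.0)


class TestScenario:
    def test_matrix_membership(self):
        temps = {k[0] for k in DEFAULT_MATRIX_TARGETS}
        lfs = {k[1] for k in DEFAULT_MATRIX_TARGETS}
        lbls = {k[2] for k in DEFAULT_MATRIX_TARGETS}
        assert temps == {8.0, 30.0}
        assert lfs == {50e-6, 150e-6}
        assert lbls == {50e-6, 250e-6}
        assert len(DEFAULT_MATRIX_TARGETS) == 8

    def test_zero_bulk_zero_rate(self, kin, rules, coarse_options):
        sc = Scenario(20.0, 50e-6, 50e-6)
        base = scenario_steady_state(sc, kin, rules, coarse_options)
        rate0 = evaluate_rate_at_bulk(
            sc, 0.0, kin, rules, coarse_options, base_result=base
        )
        assert abs(rate0) < 0.01


class TestLimitingSlope:
    def test_exact_linear_rate_recovered(self, kin, rules, monkeypatch):
        """The OLS fitter recovers the coefficient of an exactly linear
        rate-vs-concentration law."""
        k_true = 0.62

        def fake_rate(base, scenario, c, *args, **kwargs):
            return k_true * c

        monkeypatch.setattr(E, "_rate_with_frozen_biomass", fake_rate)
        slope = limiting_rate_slope(
            Scenario(20.0, 50e-6, 250e-6), kin, rules, SolverOptions(n_nodes=40),
            base_result=object(),
        )
        assert slope == pytest.approx(k_true, rel=1e-12)

    def test_degenerate_grid_rejected(self, kin, rules):
        with pytest.raises(InsufficientDataError):
            limiting_rate_slope(
                Scenario(20.0, 50e-6, 250e-6), kin, rules,
                grid=[0.5, 0.5, 0.5, 0.5], base_result=object(),
            )

    def test_film_controlled_toy_matches_film_theory(self, rules):
        """With very fast kinetics the limiting-range slope approaches the
        boundary-layer film conductance D_w / L_LBL (planar geometry)."""
        hot = KineticParameterSet(
            mu_max_AOO=8.0, mu_max_NOO=0.699, rho_X=150000.0, K_NH4=0.05
        )
        sc = Scenario(20.0, 100e-6, 250e-6, mode="planar")
        opts = SolverOptions(n_nodes=60)
        slope = limiting_rate_slope(sc, hot, rules, opts)
        from mabrsim.params import water_diffusivity

        film = water_diffusivity(rules.D_ref["NH4"], 20.0) / 250e-6
        assert slope == pytest.approx(film, rel=0.1)

    def test_slope_decreases_with_thicker_boundary_layer(
        self, kin, rules, coarse_options
    ):
        s_thin = limiting_rate_slope(
            Scenario(20.0, 50e-6, 50e-6), kin, rules, coarse_options
        )
        s_thick = limiting_rate_slope(
            Scenario(20.0, 50e-6, 250e-6), kin, rules, coarse_options
        )
        assert 0 < s_thick < s_thin


class TestDiffusivitySensitivity:
    def test_kinetically_limited_toy_is_insensitive(self, rules):
        """A sparse, slow biofilm is rate-limited by kinetics: the response
        barely depends on the diffusion coefficients."""
        lazy = KineticParameterSet(mu_max_AOO=0.15, mu_max_NOO=0.1, rho_X=20000.0)
        res = diffusivity_sensitivity(
            Scenario(20.0, 50e-6, 50e-6, mode="planar"), lazy, rules,
            target="D_NH4", response="rate_at_35",
            options=SolverOptions(n_nodes=40), re_equilibrate=False,
        )
        assert abs(res.sensitivity) < 0.05
        assert res.regime == "low"

    def test_film_limited_toy_sensitivity_one(self, rules):
        """When the LBL film controls the flux, the response is linear in
        the aqueous diffusivity: relative sensitivity = 1."""
        hot = KineticParameterSet(
            mu_max_AOO=8.0, mu_max_NOO=0.699, rho_X=150000.0, K_NH4=0.05
        )
        res = diffusivity_sensitivity(
            Scenario(20.0, 100e-6, 250e-6, mode="planar"), hot, rules,
            target="D_NH4", response="limiting_slope",
            options=SolverOptions(n_nodes=60), re_equilibrate=False,
        )
        assert res.sensitivity == pytest.approx(1.0, abs=0.1)
        assert res.regime == "high"

    def test_series_resistance_bounds(self, kin, rules, coarse_options):
        """For a flux through series resistances the relative sensitivity to
        one diffusivity lies in [0, 1]."""
        res = diffusivity_sensitivity(
            Scenario(8.0, 50e-6, 250e-6), kin, rules,
            target="D_NH4", response="limiting_slope",
            options=coarse_options, re_equilibrate=False,
        )
        assert -0.05 <= res.sensitivity <= 1.05

    def test_invalid_arguments(self, kin, rules):
        with pytest.raises(InvalidParameterError):
            diffusivity_sensitivity(
                Scenario(8.0, 50e-6, 50e-6), kin, rules, target="D_NO3"
            )
        with pytest.raises(InvalidParameterError):
            diffusivity_sensitivity(
                Scenario(8.0, 50e-6, 50e-6), kin, rules, perturbation=1.5
            )


class TestSimulationMatrix:
    def test_reduced_matrix_structure_and_ordering(self, kin, rules, coarse_options):
        res = run_simulation_matrix(
            kin, rules, coarse_options,
            temperatures=(8.0, 30.0), thicknesses=(50e-6,),
            lbl_thicknesses=(50e-6,),
        )
        assert len(res.rates) == 2
        assert len(res.sensitivity) == 1
        r8 = float(res.rates[res.rates.temperature == 8.0].rate_at_35.iloc[0])
        r30 = float(res.rates[res.rates.temperature == 30.0].rate_at_35.iloc[0])
        assert r30 > r8
        assert float(res.sensitivity.pct_per_degC_rate35.iloc[0]) > 0


class TestCalibration:
    def test_empty_free_set_passes_through(self, kin, rules, coarse_options):
        targets = {
            (8.0, 50e-6, 50e-6): 1.82,
            (30.0, 50e-6, 50e-6): 5.95,
        }
        kin2, rules2, report = calibrate_to_matrix(
            targets=targets, free_params=(), kin=kin, rules=rules,
            options=coarse_options,
        )
        assert kin2 == kin and rules2 == rules
        assert len(report) == 2
        assert np.isfinite(report.relative_error).all()

    def test_self_consistency_parameter_recovery(self, rules):
        """Targets generated by the model itself are matched by recovering
        the generating growth rate within 5 %."""
        opts = SolverOptions(n_nodes=50)
        true_kin = KineticParameterSet()
        cells = [(8.0, 50e-6, 50e-6), (30.0, 150e-6, 50e-6)]
        targets = {
            c: scenario_steady_state(Scenario(*c), true_kin, rules, opts).removal_rate
            for c in cells
        }
        start = dataclasses.replace(true_kin, mu_max_AOO=true_kin.mu_max_AOO * 1.35)
        kin_fit, _, report = calibrate_to_matrix(
            targets=targets, free_params=("mu_max_AOO",), kin=start,
            rules=rules, options=opts,
        )
        assert kin_fit.mu_max_AOO == pytest.approx(true_kin.mu_max_AOO, rel=0.05)
        assert report.relative_error.abs().max() < 0.05

    def test_unknown_free_parameter_rejected(self, kin, rules):
        with pytest.raises(InvalidParameterError):
            calibrate_to_matrix(free_params=("K_NH4",), kin=kin, rules=rules)
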