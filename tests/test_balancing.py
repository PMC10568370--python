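import numpy as np
import pytest

from fbarebalance import (
    AdjustmentConfig,
    BalancingError,
    Measurement,
    MeasurementSet,
    ToyModelParams,
    apply_result,
    balance,
    build_problem,
    default_flux_weights,
    extract_biomass_spec,
    make_random_network,
    make_toy_model,
    ov_range,
    recover_biomass_perturbation,
    simulate_measurements,
    solve_problem,
)
from fbarebalance.solvers import fba_optimum
from helpers import glpk_lp_oracle, relative_perturbation, slsqp_qp_oracle


class TestFluxWeights:
    def test_sd_reciprocal(self):
        ms = MeasurementSet({"mu": Measurement(0.46, sd=0.02)})
        weights, hard = default_flux_weights(ms, "sd_reciprocal", 1.0)
        assert weights["mu"] == pytest.approx(50.0)
        assert not hard

    def test_zero_sd_is_hard_fixed(self):
        ms = MeasurementSet(
            {"lac": Measurement(0.0, sd=0.0), "glc": Measurement(16.69, sd=0.24)}
        )
        weights, hard = default_flux_weights(ms, "sd_reciprocal", 1.0)
        assert hard == {"lac"}
        assert "lac" not in weights

    def test_relative_with_scale(self):
        ms = MeasurementSet({"glc": Measurement(13.48, sd=0.04)})
        weights, _ = default_flux_weights(ms, "relative", 0.01)
        assert weights["glc"] == pytest.approx(100.0 / 13.48)

    def test_missing_sd_falls_back_to_relative(self):
        ms = MeasurementSet({"nh4": Measurement(6.52, sd=None)})
        with pytest.warns(UserWarning, match="no standard deviation"):
            weights, hard = default_flux_weights(ms, "sd_reciprocal", 1.0)
        assert weights["nh4"] == pytest.approx(1.0 / 6.52)

    def test_custom_mapping(self):
        ms = MeasurementSet({"a": Measurement(1.0), "b": Measurement(2.0)})
        weights, hard = default_flux_weights(ms, {"a": 3.0, "b": float("inf")})
        assert weights == {"a": 3.0}
        assert hard == {"b"}


class TestChainClosedForm:
    """min w_A d_A^2 + w_B d_B^2 s.t. d_A - d_B = 1 has the KKT solution
    d_A = w_B/(w_A+w_B), d_B = -w_A/(w_A+w_B)."""

    def test_qp_splits_evenly(self, chain_model, chain_measurements):
        res = balance(chain_model, chain_measurements, AdjustmentConfig("qp"))
        assert res.optimal
        assert res.objective_value == pytest.approx(0.5, abs=1e-9)
        assert res.measurements["rA"].delta == pytest.approx(0.5, abs=1e-7)
        assert res.measurements["rB"].delta == pytest.approx(-0.5, abs=1e-7)

    def test_qp_kkt_ratio_with_unequal_weights(self, chain_model):
        ms = MeasurementSet(
            {"rA": Measurement(2.0, sd=1.0), "rB": Measurement(1.0, sd=0.25)}
        )
        # w_A = 1, w_B = 4 -> d_A = 4/5, d_B = -1/5, OV = 1*(0.8)^2+4*(0.2)^2
        res = balance(chain_model, ms, AdjustmentConfig("qp"))
        assert res.measurements["rA"].delta == pytest.approx(0.8, abs=1e-7)
        assert res.measurements["rB"].delta == pytest.approx(-0.2, abs=1e-7)
        assert res.objective_value == pytest.approx(0.8, abs=1e-8)

    def test_lp_total_correction(self, chain_model, chain_measurements):
        res = balance(chain_model, chain_measurements, AdjustmentConfig("lp"))
        assert res.objective_value == pytest.approx(1.0, abs=1e-9)

    def test_feasible_measurements_need_no_correction(self, chain_model):
        ms = MeasurementSet(
            {"rA": Measurement(2.0, sd=1.0), "rB": Measurement(2.0, sd=1.0)}
        )
        for mode in ("qp", "lp"):
            res = balance(chain_model, ms, AdjustmentConfig(mode))
            assert res.objective_value == pytest.approx(0.0, abs=1e-9)
            assert res.measurements["rA"].adjusted == pytest.approx(2.0)


class TestProblemConstruction:
    def test_delta_variables_skip_hard_entries(self, chain_model):
        ms = MeasurementSet(
            {"rA": Measurement(2.0, sd=1.0), "rB": Measurement(2.0, sd=0.0)}
        )
        problem = build_problem(chain_model, ms, config=AdjustmentConfig("qp"))
        assert set(problem.delta_vars) == {"rA"}
        assert problem.hard_fixed == {"rB"}

    def test_biomass_adjustment_requires_fixed_growth(self, toy_model):
        ms = MeasurementSet({"EX_glc__D": Measurement(-9.0, sd=0.1)})
        with pytest.raises(BalancingError, match="bilinear"):
            build_problem(
                toy_model, ms,
                config=AdjustmentConfig("qp", adjust_biomass=True),
            )

    def test_growth_is_hard_fixed_under_biomass_adjustment(self, toy_model):
        ms = MeasurementSet(
            {
                "EX_glc__D": Measurement(-9.0, sd=0.1),
                "BIOMASS": Measurement(1.0, sd=0.02),
            }
        )
        problem = build_problem(
            toy_model, ms, config=AdjustmentConfig("qp", adjust_biomass=True)
        )
        assert "BIOMASS" in problem.hard_fixed
        assert "BIOMASS" not in problem.delta_vars
        # pure GAM carriers are not adjustable components
        assert not set(problem.gam.gam_metabolite_ids) & set(problem.beta_vars)

    def test_beta_bounds_follow_max_rel_beta(self, toy_model):
        ms = MeasurementSet({"BIOMASS": Measurement(1.0, sd=0.02)})
        config = AdjustmentConfig(
            "qp", adjust_fluxes=False, adjust_biomass=True, max_rel_beta=0.3
        )
        problem = build_problem(toy_model, ms, config=config)
        for met_id, cols in problem.beta_vars.items():
            limit = 0.3 * abs(problem.c_ref[met_id])
            assert problem.ub[cols[0]] == pytest.approx(limit)


class TestPerturbationRecovery:
    def test_beta_equals_minus_delta(self):
        model = make_toy_model(ToyModelParams(seed=11))
        sol = fba_optimum(model)
        r_star = {
            r.id: float(sol.x[j]) for j, r in enumerate(model.reactions)
        }
        perturbed, expected = relative_perturbation(model, rho=0.2)
        res = recover_biomass_perturbation(perturbed, r_star)
        assert res.optimal
        for met_id, beta in expected.items():
            assert res.components[met_id].beta == pytest.approx(
                beta, abs=1e-8
            )

    def test_unperturbed_model_needs_no_beta(self, toy_model):
        sol = fba_optimum(toy_model)
        r_star = {
            r.id: float(sol.x[j]) for j, r in enumerate(toy_model.reactions)
        }
        res = recover_biomass_perturbation(toy_model, r_star)
        assert res.objective_value == pytest.approx(0.0, abs=1e-12)
        assert all(
            adj.beta == pytest.approx(0.0, abs=1e-9)
            for adj in res.components.values()
        )

    def test_incomplete_flux_vector_rejected(self, toy_model):
        with pytest.raises(BalancingError, match="every reaction"):
            recover_biomass_perturbation(toy_model, {"BIOMASS": 1.0})


class TestApplyResult:
    def test_zero_corrections_leave_model_unchanged(self, toy_model):
        ms = simulate_measurements(toy_model)
        res = balance(
            toy_model, ms,
            AdjustmentConfig("qp", adjust_biomass=True, adjust_gam=True),
        )
        applied = apply_result(toy_model, res)
        assert applied.biomass_reaction.stoichiometry == pytest.approx(
            toy_model.biomass_reaction.stoichiometry, abs=1e-7
        )

    def test_adjusted_gam_round_trips(self, toy_model):
        # measurements generated with a weaker GAM force beta_GAM < 0
        weak = make_toy_model(ToyModelParams(seed=0, gam=6.0))
        ms = simulate_measurements(weak)
        res = balance(
            toy_model, ms,
            AdjustmentConfig("qp", adjust_fluxes=False, adjust_gam=True),
        )
        assert res.optimal
        applied = apply_result(toy_model, res)
        _, gam2 = extract_biomass_spec(applied)
        assert gam2.g == pytest.approx(res.gam_adjusted, rel=1e-9)
        assert gam2.g == pytest.approx(6.0, rel=1e-6)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_lp_matches_glpk(self, seed):
        model, measurements = make_random_network(seed)
        problem = build_problem(
            model, measurements, config=AdjustmentConfig("lp")
        )
        res = solve_problem(problem)
        assert res.optimal
        oracle = glpk_lp_oracle(problem)
        assert res.objective_value == pytest.approx(
            oracle, rel=1e-6, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_qp_matches_multistart_slsqp(self, seed):
        model, measurements = make_random_network(seed)
        problem = build_problem(
            model, measurements, config=AdjustmentConfig("qp")
        )
        res = solve_problem(problem)
        assert res.optimal
        oracle = slsqp_qp_oracle(problem, seed=seed)
        rel = abs(res.objective_value - oracle) / max(1.0, abs(oracle))
        assert rel < 1e-4


class TestLpDegeneracy:
    def test_ov_range_brackets_alternate_optima(
        self, chain_model, chain_measurements
    ):
        problem = build_problem(
            chain_model, chain_measurements, config=AdjustmentConfig("lp")
        )
        res = solve_problem(problem)
        # at OV = 1 the correction can fall anywhere between the two
        # measurements: adjusted r_A ranges over [1, 2]
        lo, hi = ov_range(problem, res, {"rA": 1.0})
        assert lo == pytest.approx(1.0, abs=1e-6)
        assert hi == pytest.approx(2.0, abs=1e-6)

    def test_post_pass_rejects_qp(self, chain_model, chain_measurements):
        problem = build_problem(
            chain_model, chain_measurements, config=AdjustmentConfig("qp")
        )
        res = solve_problem(problem)
        with pytest.raises(BalancingError, match="LP"):
            ov_range(problem, res, {"rA": 1.0})


class TestResultInvariants:
    @pytest.mark.parametrize("mode", ["qp", "lp"])
    def test_steady_state_and_mass_conservation_hold(self, mode):
        model = make_toy_model(ToyModelParams(seed=21))
        sd = {
            "EX_glc__D": 0.2, "EX_o2": 0.3, "EX_co2": 0.3, "EX_h2o": 0.3,
            "BIOMASS": 0.02,
        }
        ms = simulate_measurements(model, sd_profile=sd, noise_seed=4)
        config = AdjustmentConfig(
            mode, adjust_biomass=True, adjust_gam=True, max_rel_beta=0.3
        )
        problem = build_problem(model, ms, config=config)
        res = solve_problem(problem)
        assert res.optimal
        spec, _ = extract_biomass_spec(model)
        assert res.mass_conservation_residual(spec) < 1e-8
        # bound respect
        for met_id, adj in res.components.items():
            assert abs(adj.beta) <= 0.3 * abs(adj.coefficient) + 1e-9
        assert abs(res.beta_gam) <= 1.0 + 1e-12
        # steady state of the applied model at the adjusted fluxes
        applied = apply_result(model, res)
        N = applied.stoichiometric_matrix()
        r = np.array([res.fluxes[rx.id] for rx in applied.reactions])
        assert np.max(np.abs(N @ r)) < 1e-6
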