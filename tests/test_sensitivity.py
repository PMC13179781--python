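"""One-way scans, beta/gamma fitting, PSA reproducibility and CEAC shape."""

import numpy as np
import pytest
from scipy import stats

from sdf_cea.economics import run_base_case
from sdf_cea.parameters import DistributionSpec, ParameterError, Strategy, get_value
from sdf_cea.sensitivity import (
    CeacCurve,
    FitError,
    PsaResult,
    ceac,
    ceac_crossover,
    draw_psa,
    fit_beta,
    fit_gamma,
    one_way,
    one_way_table,
    run_psa,
)


class TestOneWay:
    def test_base_value_reproduces_base_icer(self, default_params):
        base = run_base_case(default_params).icer
        res = one_way(default_params, "costs.c_sdf", [default_params.costs.c_sdf.base])
        assert res.icers[0] == pytest.approx(base, rel=1e-12)
        assert res.base_icer == pytest.approx(base)

    def test_sdf_cost_scan_monotone_increasing(self, default_params):
        res = one_way(default_params, "costs.c_sdf", [31.0, 39.0, 47.0])
        assert np.all(np.diff(res.icers) > 0)

    def test_naf_cost_scan_monotone_decreasing(self, default_params):
        """Raising the comparator's cost offsets the incremental cost."""
        res = one_way(default_params, "costs.c_naf", [27.0, 33.0, 39.0])
        assert np.all(np.diff(res.icers) < 0)

    def test_unknown_parameter_rejected(self, default_params):
        with pytest.raises(ParameterError):
            one_way(default_params, "costs.c_implant", [10.0])

    def test_table_covers_five_parameters_three_points(self, default_params):
        table = one_way_table(default_params)
        assert len(table) == 15
        assert table["parameter"].nunique() == 5
        assert np.isfinite(table["icer"]).all()

    def test_scan_leaves_params_untouched(self, default_params):
        before = default_params.model_dump()
        one_way(default_params, "costs.c_exam", [27.0, 45.0])
        assert default_params.model_dump() == before


class TestDistributionFitting:
    def test_beta_symmetric_ci_gives_equal_shapes(self):
        lo, hi = stats.beta.ppf([0.025, 0.975], 40.0, 40.0)
        spec = DistributionSpec(family="beta", mean=0.5, ci95=(float(lo), float(hi)))
        a, b = fit_beta(spec)
        assert a == pytest.approx(b, rel=1e-3)

    @pytest.mark.parametrize("mean,kappa", [(0.3, 50.0), (0.68, 120.0), (0.05, 200.0)])
    def test_beta_quantile_round_trip(self, mean, kappa):
        a0, b0 = mean * kappa, (1 - mean) * kappa
        lo, hi = stats.beta.ppf([0.025, 0.975], a0, b0)
        spec = DistributionSpec(family="beta", mean=mean, ci95=(float(lo), float(hi)))
        a, b = fit_beta(spec)
        qlo, qhi = stats.beta.ppf([0.025, 0.975], a, b)
        assert abs(qlo - lo) < 1e-3 and abs(qhi - hi) < 1e-3
        assert a / (a + b) == pytest.approx(mean, abs=1e-9)

    @pytest.mark.parametrize("mean,shape", [(39.0, 91.0), (129.0, 50.0), (5.0, 4.0)])
    def test_gamma_quantile_round_trip(self, mean, shape):
        lo, hi = stats.gamma.ppf([0.025, 0.975], shape, scale=mean / shape)
        spec = DistributionSpec(family="gamma", mean=mean, ci95=(float(lo), float(hi)))
        k, theta = fit_gamma(spec)
        qlo, qhi = stats.gamma.ppf([0.025, 0.975], k, scale=theta)
        tol = 1e-3 * max(1.0, mean)
        assert abs(qlo - lo) < tol and abs(qhi - hi) < tol
        assert k * theta == pytest.approx(mean, rel=1e-9)

    def test_gamma_fixed_point_recovers_parameters(self):
        k0, theta0 = 30.0, 2.0
        lo, hi = stats.gamma.ppf([0.025, 0.975], k0, scale=theta0)
        spec = DistributionSpec(family="gamma", mean=k0 * theta0, ci95=(float(lo), float(hi)))
        k, theta = fit_gamma(spec)
        assert k == pytest.approx(k0, rel=1e-3)
        assert theta == pytest.approx(theta0, rel=1e-3)

    def test_degenerate_ci_rejected_at_spec_construction(self):
        with pytest.raises(ValueError):
            DistributionSpec(family="beta", mean=0.5, ci95=(0.4, 0.4))

    def test_infeasible_asymmetry_raises_fit_error(self):
        # mean far outside what the requested interval allows
        spec = DistributionSpec(family="beta", mean=0.9, ci95=(0.05, 0.2))
        with pytest.raises(FitError):
            fit_beta(spec)

    def test_wrong_family_rejected(self):
        spec = DistributionSpec(family="gamma", mean=10.0, ci95=(5.0, 18.0))
        with pytest.raises(FitError):
            fit_beta(spec)


class TestPsaDraws:
    def test_same_seed_identical_draws(self, default_params):
        a = draw_psa(default_params, 5, seed=3)
        b = draw_psa(default_params, 5, seed=3)
        assert [p.model_dump() for p in a] == [p.model_dump() for p in b]

    def test_draws_are_valid_parameter_sets(self, default_params):
        for p in draw_psa(default_params, 50, seed=1):
            assert p.transition.naf.p_arrest == 0.0  # structural constraint survives

    def test_unspecced_parameters_held_at_base(self, default_params):
        specless = [n for n in ("transition.naf.p_arrest",)]
        for p in draw_psa(default_params, 5, seed=0):
            for name in specless:
                assert get_value(p, name) == get_value(default_params, name)

    def test_empirical_means_match_spec_means(self, generated_params):
        """Law of large numbers: 10 000 draws per parameter reproduce each
        spec mean within 3 standard errors."""
        n = 10_000
        draws = draw_psa(generated_params, n, seed=5)
        for name, spec in generated_params.psa_specs.items():
            values = np.array([get_value(p, name) for p in draws])
            se = values.std(ddof=1) / np.sqrt(n)
            assert abs(values.mean() - spec.mean) < 3 * se, name

    def test_no_specs_rejected(self, simple_params):
        with pytest.raises(ParameterError):
            draw_psa(simple_params, 1, seed=0)

    def test_substreams_stable_under_spec_removal(self, default_params):
        """Dropping one parameter's spec leaves the other parameters' draw
        sequences untouched."""
        full = draw_psa(default_params, 4, seed=9)
        reduced_params = default_params.model_copy(
            update={
                "psa_specs": {
                    k: v for k, v in default_params.psa_specs.items() if k != "costs.c_xray"
                }
            }
        )
        reduced = draw_psa(reduced_params, 4, seed=9)
        for pf, pr in zip(full, reduced):
            assert get_value(pf, "costs.c_sdf") == get_value(pr, "costs.c_sdf")
            assert (
                pf.transition.sdf.p_arrest == pr.transition.sdf.p_arrest
            )


@pytest.fixture(scope="module")
def psa(default_params):
    return run_psa(draw_psa(default_params, 200, seed=17), seed=17)


class TestPsaAndCeac:
    def test_costs_and_effects_nonnegative(self, psa):
        for s in Strategy:
            assert np.all(psa.costs[s] >= 0) and np.all(psa.effects[s] >= 0)

    def test_statelessness_under_concatenation(self, default_params):
        draws = draw_psa(default_params, 6, seed=2)
        once = run_psa(draws)
        twice = run_psa(list(draws) + list(draws))
        for s in Strategy:
            assert np.array_equal(twice.costs[s][:6], once.costs[s])
            assert np.array_equal(twice.costs[s][6:], once.costs[s])

    def test_degenerate_draws_reproduce_base_case(self, default_params):
        base_only = [default_params.model_copy(update={"psa_specs": {}})] * 3
        res = run_psa(base_only)
        bc = run_base_case(default_params)
        assert np.allclose(res.costs[Strategy.SDF], bc.b.discounted_cost)
        assert np.allclose(res.effects[Strategy.NAF], bc.a.discounted_effect)

    def test_ceac_partition_and_monotonicity(self, psa):
        grid = np.arange(0.0, 5001.0, 100.0)
        curve = ceac(psa, grid)
        p_sdf = curve.probability[Strategy.SDF]
        p_naf = curve.probability[Strategy.NAF]
        assert np.allclose(p_sdf + p_naf, 1.0)
        assert np.all((p_sdf >= 0) & (p_sdf <= 1))
        # SDF has the higher mean effect: acceptability non-decreasing in WTP
        assert np.all(np.diff(p_sdf) >= -1e-12)

    def test_ceac_at_zero_wtp_rewards_lower_cost(self, psa):
        curve = ceac(psa, [0.0])
        frac_sdf_cheaper = float(
            np.mean(psa.costs[Strategy.SDF] < psa.costs[Strategy.NAF])
        )
        assert curve.probability[Strategy.SDF][0] == pytest.approx(frac_sdf_cheaper)

    def test_single_draw_step_function_jumps_at_icer(self):
        costs = {Strategy.NAF: np.array([100.0]), Strategy.SDF: np.array([300.0])}
        effects = {Strategy.NAF: np.array([1.0]), Strategy.SDF: np.array([3.0])}
        psa1 = PsaResult(costs=costs, effects=effects, n_draws=1)
        icer = 100.0  # (300-100)/(3-1)
        curve = ceac(psa1, np.arange(0.0, 201.0, 1.0))
        assert ceac_crossover(curve) == pytest.approx(icer, abs=1.0)
        assert curve.probability[Strategy.SDF][0] == 0.0
        assert curve.probability[Strategy.SDF][-1] == 1.0

    def test_crossover_at_grid_minimum_when_always_accepted(self):
        costs = {Strategy.NAF: np.array([100.0]), Strategy.SDF: np.array([50.0])}
        effects = {Strategy.NAF: np.array([1.0]), Strategy.SDF: np.array([3.0])}
        curve = ceac(PsaResult(costs=costs, effects=effects, n_draws=1), [0.0, 10.0])
        assert ceac_crossover(curve) == 0.0

    def test_no_crossing_returns_none(self):
        costs = {Strategy.NAF: np.array([10.0]), Strategy.SDF: np.array([500.0])}
        effects = {Strategy.NAF: np.array([1.0]), Strategy.SDF: np.array([1.1])}
        curve = ceac(PsaResult(costs=costs, effects=effects, n_draws=1), [0.0, 10.0])
        assert ceac_crossover(curve) is None

    def test_empty_grid_rejected(self, psa):
        with pytest.raises(ParameterError):
            ceac(psa, [])

    def test_crossover_consistent_with_deterministic_icer(self, default_params):
        """Under mean-preserving parameter uncertainty the CEAC's 50%
        crossover sits within a few percent of the base-case ICER."""
        psa = run_psa(draw_psa(default_params, 500, seed=29))
        curve = ceac(psa, np.arange(0.0, 5001.0, 25.0))
        crossover = ceac_crossover(curve)
        icer = run_base_case(default_params).icer
        assert crossover is not None
        assert abs(crossover - icer) / icer < 0.10
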