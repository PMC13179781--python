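"""Markov engine: step semantics, conservation laws, and the
microsimulation oracle for the cohort recursion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdf_cea.markov import (
    initial_distribution,
    natural_history_step,
    relabel_cycle_start,
    run_cohort,
    simulate_microsim,
    treatment_step,
)
from sdf_cea.parameters import ParameterError, Strategy
from conftest import make_params


class TestSteps:
    def test_initial_distribution_published_prevalence(self):
        occ = initial_distribution(0.68)
        assert occ == pytest.approx([0.32, 0.68, 0, 0, 0])

    @pytest.mark.parametrize("p,expected_idx", [(0.0, 0), (1.0, 1)])
    def test_initial_distribution_degenerate(self, p, expected_idx):
        occ = initial_distribution(p)
        assert occ[expected_idx] == 1.0 and occ.sum() == 1.0

    def test_initial_distribution_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            initial_distribution(1.5)

    def test_natural_history_moves_only_incidence(self):
        params = make_params(p_inc_nat=0.3)
        occ = natural_history_step(np.array([1.0, 0, 0, 0, 0]), params.transition)
        assert occ == pytest.approx([0.7, 0.3, 0, 0, 0])

    def test_natural_history_zero_incidence_is_identity(self):
        params = make_params(p_inc_nat=0.0)
        occ0 = np.array([0.2, 0.3, 0.0, 0.0, 0.5])
        assert natural_history_step(occ0, params.transition) == pytest.approx(occ0)

    def test_natural_history_preserves_extracted(self):
        params = make_params(p_inc_nat=0.4)
        occ = natural_history_step(np.array([0.3, 0.2, 0, 0, 0.5]), params.transition)
        assert occ[4] == pytest.approx(0.5)

    def test_treatment_splits_caries_row(self):
        params = make_params(sdf=(0.0, 0.0, 0.6, 0.1))
        occ = treatment_step(np.array([0, 1.0, 0, 0, 0]), params.transition, Strategy.SDF)
        assert occ == pytest.approx([0, 0, 0.6, 0.3, 0.1])

    def test_treatment_all_zero_probs_sends_caries_to_persistent(self):
        params = make_params(p_inc_nat=0.0, sdf=(0, 0, 0, 0), naf=(0, 0, 0, 0))
        occ = treatment_step(np.array([0.4, 0.6, 0, 0, 0]), params.transition, Strategy.SDF)
        assert occ == pytest.approx([0.4, 0, 0, 0.6, 0])

    def test_naf_never_produces_arrest(self):
        params = make_params(naf=(0.2, 0.05, 0.0, 0.4))
        occ = treatment_step(np.array([0.3, 0.7, 0, 0, 0]), params.transition, Strategy.NAF)
        assert occ[2] == 0.0

    def test_relabel_collapses_transient_states(self):
        occ = relabel_cycle_start(np.array([0.2, 0.1, 0.3, 0.3, 0.1]))
        assert occ == pytest.approx([0.5, 0.4, 0, 0, 0.1])

    def test_relabel_identity_without_transient_mass(self):
        occ0 = np.array([0.5, 0.3, 0.0, 0.0, 0.2])
        assert relabel_cycle_start(occ0) == pytest.approx(occ0)


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_mass_conservation_through_every_operation(seed):
    """Occupancy stays a probability vector through each step type."""
    rng = np.random.default_rng(seed)
    occ = rng.dirichlet(np.ones(5))
    params = make_params(
        p_inc_nat=rng.uniform(0, 1),
        sdf=tuple(rng.dirichlet(np.ones(5))[:4]),
        naf=(0.1, 0.1, 0.0, 0.5),
    )
    for out in (
        natural_history_step(occ, params.transition),
        treatment_step(occ, params.transition, Strategy.SDF),
        treatment_step(occ, params.transition, Strategy.NAF),
        relabel_cycle_start(occ),
    ):
        assert abs(out.sum() - 1.0) < 1e-12
        assert np.all(out >= -1e-12)


class TestCohort:
    def test_trajectory_length_contract(self, default_params):
        traj = run_cohort(default_params, Strategy.SDF)
        s = default_params.settings
        assert len(traj) == s.cycles_per_year * s.horizon_years + 1

    def test_one_year_horizon_records_three_occupancies(self):
        params = make_params(horizon_years=1)
        assert len(run_cohort(params, Strategy.NAF)) == 3

    def test_extracted_monotone_nondecreasing(self, default_params, generated_params):
        for params in (default_params, generated_params):
            for strategy in Strategy:
                ext = run_cohort(params, strategy).extracted
                assert np.all(np.diff(ext) >= -1e-15)

    def test_no_extraction_probabilities_no_extraction(self):
        params = make_params(sdf=(0.1, 0.0, 0.5, 0.0), naf=(0.2, 0.0, 0.0, 0.0))
        for strategy in Strategy:
            assert np.all(run_cohort(params, strategy).extracted == 0.0)

    def test_equal_arms_give_identical_trajectories(self):
        arm = (0.1, 0.02, 0.0, 0.3)
        params = make_params(sdf=arm, naf=arm)
        t_sdf = run_cohort(params, Strategy.SDF)
        t_naf = run_cohort(params, Strategy.NAF)
        assert np.allclose(t_sdf.occupancies, t_naf.occupancies)
        assert np.allclose(t_sdf.effects, t_naf.effects)

    def test_arrest_pathway_protects_against_extraction(self):
        """With arms equal except a positive SDF arrest probability, SDF keeps
        fewer teeth in active caries at risk, so its extracted mass never
        exceeds NaF's at any half-cycle."""
        params = make_params(sdf=(0.15, 0.02, 0.5, 0.4), naf=(0.15, 0.02, 0.0, 0.4))
        ext_sdf = run_cohort(params, Strategy.SDF).extracted
        ext_naf = run_cohort(params, Strategy.NAF).extracted
        assert np.all(ext_sdf <= ext_naf + 1e-15)

    def test_occupancies_sum_to_one_everywhere(self, default_params):
        for strategy in Strategy:
            occ = run_cohort(default_params, strategy).occupancies
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)


class TestMicrosim:
    def test_same_seed_identical_output(self, simple_params):
        a = simulate_microsim(simple_params, Strategy.SDF, 500, seed=42)
        b = simulate_microsim(simple_params, Strategy.SDF, 500, seed=42)
        assert np.array_equal(a.occupancies, b.occupancies)

    def test_degenerate_probabilities_match_cohort_exactly(self):
        params = make_params(p_init=1.0, p_inc_nat=0.0, sdf=(0, 0, 1.0, 0.0), naf=(0, 0, 0, 1.0))
        for strategy in Strategy:
            micro = simulate_microsim(params, strategy, 50, seed=0)
            cohort = run_cohort(params, strategy)
            assert np.allclose(micro.occupancies, cohort.occupancies)

    @pytest.mark.parametrize("strategy", list(Strategy))
    def test_cohort_matches_microsim_within_sampling_error(self, default_params, strategy):
        """The deterministic recursion agrees with a 100 000-tooth stochastic
        simulation within 3 binomial standard errors (and within 0.005
        absolute) at every state and half-cycle."""
        n = 100_000
        micro = simulate_microsim(default_params, strategy, n, seed=7)
        cohort = run_cohort(default_params, strategy)
        p = cohort.occupancies
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
        diff = np.abs(micro.occupancies - p)
        assert np.all(diff <= np.maximum(3 * se, 3 / n))
        assert diff.max() < 0.005
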