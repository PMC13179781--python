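"""Markov cohort engine for the tooth-level root-caries model.

State order everywhere: (NO_CARIES, ROOT_CARIES, ARREST, PERSISTENT,
EXTRACTED).  Each annual cycle is two 6-month transitions: a natural-history
step in which caries-free teeth may develop root caries, then a treatment
step in which the assigned strategy (SDF or NaF varnish) is applied.  At the
start of the next cycle, ARREST collapses into NO_CARIES and PERSISTENT into
ROOT_CARIES; EXTRACTED is absorbing.  Extraction can occur only during the
treatment step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    N_STATES,
    STATE_ORDER,
    HealthState,
    ModelParameters,
    ParameterError,
    Strategy,
    TransitionProbabilities,
)

__all__ = [
    "Trajectory",
    "initial_distribution",
    "natural_history_step",
    "treatment_step",
    "relabel_cycle_start",
    "natural_history_matrix",
    "treatment_matrix",
    "relabel_matrix",
    "run_cohort",
    "simulate_microsim",
]

_I_NO, _I_RC, _I_AR, _I_PE, _I_EX = range(N_STATES)
_SUM_TOL = 1e-12


def _validate_occupancy(occ: np.ndarray) -> np.ndarray:
    occ = np.asarray(occ, dtype=float)
    if occ.shape != (N_STATES,):
        raise ParameterError(f"occupancy must have shape ({N_STATES},), got {occ.shape}")
    if np.any(occ < -_SUM_TOL):
        raise ParameterError(f"occupancy has negative entries: {occ}")
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ParameterError(f"occupancy must sum to 1, got {occ.sum()}")
    return occ


@dataclass
class Trajectory:
    """Occupancy and undiscounted accruals over every half-cycle boundary.

    ``occupancies[k]`` is the distribution after k half-cycles (k = 0 is the
    initial distribution); there are ``2 * horizon_years + 1`` boundaries.
    ``effects[k-1]`` and ``costs[k-1]`` are the undiscounted per-tooth accruals
    of half-cycle k (the step ending at boundary k).
    """

    strategy: Strategy
    times: np.ndarray  # years at each boundary, shape (n_boundaries,)
    occupancies: np.ndarray  # shape (n_boundaries, 5)
    effects: np.ndarray  # per-tooth tooth-year accrual per half-cycle
    costs: np.ndarray  # per-tooth cost accrual per half-cycle

    def __len__(self) -> int:
        return self.occupancies.shape[0]

    @property
    def extracted(self) -> np.ndarray:
        return self.occupancies[:, _I_EX]

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a table: one row per half-cycle boundary."""
        df = pd.DataFrame(self.occupancies, columns=[s.value for s in STATE_ORDER])
        df.insert(0, "time_years", self.times)
        df["effect_accrual"] = np.concatenate([[0.0], self.effects])
        df["cost_accrual"] = np.concatenate([[0.0], self.costs])
        return df


def initial_distribution(p_init: float) -> np.ndarray:
    """Starting occupancy: root caries with prevalence ``p_init``, else caries-free."""
    if not (0.0 <= p_init <= 1.0):
        raise ParameterError(f"p_init must lie in [0, 1], got {p_init}")
    occ = np.zeros(N_STATES)
    occ[_I_NO] = 1.0 - p_init
    occ[_I_RC] = p_init
    return occ


def natural_history_matrix(tp: TransitionProbabilities) -> np.ndarray:
    """Row-stochastic matrix for the natural-history half-cycle.

    Only NO_CARIES -> ROOT_CARIES (probability ``p_incidence_nat``) can occur;
    every other state holds.
    """
    m = np.eye(N_STATES)
    m[_I_NO, _I_NO] = 1.0 - tp.p_incidence_nat
    m[_I_NO, _I_RC] = tp.p_incidence_nat
    return m

def treatment_matrix(tp: TransitionProbabilities, strategy: Strategy) -> np.ndarray:
    """Row-stochastic matrix for the treatment half-cycle of ``strategy``.

    Caries-free teeth stay caries-free, develop caries, or are extracted.
    Teeth with active root caries become arrested (SDF only), persist, or are
    extracted; under NaF the arrest branch carries zero mass.
    """
    if not isinstance(strategy, Strategy):
        raise ParameterError(f"unknown strategy {strategy!r}")
    arm = tp.for_strategy(strategy)
    m = np.eye(N_STATES)
    m[_I_NO, _I_NO] = 1.0 - arm.p_incidence_tx - arm.p_extract_nocaries
    m[_I_NO, _I_RC] = arm.p_incidence_tx
    m[_I_NO, _I_EX] = arm.p_extract_nocaries
    m[_I_RC, _I_RC] = 0.0
    m[_I_RC, _I_AR] = arm.p_arrest
    m[_I_RC, _I_PE] = 1.0 - arm.p_arrest - arm.p_extract_caries
    m[_I_RC, _I_EX] = arm.p_extract_caries
    return m


def relabel_matrix() -> np.ndarray:
    """Cycle-start collapse: ARREST -> NO_CARIES, PERSISTENT -> ROOT_CARIES."""
    m = np.eye(N_STATES)
    m[_I_AR, _I_AR] = 0.0
    m[_I_AR, _I_NO] = 1.0
    m[_I_PE, _I_PE] = 0.0
    m[_I_PE, _I_RC] = 1.0
    return m


def natural_history_step(occ: np.ndarray, tp: TransitionProbabilities) -> np.ndarray:
    return _validate_occupancy(occ) @ natural_history_matrix(tp)


def treatment_step(
    occ: np.ndarray, tp: TransitionProbabilities, strategy: Strategy
) -> np.ndarray:
    return _validate_occupancy(occ) @ treatment_matrix(tp, strategy)


def relabel_cycle_start(occ: np.ndarray) -> np.ndarray:
    return _validate_occupancy(occ) @ relabel_matrix()


def _half_cycle_cost(
    params: ModelParameters, strategy: Strategy, nonextracted: float, is_visit: bool
) -> float:
    """Undiscounted per-tooth cost accrual of one half-cycle.

    ``nonextracted`` is the non-extracted occupancy at the start of the step,
    i.e. the expected fraction of teeth present at the visit.  Application
    cost is charged per tooth still present; visit-level costs (exam,
    radiography, access) are charged once per visit (shared across the
    subject's teeth) or per tooth, according to ``cost_allocation``.
    """
    if not is_visit or nonextracted <= 0.0:
        return 0.0
    s = params.settings
    app = params.costs.application_cost(strategy) * nonextracted
    visit = params.costs.visit_cost
    if s.cost_allocation == "per_visit_shared":
        return app + visit / s.n_teeth
    return app + visit * nonextracted


def run_cohort(params: ModelParameters, strategy: Strategy) -> Trajectory:
    """Evolve the expected tooth through the full horizon.

    Records occupancy at every half-cycle boundary and undiscounted per-tooth
    effect and cost accruals per half-cycle.  Effects accrue 0.5 year times
    the utility-weighted occupancy at the end of each 6-month step.
    """
    tp = params.transition
    s = params.settings
    n_half = s.cycles_per_year * s.horizon_years
    m_nat = natural_history_matrix(tp)
    m_tx = treatment_matrix(tp, strategy)
    m_rl = relabel_matrix()
    w = np.array(params.utilities.as_vector())

    occ = initial_distribution(tp.p_init_caries)
    occupancies = np.empty((n_half + 1, N_STATES))
    effects = np.empty(n_half)
    costs = np.empty(n_half)
    occupancies[0] = occ
    charge_nat = s.charge_schedule == "both_half_cycles"
    for year in range(s.horizon_years):
        if year > 0:
            occ = occ @ m_rl
        # natural-history half-cycle
        pres = 1.0 - occ[_I_EX]
        occ = occ @ m_nat
        k = 2 * year + 1
        occupancies[k] = occ
        effects[k - 1] = 0.5 * float(w @ occ)
        costs[k - 1] = _half_cycle_cost(params, strategy, pres, charge_nat)
        # treatment half-cycle
        pres = 1.0 - occ[_I_EX]
        occ = occ @ m_tx
        k = 2 * year + 2
        occupancies[k] = occ
        effects[k - 1] = 0.5 * float(w @ occ)
        costs[k - 1] = _half_cycle_cost(params, strategy, pres, True)
    times = np.arange(n_half + 1) / s.cycles_per_year
    return Trajectory(
        strategy=strategy, times=times, occupancies=occupancies, effects=effects, costs=costs
    )


def simulate_microsim(
    params: ModelParameters, strategy: Strategy, n_teeth: int, seed: int
) -> Trajectory:
    """Monte Carlo microsimulation oracle for :func:`run_cohort`.

    Simulates ``n_teeth`` independent teeth through the same transition rules
    and returns empirical occupancy fractions at every half-cycle boundary.
    Accruals are computed from the empirical occupancies with the same rules
    as the cohort model.  Deterministic for a fixed seed.
    """
    if n_teeth < 1:
        raise ParameterError(f"n_teeth must be >= 1, got {n_teeth}")
    rng = np.random.default_rng(seed)
    tp = params.transition
    s = params.settings
    n_half = s.cycles_per_year * s.horizon_years
    m_nat = natural_history_matrix(tp)
    m_tx = treatment_matrix(tp, strategy)
    m_rl = relabel_matrix()
    w = np.array(params.utilities.as_vector())

    cum_nat, cum_tx, cum_rl = (np.cumsum(m, axis=1) for m in (m_nat, m_tx, m_rl))
    state = np.where(rng.random(n_teeth) < tp.p_init_caries, _I_RC, _I_NO).astype(np.int64)

    def occupancy(st: np.ndarray) -> np.ndarray:
        return np.bincount(st, minlength=N_STATES) / n_teeth

    def advance(st: np.ndarray, cum: np.ndarray) -> np.ndarray:
        u = rng.random(st.shape[0])
        # inverse-CDF draw along each tooth's current row
        return (u[:, None] > cum[st]).sum(axis=1).astype(np.int64)

    occupancies = np.empty((n_half + 1, N_STATES))
    effects = np.empty(n_half)
    costs = np.empty(n_half)
    occupancies[0] = occupancy(state)
    charge_nat = s.charge_schedule == "both_half_cycles"
    for year in range(s.horizon_years):
        if year > 0:
            state = advance(state, cum_rl)
        pres = 1.0 - occupancy(state)[_I_EX]
        state = advance(state, cum_nat)
        occ = occupancy(state)
        k = 2 * year + 1
        occupancies[k] = occ
        effects[k - 1] = 0.5 * float(w @ occ)
        costs[k - 1] = _half_cycle_cost(params, strategy, pres, charge_nat)
        pres = 1.0 - occ[_I_EX]
        state = advance(state, cum_tx)
        occ = occupancy(state)
        k = 2 * year + 2
        occupancies[k] = occ
        effects[k - 1] = 0.5 * float(w @ occ)
        costs[k - 1] = _half_cycle_cost(params, strategy, pres, True)
    times = np.arange(n_half + 1) / s.cycles_per_year
    return Trajectory(
        strategy=strategy, times=times, occupancies=occupancies, effects=effects, costs=costs
    )
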