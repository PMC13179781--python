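"""Discounting, cost/effect accrual, ICER and net monetary benefit.

Effectiveness is measured in extraction-free tooth-years (optionally
utility-weighted): each 6-month step a tooth spends non-extracted contributes
half a year, discounted at the annual rate to the time of the step's end
boundary.  Costs accrue at visits on the same time grid.  Both streams are
discounted at the same 3%/year default rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .markov import Trajectory, run_cohort
from .parameters import ModelParameters, ParameterError, Strategy

__all__ = [
    "StrategyResult",
    "CEResult",
    "discount_factor",
    "accrue",
    "evaluate_strategy",
    "compare",
    "run_base_case",
]


@dataclass(frozen=True)
class StrategyResult:
    """Discounted cost and effect of one strategy."""

    strategy: Strategy
    discounted_cost: float
    discounted_effect: float  # extraction-free tooth-years


@dataclass(frozen=True)
class CEResult:
    """Pairwise comparison of an intervention (b) against a comparator (a).

    ``icer`` is ``delta_cost / delta_effect`` when both increments are
    positive (or both negative); it is None when the comparison is settled by
    dominance or the increment in effect is zero.
    """

    a: StrategyResult
    b: StrategyResult
    wtp: float
    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    dominance: str  # "none" | "b_dominant" | "b_dominated" | "icer_undefined"
    nmb_a: float
    nmb_b: float
    incremental_nmb: float

    def to_frame(self) -> pd.DataFrame:
        """Publication-style table: one row per strategy."""
        rows = [
            {
                "strategy": self.a.strategy.value,
                "cost": self.a.discounted_cost,
                "incremental_cost": np.nan,
                "effectiveness": self.a.discounted_effect,
                "incremental_effectiveness": np.nan,
                "icer": np.nan,
                "nmb": self.nmb_a,
            },
            {
                "strategy": self.b.strategy.value,
                "cost": self.b.discounted_cost,
                "incremental_cost": self.delta_cost,
                "effectiveness": self.b.discounted_effect,
                "incremental_effectiveness": self.delta_effect,
                "icer": self.icer if self.icer is not None else np.nan,
                "nmb": self.nmb_b,
            },
        ]
        return pd.DataFrame(rows)


def discount_factor(rate: float, t: float | np.ndarray) -> float | np.ndarray:
    """Present-value factor ``(1 + rate)**(-t)`` for time ``t`` in years."""
    if rate < 0:
        raise ParameterError(f"discount rate must be >= 0, got {rate}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("discount time must be >= 0")
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


def accrue(trajectory: Trajectory, params: ModelParameters, strategy: Strategy) -> StrategyResult:
    """Discount and aggregate a trajectory's per-half-cycle accruals.

    Each half-cycle's accrual is discounted to its end boundary (t = k/2
    years for the k-th half-cycle; no half-cycle correction).  The effect is
    reported on the scale chosen by ``effect_aggregation`` and the cost on the
    scale chosen by ``cost_aggregation``.
    """
    s = params.settings
    n_half = s.cycles_per_year * s.horizon_years
    if len(trajectory) != n_half + 1:
        raise ParameterError(
            f"trajectory length {len(trajectory)} does not match settings "
            f"({n_half + 1} boundaries expected)"
        )
    t_end = trajectory.times[1:]
    df = discount_factor(s.discount_rate, t_end)
    effect = float(np.sum(trajectory.effects * df))
    cost = float(np.sum(trajectory.costs * df))
    if s.effect_aggregation == "cohort_sum":
        effect *= s.n_teeth
    if s.cost_aggregation == "cohort_sum":
        cost *= s.n_teeth
    return StrategyResult(strategy=strategy, discounted_cost=cost, discounted_effect=effect)


def evaluate_strategy(params: ModelParameters, strategy: Strategy) -> StrategyResult:
    """Run the cohort model for one strategy and accrue its outcomes."""
    return accrue(run_cohort(params, strategy), params, strategy)


def compare(a: StrategyResult, b: StrategyResult, wtp: float) -> CEResult:
    """Incremental comparison of strategy ``b`` against comparator ``a``.

    NMB_x = wtp * effect_x - cost_x; the incremental NMB is NMB_b - NMB_a.
    Dominance flags replace the ICER when the increments disagree in sign.
    """
    delta_cost = b.discounted_cost - a.discounted_cost
    delta_effect = b.discounted_effect - a.discounted_effect
    nmb_a = wtp * a.discounted_effect - a.discounted_cost
    nmb_b = wtp * b.discounted_effect - b.discounted_cost

    dominance = "none"
    icer: Optional[float] = None
    if delta_effect == 0.0:
        dominance = "none" if delta_cost == 0.0 else "icer_undefined"
    elif delta_cost <= 0.0 and delta_effect > 0.0:
        dominance = "b_dominant"
    elif delta_cost >= 0.0 and delta_effect < 0.0:
        dominance = "b_dominated"
    else:
        icer = delta_cost / delta_effect
    return CEResult(
        a=a,
        b=b,
        wtp=wtp,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=dominance,
        nmb_a=nmb_a,
        nmb_b=nmb_b,
        incremental_nmb=nmb_b - nmb_a,
    )


def run_base_case(params: ModelParameters, wtp: Optional[float] = None) -> CEResult:
    """Evaluate both strategies and compare SDF against the NaF comparator."""
    naf = evaluate_strategy(params, Strategy.NAF)
    sdf = evaluate_strategy(params, Strategy.SDF)
    return compare(naf, sdf, params.settings.wtp if wtp is None else wtp)
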