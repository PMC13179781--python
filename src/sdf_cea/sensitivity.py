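"""Sensitivity analyses: one-way scans, beta/gamma uncertainty fitting,
probabilistic sensitivity analysis (PSA), and cost-effectiveness
acceptability curves (CEAC).

Uncertainty follows the usual health-economic conventions: beta distributions
for probabilities, gamma for costs, each summarized by its mean and a 95%
interval.  PSA draws are reproducible: a root seed spawns one independent
substream per parameter, keyed by the parameter's name, so adding or removing
a parameter does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .economics import compare, evaluate_strategy, run_base_case
from .parameters import (
    DistributionSpec,
    ModelParameters,
    ParameterError,
    Strategy,
    apply_values,
    get_value,
    set_value,
)

__all__ = [
    "OneWayResult",
    "PsaResult",
    "CeacCurve",
    "FitError",
    "one_way",
    "one_way_table",
    "fit_beta",
    "fit_gamma",
    "draw_psa",
    "run_psa",
    "ceac",
    "ceac_crossover",
]

#: The five cost parameters scanned in the one-way analysis.
ONE_WAY_COST_PARAMETERS = ("costs.c_sdf", "costs.c_naf", "costs.c_access", "costs.c_exam", "costs.c_xray")


class FitError(ValueError):
    """Raised when no distribution matches the requested mean/CI summary."""


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OneWayResult:
    """ICER of SDF vs NaF at each tested value of a single parameter."""

    parameter: str
    values: np.ndarray
    icers: np.ndarray
    base_icer: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.parameter, "value": self.values, "icer": self.icers}
        )


def one_way(params: ModelParameters, name: str, values: Sequence[float]) -> OneWayResult:
    """Recompute the ICER while a single parameter sweeps over ``values``.

    Both strategies are re-run at every value; the input parameter set is
    left untouched.
    """
    get_value(params, name)  # raises on unknown name
    base = run_base_case(params)
    if base.icer is None:
        raise ParameterError(f"base-case ICER undefined ({base.dominance}); one-way scan meaningless")
    icers = []
    for v in values:
        res = run_base_case(set_value(params, name, float(v)))
        icers.append(np.nan if res.icer is None else res.icer)
    return OneWayResult(
        parameter=name,
        values=np.asarray(values, dtype=float),
        icers=np.asarray(icers, dtype=float),
        base_icer=base.icer,
    )


def one_way_table(
    params: ModelParameters, names: Sequence[str] = ONE_WAY_COST_PARAMETERS
) -> pd.DataFrame:
    """One-way scan of each cost parameter at its (low, base, high) points."""
    frames = []
    for name in names:
        item = getattr(params.costs, name.split(".")[1])
        res = one_way(params, name, [item.low, item.base, item.high])
        frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Beta / gamma fitting from mean + 95% CI
# ---------------------------------------------------------------------------

_QLO, _QHI = 0.025, 0.975


def _implied_sd(spec: DistributionSpec) -> float:
    low, high = spec.ci95
    return (high - low) / 3.92  # normal-approximation width of a 95% CI


def fit_beta(spec: DistributionSpec) -> tuple[float, float]:
    """Fit beta shape parameters (alpha, beta) to a mean + 95% CI summary.

    The mean is matched exactly by parametrizing on the concentration
    kappa (alpha = mean*kappa, beta = (1-mean)*kappa); kappa is warm-started
    by method of moments on the CI-implied variance and refined so the
    central 95% interval of the fitted distribution reproduces the requested
    one within 1e-3.
    """
    if spec.family != "beta":
        raise FitError(f"fit_beta requires a beta spec, got {spec.family}")
    m = spec.mean
    low, high = spec.ci95
    sd = _implied_sd(spec)
    if sd <= 0:
        raise FitError(f"degenerate CI width for {spec}")
    var = min(sd * sd, 0.95 * m * (1 - m))  # beta variance must stay below m(1-m)
    kappa0 = m * (1 - m) / var - 1.0
    kappa0 = max(kappa0, 1e-3)

    def err(log_kappa: float) -> float:
        kappa = np.exp(log_kappa)
        a, b = m * kappa, (1 - m) * kappa
        qlo, qhi = stats.beta.ppf([_QLO, _QHI], a, b)
        return (qlo - low) ** 2 + (qhi - high) ** 2

    res = optimize.minimize_scalar(
        err, bracket=(np.log(kappa0) - 1, np.log(kappa0) + 1), method="brent"
    )
    kappa = float(np.exp(res.x))
    a, b = m * kappa, (1 - m) * kappa
    qlo, qhi = stats.beta.ppf([_QLO, _QHI], a, b)
    if max(abs(qlo - low), abs(qhi - high)) > 1e-3:
        raise FitError(
            f"no beta distribution with mean {m} matches CI ({low}, {high}); "
            f"best fit alpha={a:.4g}, beta={b:.4g} gives ({qlo:.4g}, {qhi:.4g})"
        )
    return a, b


def fit_gamma(spec: DistributionSpec) -> tuple[float, float]:
    """Fit gamma (shape, scale) to a mean + 95% CI summary.

    Same contract as :func:`fit_beta`: the mean is exact (scale = mean/shape)
    and the shape is refined until the fitted central 95% interval matches
    the requested one within a relative tolerance of 1e-3.
    """
    if spec.family != "gamma":
        raise FitError(f"fit_gamma requires a gamma spec, got {spec.family}")
    m = spec.mean
    low, high = spec.ci95
    if m <= 0:
        raise FitError(f"gamma mean must be positive, got {m}")
    sd = _implied_sd(spec)
    if sd <= 0:
        raise FitError(f"degenerate CI width for {spec}")
    shape0 = max((m / sd) ** 2, 1e-3)

    def err(log_shape: float) -> float:
        shape = np.exp(log_shape)
        qlo, qhi = stats.gamma.ppf([_QLO, _QHI], shape, scale=m / shape)
        return ((qlo - low) / m) ** 2 + ((qhi - high) / m) ** 2

    res = optimize.minimize_scalar(
        err, bracket=(np.log(shape0) - 1, np.log(shape0) + 1), method="brent"
    )
    shape = float(np.exp(res.x))
    scale = m / shape
    qlo, qhi = stats.gamma.ppf([_QLO, _QHI], shape, scale=scale)
    tol = 1e-3 * max(1.0, m)
    if max(abs(qlo - low), abs(qhi - high)) > tol:
        raise FitError(
            f"no gamma distribution with mean {m} matches CI ({low}, {high}); "
            f"best fit shape={shape:.4g}, scale={scale:.4g} gives ({qlo:.4g}, {qhi:.4g})"
        )
    return shape, scale


# ---------------------------------------------------------------------------
# PSA draws and CEAC
# ---------------------------------------------------------------------------


def _substream(seed: int, name: str) -> np.random.Generator:
    # keyed by parameter name: insertion/removal of other parameters does not
    # shift this parameter's draws
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def draw_psa(params: ModelParameters, n: int, seed: int) -> list[ModelParameters]:
    """Draw ``n`` parameter sets from the distributions in ``psa_specs``.

    Parameters without a spec stay at their base value.  If a joint draw
    violates a branch-mass constraint (two exclusive probabilities summing
    above 1), the offending pair is rescaled proportionally onto the simplex;
    with realistic parameter uncertainty this is a rare tail event.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not params.psa_specs:
        raise ParameterError("params.psa_specs is empty; nothing to draw")
    draws_by_name: dict[str, np.ndarray] = {}
    for name in sorted(params.psa_specs):
        spec = params.psa_specs[name]
        rng = _substream(seed, name)
        if spec.family == "beta":
            a, b = fit_beta(spec)
            draws_by_name[name] = rng.beta(a, b, size=n)
        else:
            shape, scale = fit_gamma(spec)
            draws_by_name[name] = rng.gamma(shape, scale, size=n)

    exclusive_pairs = [
        ("transition.sdf.p_incidence_tx", "transition.sdf.p_extract_nocaries"),
        ("transition.sdf.p_arrest", "transition.sdf.p_extract_caries"),
        ("transition.naf.p_incidence_tx", "transition.naf.p_extract_nocaries"),
        ("transition.naf.p_arrest", "transition.naf.p_extract_caries"),
    ]
    out = []
    for i in range(n):
        values = {name: float(v[i]) for name, v in draws_by_name.items()}
        for pa, pb in exclusive_pairs:
            va = values.get(pa, get_value(params, pa))
            vb = values.get(pb, get_value(params, pb))
            total = va + vb
            if total > 1.0:
                scale = (1.0 - 1e-9) / total
                if pa in values:
                    values[pa] = va * scale
                if pb in values:
                    values[pb] = vb * scale
        out.append(apply_values(params, values))
    return out


@dataclass(frozen=True)
class PsaResult:
    """Per-draw discounted (cost, effect) pairs for each strategy."""

    costs: dict[Strategy, np.ndarray]
    effects: dict[Strategy, np.ndarray]
    n_draws: int
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"draw": np.arange(self.n_draws)}
        for strat in (Strategy.NAF, Strategy.SDF):
            cols[f"cost_{strat.value.lower()}"] = self.costs[strat]
            cols[f"effect_{strat.value.lower()}"] = self.effects[strat]
        return pd.DataFrame(cols)


def run_psa(draws: Sequence[ModelParameters], seed: Optional[int] = None) -> PsaResult:
    """Evaluate both strategies on every drawn parameter set."""
    if not draws:
        raise ParameterError("draws must be nonempty")
    costs = {s: np.empty(len(draws)) for s in Strategy}
    effects = {s: np.empty(len(draws)) for s in Strategy}
    for i, p in enumerate(draws):
        try:
            for s in Strategy:
                res = evaluate_strategy(p, s)
                costs[s][i] = res.discounted_cost
                effects[s][i] = res.discounted_effect
        except Exception as exc:  # surface the offending draw
            raise RuntimeError(f"model evaluation failed at draw {i}: {exc}") from exc
    return PsaResult(costs=costs, effects=effects, n_draws=len(draws), seed=seed)


@dataclass(frozen=True)
class CeacCurve:
    """Probability each strategy is cost-effective over a WTP grid."""

    wtp: np.ndarray
    probability: dict[Strategy, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp,
                "p_naf": self.probability[Strategy.NAF],
                "p_sdf": self.probability[Strategy.SDF],
            }
        )


def ceac(psa: PsaResult, wtp_grid: Sequence[float]) -> CeacCurve:
    """Acceptability: the fraction of draws in which each strategy has the
    strictly highest net monetary benefit (exact ties split half and half)."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("wtp_grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ParameterError("wtp_grid must be sorted ascending")
    nmb = {
        s: grid[:, None] * psa.effects[s][None, :] - psa.costs[s][None, :] for s in Strategy
    }
    sdf_wins = nmb[Strategy.SDF] > nmb[Strategy.NAF]
    ties = nmb[Strategy.SDF] == nmb[Strategy.NAF]
    p_sdf = (sdf_wins + 0.5 * ties).mean(axis=1)
    return CeacCurve(
        wtp=grid, probability={Strategy.SDF: p_sdf, Strategy.NAF: 1.0 - p_sdf}
    )


def ceac_crossover(curve: CeacCurve, strategy: Strategy = Strategy.SDF) -> Optional[float]:
    """WTP at which ``strategy`` first reaches 50% acceptability.

    Returns the smallest grid WTP whose acceptability is >= 0.5, linearly
    interpolated against the preceding grid point; None when the curve never
    crosses 0.5 on the grid.
    """
    p = curve.probability[strategy]
    idx = np.flatnonzero(p >= 0.5)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(curve.wtp[0])
    w0, w1 = curve.wtp[i - 1], curve.wtp[i]
    p0, p1 = p[i - 1], p[i]
    if p1 == p0:
        return float(w1)
    return float(w0 + (0.5 - p0) / (p1 - p0) * (w1 - w0))
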