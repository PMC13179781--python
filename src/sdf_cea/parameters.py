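"""Parameter schema for the tooth-level Markov cost-effectiveness model.

The model compares semiannual 38% silver diamine fluoride (SDF) application
against 5% sodium fluoride (NaF) varnish for managing high-risk root caries.
Everything a run needs — transition probabilities, unit costs with their
one-way ranges, utility weights, and economic settings — lives in a single
validated :class:`ModelParameters` object, which can be round-tripped through
a structured YAML document or a flat CSV parameter table.

All transition probabilities are per 6-month transition (the model's native
step); they are never annualized.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Literal, Optional, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "HealthState",
    "Strategy",
    "STATE_ORDER",
    "StrategyTransitions",
    "TransitionProbabilities",
    "CostItem",
    "CostParameters",
    "EconomicSettings",
    "UtilityWeights",
    "DistributionSpec",
    "ModelParameters",
    "load_parameters",
    "save_parameters",
    "load_parameter_table",
    "save_parameter_table",
    "get_value",
    "set_value",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised for invalid parameter values or unknown parameter names."""


class HealthState(str, enum.Enum):
    """The five tooth states.

    ARREST and PERSISTENT exist only transiently within an annual cycle;
    they are collapsed back into NO_CARIES / ROOT_CARIES at each cycle start.
    EXTRACTED is the unique absorbing state.
    """

    NO_CARIES = "NO_CARIES"
    ROOT_CARIES = "ROOT_CARIES"
    ARREST = "ARREST"
    PERSISTENT = "PERSISTENT"
    EXTRACTED = "EXTRACTED"


#: Fixed state order for every vector/matrix representation.
STATE_ORDER: Tuple[HealthState, ...] = (
    HealthState.NO_CARIES,
    HealthState.ROOT_CARIES,
    HealthState.ARREST,
    HealthState.PERSISTENT,
    HealthState.EXTRACTED,
)

STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}
N_STATES = len(STATE_ORDER)


class Strategy(str, enum.Enum):
    """Treatment strategy applied in the second half of each annual cycle."""

    SDF = "SDF"  # 38% silver diamine fluoride: preventive and therapeutic
    NAF = "NAF"  # 5% sodium fluoride varnish: preventive only


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {p}")


class StrategyTransitions(BaseModel):
    """Per-strategy 6-month transition probabilities for the treatment step."""

    model_config = ConfigDict(frozen=True)

    p_incidence_tx: float = Field(ge=0.0, le=1.0, description="no caries -> root caries")
    p_extract_nocaries: float = Field(ge=0.0, le=1.0, description="no caries -> extraction")
    p_arrest: float = Field(ge=0.0, le=1.0, description="root caries -> arrest")
    p_extract_caries: float = Field(ge=0.0, le=1.0, description="root caries -> extraction")

    @model_validator(mode="after")
    def _branch_masses(self) -> "StrategyTransitions":
        if self.p_incidence_tx + self.p_extract_nocaries > 1.0 + 1e-12:
            raise ValueError(
                "p_incidence_tx + p_extract_nocaries exceeds 1 "
                f"({self.p_incidence_tx} + {self.p_extract_nocaries})"
            )
        if self.p_arrest + self.p_extract_caries > 1.0 + 1e-12:
            raise ValueError(
                "p_arrest + p_extract_caries exceeds 1 "
                f"({self.p_arrest} + {self.p_extract_caries})"
            )
        return self


class TransitionProbabilities(BaseModel):
    """All 6-month transition probabilities driving the Markov model.

    The NaF varnish arm is preventive only: it has no arrest pathway, so
    ``naf.p_arrest`` must be structurally zero.
    """

    model_config = ConfigDict(frozen=True)

    p_init_caries: float = Field(ge=0.0, le=1.0, description="initial root-caries prevalence")
    p_incidence_nat: float = Field(
        ge=0.0, le=1.0, description="no caries -> root caries in the natural-history half-cycle"
    )
    sdf: StrategyTransitions
    naf: StrategyTransitions

    @model_validator(mode="after")
    def _naf_no_arrest(self) -> "TransitionProbabilities":
        if self.naf.p_arrest != 0.0:
            raise ValueError(
                "naf.p_arrest must be 0: NaF varnish is modeled as preventive only "
                f"(got {self.naf.p_arrest})"
            )
        return self

    def for_strategy(self, strategy: Strategy) -> StrategyTransitions:
        return self.sdf if strategy is Strategy.SDF else self.naf


class CostItem(BaseModel):
    """A unit cost with its one-way sensitivity range (2025 US$)."""

    model_config = ConfigDict(frozen=True)

    base: float = Field(ge=0.0)
    low: float = Field(ge=0.0)
    high: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _ordered(self) -> "CostItem":
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"cost range must satisfy low <= base <= high, got {self.low}, {self.base}, {self.high}")
        return self


class CostParameters(BaseModel):
    """Unit costs per application / per visit, with one-way ranges."""

    model_config = ConfigDict(frozen=True)

    c_sdf: CostItem = CostItem(base=39.0, low=31.0, high=47.0)
    c_naf: CostItem = CostItem(base=33.0, low=27.0, high=39.0)
    c_exam: CostItem = CostItem(base=36.0, low=27.0, high=45.0)
    c_xray: CostItem = CostItem(base=45.0, low=37.0, high=53.0)
    c_access: CostItem = CostItem(base=129.0, low=93.0, high=165.0)
    currency: str = "2025 US$"

    def application_cost(self, strategy: Strategy) -> float:
        return self.c_sdf.base if strategy is Strategy.SDF else self.c_naf.base

    @property
    def visit_cost(self) -> float:
        """Per-visit cost shared by all teeth: exam + radiography + access."""
        return self.c_exam.base + self.c_xray.base + self.c_access.base


class EconomicSettings(BaseModel):
    """Economic and structural settings for a model run."""

    model_config = ConfigDict(frozen=True)

    discount_rate: float = Field(default=0.03, ge=0.0)
    horizon_years: int = Field(default=19, ge=1)
    cycles_per_year: int = Field(default=2, ge=2, le=2)
    n_teeth: int = Field(default=21, ge=1)
    start_age: float = 45.0
    wtp: float = Field(default=50_000.0, ge=0.0)
    # How visit-level costs (exam, radiography, access) are allocated:
    #   per_visit_shared - incurred once per visit and shared across teeth
    #   per_tooth        - charged in full against every non-extracted tooth
    cost_allocation: Literal["per_visit_shared", "per_tooth"] = "per_visit_shared"
    # Reporting scale of the discounted effect: expectation for a single tooth
    # or the 21-tooth cohort sum.
    effect_aggregation: Literal["per_tooth_mean", "cohort_sum"] = "per_tooth_mean"
    # Reporting scale of the discounted cost.  Costs and effects are allowed
    # different scales because the subject attends visits as a whole person
    # while effectiveness is a per-tooth quantity.
    cost_aggregation: Literal["per_tooth_mean", "cohort_sum"] = "cohort_sum"
    # Which half-cycles incur visit/application costs: only the treatment
    # half-cycle, or both 6-month visits of each annual cycle (semiannual
    # preventive visits).
    charge_schedule: Literal["treatment_only", "both_half_cycles"] = "both_half_cycles"


class UtilityWeights(BaseModel):
    """Per-state weights applied to effect accrual (extraction-free tooth-years).

    The default of 1 for every non-extracted state and 0 for EXTRACTED makes
    the effect plain tooth-years free of extraction; other weights yield
    utility-weighted tooth-years.
    """

    model_config = ConfigDict(frozen=True)

    NO_CARIES: float = Field(default=1.0, ge=0.0, le=1.0)
    ROOT_CARIES: float = Field(default=1.0, ge=0.0, le=1.0)
    ARREST: float = Field(default=1.0, ge=0.0, le=1.0)
    PERSISTENT: float = Field(default=1.0, ge=0.0, le=1.0)
    EXTRACTED: float = Field(default=0.0, ge=0.0, le=0.0)

    def as_vector(self) -> list[float]:
        return [getattr(self, s.value) for s in STATE_ORDER]


class DistributionSpec(BaseModel):
    """A parametric uncertainty distribution summarized by mean and 95% CI.

    beta is used for probabilities, gamma for costs.
    """

    model_config = ConfigDict(frozen=True)

    family: Literal["beta", "gamma"]
    mean: float
    ci95: Tuple[float, float]

    @model_validator(mode="after")
    def _feasible(self) -> "DistributionSpec":
        low, high = self.ci95
        if not (low < high):
            raise ValueError(f"ci95 must satisfy low < high, got ({low}, {high})")
        if self.family == "beta":
            if not (0.0 < self.mean < 1.0):
                raise ValueError(f"beta mean must lie in (0, 1), got {self.mean}")
            if not (0.0 <= low and high <= 1.0):
                raise ValueError(f"beta ci95 must lie in [0, 1], got ({low}, {high})")
        else:
            if self.mean <= 0.0:
                raise ValueError(f"gamma mean must be positive, got {self.mean}")
            if low < 0.0:
                raise ValueError(f"gamma ci95 low must be >= 0, got {low}")
        return self


class ModelParameters(BaseModel):
    """The single source of truth for a model run."""

    model_config = ConfigDict(frozen=True)

    transition: TransitionProbabilities
    costs: CostParameters = CostParameters()
    utilities: UtilityWeights = UtilityWeights()
    settings: EconomicSettings = EconomicSettings()
    #: Uncertainty distributions for the probabilistic sensitivity analysis,
    #: keyed by dotted parameter name (e.g. "costs.c_sdf",
    #: "transition.sdf.p_arrest").
    psa_specs: dict[str, DistributionSpec] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _specs_consistent(self) -> "ModelParameters":
        for name, spec in self.psa_specs.items():
            base = get_value(self, name)  # raises on unknown name
            if abs(spec.mean - base) > 1e-9 * max(1.0, abs(base)):
                raise ValueError(
                    f"psa_specs[{name!r}].mean = {spec.mean} does not equal the base value {base}"
                )
            expect = "gamma" if name.startswith("costs.") else "beta"
            if spec.family != expect:
                raise ValueError(
                    f"psa_specs[{name!r}] must use the {expect} family, got {spec.family}"
                )
        return self


# ---------------------------------------------------------------------------
# Dotted-path access.  These names are the ones one_way and draw_psa accept.
# ---------------------------------------------------------------------------

_COST_NAMES = ("c_sdf", "c_naf", "c_exam", "c_xray", "c_access")
_STRATEGY_PROB_NAMES = ("p_incidence_tx", "p_extract_nocaries", "p_arrest", "p_extract_caries")


def parameter_names(params: Optional[ModelParameters] = None) -> list[str]:
    """All scalar parameter names addressable by :func:`get_value`/:func:`set_value`."""
    names = ["transition.p_init_caries", "transition.p_incidence_nat"]
    for arm in ("sdf", "naf"):
        names += [f"transition.{arm}.{p}" for p in _STRATEGY_PROB_NAMES]
    names += [f"costs.{c}" for c in _COST_NAMES]
    return names


def get_value(params: ModelParameters, name: str) -> float:
    """Return the scalar base value of a dotted parameter name."""
    parts = name.split(".")
    if parts[0] == "costs" and len(parts) == 2 and parts[1] in _COST_NAMES:
        return getattr(params.costs, parts[1]).base
    if parts[0] == "transition":
        if len(parts) == 2 and parts[1] in ("p_init_caries", "p_incidence_nat"):
            return getattr(params.transition, parts[1])
        if len(parts) == 3 and parts[1] in ("sdf", "naf") and parts[2] in _STRATEGY_PROB_NAMES:
            return getattr(getattr(params.transition, parts[1]), parts[2])
    raise ParameterError(f"unknown parameter name {name!r}")


def set_value(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one scalar replaced.

    Cost substitutions move the base value; the stored one-way range is widened
    if necessary so the range invariant keeps holding for values drawn outside
    it (as happens in the tails of gamma PSA draws).  The matching psa_spec, if
    any, is dropped from the copy because its mean no longer equals the base.
    """
    parts = name.split(".")
    specs = {k: v for k, v in params.psa_specs.items() if k != name}
    if parts[0] == "costs" and len(parts) == 2 and parts[1] in _COST_NAMES:
        if value < 0:
            raise ParameterError(f"{name} must be non-negative, got {value}")
        item: CostItem = getattr(params.costs, parts[1])
        new_item = CostItem(base=value, low=min(item.low, value), high=max(item.high, value))
        costs = params.costs.model_copy(update={parts[1]: new_item})
        return ModelParameters(
            transition=params.transition,
            costs=costs,
            utilities=params.utilities,
            settings=params.settings,
            psa_specs=specs,
        )
    if parts[0] == "transition":
        _check_prob(name, value)
        if len(parts) == 2 and parts[1] in ("p_init_caries", "p_incidence_nat"):
            tr = params.transition.model_copy(update={parts[1]: value})
            tr = TransitionProbabilities.model_validate(tr.model_dump())
        elif len(parts) == 3 and parts[1] in ("sdf", "naf") and parts[2] in _STRATEGY_PROB_NAMES:
            arm: StrategyTransitions = getattr(params.transition, parts[1])
            new_arm = StrategyTransitions.model_validate(
                {**arm.model_dump(), parts[2]: value}
            )
            tr = TransitionProbabilities.model_validate(
                {**params.transition.model_dump(), parts[1]: new_arm.model_dump()}
            )
        else:
            raise ParameterError(f"unknown parameter name {name!r}")
        return ModelParameters(
            transition=tr,
            costs=params.costs,
            utilities=params.utilities,
            settings=params.settings,
            psa_specs=specs,
        )
    raise ParameterError(f"unknown parameter name {name!r}")


def apply_values(params: ModelParameters, values: dict[str, float]) -> ModelParameters:
    """Return a copy with several scalars replaced atomically.

    Unlike chained :func:`set_value` calls, the branch-mass invariants are
    checked only on the final state, so jointly valid updates cannot fail on
    an invalid intermediate.  psa_specs of the touched parameters are dropped.
    """
    doc = params.model_dump()
    for name, value in values.items():
        get_value(params, name)  # raises on unknown name
        parts = name.split(".")
        if parts[0] == "costs":
            item = doc["costs"][parts[1]]
            item["base"] = value
            item["low"] = min(item["low"], value)
            item["high"] = max(item["high"], value)
        elif len(parts) == 2:
            doc["transition"][parts[1]] = value
        else:
            doc["transition"][parts[1]][parts[2]] = value
    doc["psa_specs"] = {k: v for k, v in doc["psa_specs"].items() if k not in values}
    try:
        return ModelParameters.model_validate(doc)
    except ValidationError as exc:
        raise ParameterError(f"invalid parameter update {sorted(values)}: {exc}") from exc


# ---------------------------------------------------------------------------
# Serialization: structured YAML and a flat CSV parameter table.
# ---------------------------------------------------------------------------


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a ModelParameters as a structured YAML document."""
    doc = params.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter file (YAML document or CSV table)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return load_parameter_table(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParameterError(f"malformed parameter file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParameterError(f"parameter file {path} does not contain a mapping")
    try:
        return ModelParameters.model_validate(doc)
    except ValidationError as exc:
        raise ParameterError(f"invalid parameter file {path}: {exc}") from exc


def save_parameter_table(params: ModelParameters, path: str | Path) -> None:
    """Write the scalar parameters as a flat CSV table.

    Columns: parameter, value, low, high, distribution — one row per scalar
    transition probability and unit cost, mirroring a supplementary-table
    layout.  Settings and utilities are not representable in this form and are
    carried by the structured YAML format instead.
    """
    rows = []
    for name in parameter_names():
        value = get_value(params, name)
        spec = params.psa_specs.get(name)
        if name.startswith("costs."):
            item: CostItem = getattr(params.costs, name.split(".")[1])
            low, high = item.low, item.high
        elif spec is not None:
            low, high = spec.ci95
        else:
            low = high = ""
        rows.append(
            {
                "parameter": name,
                "value": value,
                "low": low,
                "high": high,
                "distribution": spec.family if spec is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_parameter_table(
    path: str | Path, settings: Optional[EconomicSettings] = None
) -> ModelParameters:
    """Build ModelParameters from a flat CSV table (see save_parameter_table).

    Missing rows fall back to package defaults; settings and utilities take
    their defaults unless ``settings`` is supplied.
    """
    df = pd.read_csv(path)
    required = {"parameter", "value"}
    if not required.issubset(df.columns):
        raise ParameterError(f"parameter table {path} must have columns {sorted(required)}")
    values = dict(zip(df["parameter"].astype(str), df["value"].astype(float)))

    def take(name: str, default: float) -> float:
        return float(values.pop(name, default))

    tr = TransitionProbabilities(
        p_init_caries=take("transition.p_init_caries", 0.68),
        p_incidence_nat=take("transition.p_incidence_nat", 0.0),
        sdf=StrategyTransitions(
            p_incidence_tx=take("transition.sdf.p_incidence_tx", 0.0),
            p_extract_nocaries=take("transition.sdf.p_extract_nocaries", 0.0),
            p_arrest=take("transition.sdf.p_arrest", 0.0),
            p_extract_caries=take("transition.sdf.p_extract_caries", 0.0),
        ),
        naf=StrategyTransitions(
            p_incidence_tx=take("transition.naf.p_incidence_tx", 0.0),
            p_extract_nocaries=take("transition.naf.p_extract_nocaries", 0.0),
            p_arrest=take("transition.naf.p_arrest", 0.0),
            p_extract_caries=take("transition.naf.p_extract_caries", 0.0),
        ),
    )
    defaults = CostParameters()
    cost_items = {}
    low_col = dict(zip(df["parameter"].astype(str), df.get("low", pd.Series(dtype=float))))
    high_col = dict(zip(df["parameter"].astype(str), df.get("high", pd.Series(dtype=float))))
    for cname in _COST_NAMES:
        key = f"costs.{cname}"
        default_item: CostItem = getattr(defaults, cname)
        base = float(values.pop(key, default_item.base))
        low = low_col.get(key)
        high = high_col.get(key)
        low = default_item.low if low is None or pd.isna(low) else float(low)
        high = default_item.high if high is None or pd.isna(high) else float(high)
        cost_items[cname] = CostItem(base=base, low=min(low, base), high=max(high, base))
    if values:
        raise ParameterError(f"unknown parameter rows in {path}: {sorted(values)}")
    return ModelParameters(
        transition=tr,
        costs=CostParameters(**cost_items),
        settings=settings or EconomicSettings(),
    )
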