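"""Tooth-level Markov cost-effectiveness analysis of 38% silver diamine
fluoride (SDF) versus 5% sodium fluoride (NaF) varnish for high-risk root
caries: base case, one-way sensitivity analysis, and probabilistic
sensitivity analysis with cost-effectiveness acceptability curves."""

from importlib.resources import files

from .economics import (
    CEResult,
    StrategyResult,
    compare,
    discount_factor,
    evaluate_strategy,
    run_base_case,
)
from .markov import (
    Trajectory,
    initial_distribution,
    natural_history_step,
    relabel_cycle_start,
    run_cohort,
    simulate_microsim,
    treatment_step,
)
from .parameters import (
    DistributionSpec,
    EconomicSettings,
    HealthState,
    ModelParameters,
    ParameterError,
    Strategy,
    TransitionProbabilities,
    UtilityWeights,
    load_parameters,
    save_parameters,
)
from .sensitivity import (
    CeacCurve,
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
from .synthetic import (
    CalibrationResult,
    CalibrationTarget,
    calibrate_base_case,
    generate_parameter_set,
    observables,
    reference_targets,
)

__version__ = "0.1.0"

#: Packaged default parameter file: a synthetic, calibrated stand-in.
DEFAULT_PARAMS_RESOURCE = "data/default_synthetic_params.yaml"


def load_default_parameters() -> ModelParameters:
    """Load the packaged default (synthetic, calibrated) parameter set."""
    path = files("sdf_cea").joinpath(DEFAULT_PARAMS_RESOURCE)
    return load_parameters(str(path))
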