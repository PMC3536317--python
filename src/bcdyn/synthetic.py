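"""Synthetic inputs: random feasible parameter sets, ground-truth
scenarios, noisy observed trajectories and least-squares recovery.

No measured data exist for these models; every input the analysis
consumes is either a published parameter table or a trajectory the
models themselves generate.  This module makes that explicit and
testable: parameter sets are drawn uniformly from per-parameter
intervals (rejection-sampled against the validity constraints
sigma2 < sigma1 and alpha3 > alpha2), observations are forward
simulations plus additive Gaussian noise truncated at zero (the
simplest observation model consistent with nonnegative densities),
and recovery is bounded local least squares over a small free subset
of parameters.  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .models import InvalidInputError, rhs, validate_params
from .presets import DEFAULT_ESTROGEN_PARAMS, IC_ESTROGEN_PAPER, TABLE1_PARAMS

#: Half-width of the default sampling intervals, relative to the defaults.
DEFAULT_RANGE_HALFWIDTH = 0.2
#: Rejection-sampling budget before the ranges are declared infeasible.
MAX_DRAWS = 1000
#: Default number of observation times (equally spaced over (0, t_end]).
DEFAULT_N_OBS = 41
#: Default horizon for recovery scenarios (days): long enough for the
#: tumor and immune transients to express the rate constants.
DEFAULT_SCENARIO_T_END = 30.0


class InfeasibleRangesError(InvalidInputError):
    """Raised when rejection sampling exhausts its draw budget."""


@dataclass(frozen=True)
class Scenario:
    model: str
    true_params: object
    init: np.ndarray
    observation_times: np.ndarray
    noise_sd: float
    seed: int


@dataclass
class ObservedTrajectory:
    scenario: Scenario
    times: np.ndarray
    observed: np.ndarray   # noisy, truncated at zero
    truth: np.ndarray      # exact forward simulation at the same times


@dataclass
class RecoveryResult:
    params: object
    loss: float
    converged: bool
    free_names: tuple[str, ...] = ()
    n_evals: int = 0


def default_ranges(model: str) -> dict[str, tuple[float, float]]:
    """Per-parameter uniform sampling intervals: defaults +/- 20%.

    Centered on the published table for the estrogen-free rates and on
    the package defaults for the estrogen-specific ones.
    """
    base = TABLE1_PARAMS if model == "estrogen_free" else DEFAULT_ESTROGEN_PARAMS
    return {
        name: (v * (1 - DEFAULT_RANGE_HALFWIDTH), v * (1 + DEFAULT_RANGE_HALFWIDTH))
        for name, v in base.to_dict().items()
    }


def sample_parameter_set(ranges=None, model: str = "estrogen_free", seed: int = 0):
    """Draw one valid parameter set, uniformly and independently per rate.

    Draws are rejected until the full validity check passes (positivity,
    sigma2 < sigma1, alpha3 > alpha2); deterministic given ``seed``.
    Degenerate intervals [v, v] return v exactly.  After MAX_DRAWS
    rejections the ranges are declared infeasible.
    """
    if ranges is None:
        ranges = default_ranges(model)
    for name, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi or lo < 0:
            raise InvalidInputError(f"invalid interval for {name}: [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(MAX_DRAWS):
        draw = {
            name: lo if lo == hi else float(rng.uniform(lo, hi))
            for name, (lo, hi) in ranges.items()
        }
        try:
            return validate_params(draw, model)
        except InvalidInputError as err:
            last_err = err
    raise InfeasibleRangesError(
        f"no valid parameter set after {MAX_DRAWS} draws; last error: {last_err}"
    )


def default_scenario(
    model: str = "estrogen_free",
    seed: int = 0,
    noise_sd: float = 0.02,
    t_end: float = DEFAULT_SCENARIO_T_END,
) -> Scenario:
    """Ground-truth scenario at the canonical parameter values.

    The initial state starts the tumor at a detectable burden
    (T(0) = 0.1) rather than the near-extinct published value 1e-5:
    with a vanishing tumor the growth and predation rates leave no
    signature in the trajectory and no finite-noise fit could recover
    them.  Host starts at its normalized value 1 and immune at its
    source/death balance s/mu.
    """
    times = np.linspace(0.0, t_end, DEFAULT_N_OBS + 1)[1:]
    if model == "estrogen_free":
        params = TABLE1_PARAMS
        init = np.array([1.0, 0.1, TABLE1_PARAMS.s / TABLE1_PARAMS.mu])
    elif model == "estrogen":
        params = DEFAULT_ESTROGEN_PARAMS
        init = IC_ESTROGEN_PAPER
    else:
        raise InvalidInputError(f"unknown model {model!r}")
    return Scenario(model, params, init, times, float(noise_sd), int(seed))


def _simulate_at(params, init, times) -> np.ndarray:
    """Tight-tolerance forward simulation sampled on the observation grid."""
    t_end = float(times[-1])
    sol = solve_ivp(
        lambda t, y: rhs(params.model, y, params),
        (0.0, t_end),
        np.asarray(init, dtype=float),
        method="RK45",
        rtol=1e-10,
        atol=1e-12,
        t_eval=np.asarray(times, dtype=float),
    )
    if not sol.success:
        raise InvalidInputError(f"truth simulation failed: {sol.message}")
    return sol.y.T


def generate_observations(scenario: Scenario) -> ObservedTrajectory:
    """Truth trajectory at the observation times plus truncated noise.

    Noise is additive Gaussian with standard deviation ``noise_sd`` per
    compartment, truncated at zero; the noise stream is drawn from
    ``default_rng(seed)`` so identical scenarios give bitwise-identical
    observations.
    """
    if scenario.noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    times = np.asarray(scenario.observation_times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0) or times[0] <= 0:
        raise InvalidInputError("observation_times must be increasing and > 0")
    truth = _simulate_at(scenario.true_params, scenario.init, times)
    rng = np.random.default_rng(scenario.seed)
    noise = rng.normal(0.0, 1.0, size=truth.shape) * scenario.noise_sd
    observed = np.maximum(truth + noise, 0.0)
    return ObservedTrajectory(scenario, times, observed, truth)


def recover_parameters(
    observed: ObservedTrajectory,
    free_names,
    bounds: dict[str, tuple[float, float]] | None = None,
    init_guess: dict[str, float] | None = None,
) -> RecoveryResult:
    """Least-squares fit of a free parameter subset to noisy observations.

    Minimizes the sum of squared residuals between the forward
    simulation and the observed states over ``free_names``; all other
    parameters stay fixed at the scenario truth.  Bounds default to
    [truth/5, truth*5] clipped to the validity constraints; the initial
    guess defaults to the truth (callers probing identifiability should
    perturb it).  Non-convergence returns the best-found parameters
    with ``converged=False`` rather than raising.
    """
    scen = observed.scenario
    truth = scen.true_params
    free_names = tuple(free_names)
    valid = {f.name for f in fields(truth)}
    bad = set(free_names) - valid
    if bad:
        raise InvalidInputError(f"unknown parameter name(s): {sorted(bad)}")

    if not free_names:
        res = _simulate_at(truth, scen.init, observed.times) - observed.observed
        return RecoveryResult(truth, float(np.sum(res**2)), True, (), 1)

    truth_vals = {n: getattr(truth, n) for n in free_names}
    if bounds is None:
        bounds = {}
    lo = np.array([bounds.get(n, (truth_vals[n] / 5, truth_vals[n] * 5))[0]
                   for n in free_names])
    hi = np.array([bounds.get(n, (truth_vals[n] / 5, truth_vals[n] * 5))[1]
                   for n in free_names])
    x0 = np.array([
        (init_guess or {}).get(n, truth_vals[n]) for n in free_names
    ])
    x0 = np.clip(x0, lo, hi)

    def residuals(x):
        try:
            p = truth.replace(**dict(zip(free_names, x)))
            sim = _simulate_at(p, scen.init, observed.times)
        except InvalidInputError:
            return np.full(observed.observed.size, 1e6)
        return (sim - observed.observed).ravel()

    fit = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    fitted = truth.replace(**dict(zip(free_names, fit.x)))
    return RecoveryResult(
        fitted,
        float(np.sum(fit.fun**2)),
        bool(fit.status > 0),
        free_names,
        int(fit.nfev),
    )
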