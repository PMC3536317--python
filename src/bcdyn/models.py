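"""ODE right-hand sides, analytic Jacobians and parameter validation.

Both models track normalized, dimensionless cell densities.  The
estrogen-free model couples host cells H, tumor cells T and immune
effectors I through logistic growth, interspecific competition and a
Michaelis-Menten immune recruitment term:

    dH/dt = H (alpha1 - beta1 H - delta1 T)
    dT/dt = T (alpha2 - beta2 T) - gamma2 I T
    dI/dt = s + rho I T / (omega + T) - gamma3 I T - mu I

The estrogen model adds a 17-beta-estradiol compartment E with constant
source pi_src and first-order clearance theta.  Estrogen converts host
cells to tumor cells (sigma1 out of H, sigma2 into T, sigma2 < sigma1
because some damaged cells are immediately destroyed), raises the
intrinsic tumor growth rate to alpha3 > alpha2 (autocrine stimulation),
and suppresses the immune compartment through a saturating decay term
sigma3 I E / (upsilon + E):

    dH/dt = H (alpha1 - beta1 H - delta1 T) - sigma1 H E
    dT/dt = T (alpha3 - beta2 T) - gamma2 I T + sigma2 H E
    dI/dt = s + rho I T / (omega + T) - gamma3 I T - mu I
            - sigma3 I E / (upsilon + E)
    dE/dt = pi_src - theta E

All rates carry units of day^-1; omega and upsilon are half-saturation
constants in population / estrogen units.
"""

from __future__ import annotations

from dataclasses import MISSING, dataclass, fields
from typing import Mapping

import numpy as np

MODEL_IDS = ("estrogen_free", "estrogen")


class InvalidInputError(ValueError):
    """Raised for invalid states, parameters or model identifiers."""


@dataclass(frozen=True)
class EstrogenFreeParams:
    """Rate constants of the three-compartment (H, T, I) model.

    All rates are per day.  ``gamma3`` (immune inactivation by tumor
    contact) may be zero; every other rate must be strictly positive.
    """

    alpha1: float  # host per-capita growth rate
    beta1: float   # host self-limitation rate
    delta1: float  # host death rate from tumor competition
    alpha2: float  # tumor per-capita growth rate
    beta2: float   # tumor self-limitation rate
    gamma2: float  # tumor death rate from immune predation
    gamma3: float  # immune inactivation rate by tumor
    s: float       # constant immune source rate
    rho: float     # immune response (recruitment) rate
    omega: float   # immune half-saturation threshold
    mu: float      # immune natural death rate

    def __post_init__(self) -> None:
        _check_positive(self, allow_zero=("gamma3",))

    @property
    def model(self) -> str:
        return "estrogen_free"

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def replace(self, **kwargs: float) -> "EstrogenFreeParams":
        d = self.to_dict()
        d.update(kwargs)
        return type(self)(**d)


@dataclass(frozen=True)
class EstrogenParams(EstrogenFreeParams):
    """Rate constants of the four-compartment (H, T, I, E) model.

    In addition to the positivity constraints, two orderings are
    enforced: ``sigma2 < sigma1`` (only part of the estrogen-damaged
    host cells become established tumor cells) and ``alpha3 > alpha2``
    (autocrine estrogen stimulation adds to natural tumor growth).
    ``pi_src`` may be zero (no exogenous estrogen).
    """

    alpha3: float = 1.0    # tumor growth rate under autocrine stimulation
    sigma1: float = 0.3    # host DNA-damage (conversion-out) rate per estrogen unit
    sigma2: float = 0.2    # tumor-formation (conversion-in) rate per estrogen unit
    sigma3: float = 0.1    # immune suppression rate by estrogen
    upsilon: float = 0.5   # estrogen half-saturation threshold
    pi_src: float = 0.2    # constant estrogen source
    theta: float = 0.97    # estrogen clearance rate

    def __post_init__(self) -> None:
        _check_positive(self, allow_zero=("gamma3", "pi_src"))
        if not self.sigma2 < self.sigma1:
            raise InvalidInputError(
                f"constraint sigma2 < sigma1 violated: "
                f"sigma2={self.sigma2}, sigma1={self.sigma1}"
            )
        if not self.alpha3 > self.alpha2:
            raise InvalidInputError(
                f"constraint alpha3 > alpha2 violated: "
                f"alpha3={self.alpha3}, alpha2={self.alpha2}"
            )

    @property
    def model(self) -> str:
        return "estrogen"


def _check_positive(params, allow_zero=()) -> None:
    for f in fields(params):
        v = getattr(params, f.name)
        if not np.isfinite(v):
            raise InvalidInputError(f"parameter {f.name} is not finite: {v!r}")
        if f.name in allow_zero:
            if v < 0:
                raise InvalidInputError(
                    f"parameter {f.name} must be >= 0, got {v}"
                )
        elif v <= 0:
            raise InvalidInputError(
                f"parameter {f.name} must be strictly positive, got {v}"
            )


PARAM_CLASSES = {"estrogen_free": EstrogenFreeParams, "estrogen": EstrogenParams}


def validate_params(raw: Mapping[str, float], model: str):
    """Build a validated parameter set from a flat name -> value mapping.

    Raises :class:`InvalidInputError` naming the violated constraint
    (missing field, non-positive rate, sigma2 >= sigma1, alpha3 <= alpha2)
    or an unknown model id.
    """
    if model not in PARAM_CLASSES:
        raise InvalidInputError(
            f"unknown model {model!r}; expected one of {MODEL_IDS}"
        )
    cls = PARAM_CLASSES[model]
    names = {f.name for f in fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise InvalidInputError(f"unknown parameter(s): {sorted(unknown)}")
    missing = [
        f.name
        for f in fields(cls)
        if f.name not in raw and f.default is MISSING
    ]
    if missing:
        raise InvalidInputError(f"missing parameter(s): {missing}")
    return cls(**{k: float(v) for k, v in raw.items()})


def _check_state(state: np.ndarray, n: int) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (n,):
        raise InvalidInputError(f"state must have shape ({n},), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise InvalidInputError(f"non-finite state: {state}")
    return state


def rhs_estrogen_free(state, params: EstrogenFreeParams) -> np.ndarray:
    """Time derivative (dH/dt, dT/dt, dI/dt) of the estrogen-free model."""
    H, T, I = _check_state(state, 3)
    p = params
    dH = H * (p.alpha1 - p.beta1 * H - p.delta1 * T)
    dT = T * (p.alpha2 - p.beta2 * T) - p.gamma2 * I * T
    dI = p.s + p.rho * I * T / (p.omega + T) - p.gamma3 * I * T - p.mu * I
    return np.array([dH, dT, dI])


def rhs_estrogen(state, params: EstrogenParams) -> np.ndarray:
    """Time derivative (dH/dt, dT/dt, dI/dt, dE/dt) of the estrogen model."""
    H, T, I, E = _check_state(state, 4)
    p = params
    dH = H * (p.alpha1 - p.beta1 * H - p.delta1 * T) - p.sigma1 * H * E
    dT = T * (p.alpha3 - p.beta2 * T) - p.gamma2 * I * T + p.sigma2 * H * E
    dI = (
        p.s
        + p.rho * I * T / (p.omega + T)
        - p.gamma3 * I * T
        - p.mu * I
        - p.sigma3 * I * E / (p.upsilon + E)
    )
    dE = p.pi_src - p.theta * E
    return np.array([dH, dT, dI, dE])


def rhs(model: str, state, params) -> np.ndarray:
    """Dispatch the RHS by model id ("estrogen_free" or "estrogen")."""
    if model == "estrogen_free":
        return rhs_estrogen_free(state, params)
    if model == "estrogen":
        return rhs_estrogen(state, params)
    raise InvalidInputError(f"unknown model {model!r}; expected one of {MODEL_IDS}")


def jacobian(model: str, state, params) -> np.ndarray:
    """Analytic Jacobian of the chosen model's RHS at ``state``.

    3x3 for the estrogen-free model, 4x4 (ordering H, T, I, E) for the
    estrogen model.
    """
    p = params
    if model == "estrogen_free":
        H, T, I = _check_state(state, 3)
        return np.array(
            [
                [p.alpha1 - 2 * p.beta1 * H - p.delta1 * T, -p.delta1 * H, 0.0],
                [0.0, p.alpha2 - 2 * p.beta2 * T - p.gamma2 * I, -p.gamma2 * T],
                [
                    0.0,
                    p.rho * I * p.omega / (p.omega + T) ** 2 - p.gamma3 * I,
                    p.rho * T / (p.omega + T) - p.gamma3 * T - p.mu,
                ],
            ]
        )
    if model == "estrogen":
        H, T, I, E = _check_state(state, 4)
        return np.array(
            [
                [
                    p.alpha1 - 2 * p.beta1 * H - p.delta1 * T - p.sigma1 * E,
                    -p.delta1 * H,
                    0.0,
                    -p.sigma1 * H,
                ],
                [
                    p.sigma2 * E,
                    p.alpha3 - 2 * p.beta2 * T - p.gamma2 * I,
                    -p.gamma2 * T,
                    p.sigma2 * H,
                ],
                [
                    0.0,
                    p.rho * I * p.omega / (p.omega + T) ** 2 - p.gamma3 * I,
                    p.rho * T / (p.omega + T)
                    - p.gamma3 * T
                    - p.mu
                    - p.sigma3 * E / (p.upsilon + E),
                    -p.sigma3 * I * p.upsilon / (p.upsilon + E) ** 2,
                ],
                [0.0, 0.0, 0.0, -p.theta],
            ]
        )
    raise InvalidInputError(f"unknown model {model!r}; expected one of {MODEL_IDS}")
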