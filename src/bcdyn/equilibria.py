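"""Equilibria of both models: closed forms, coupled scalar root-finds,
feasibility and existence-condition checks.

Taxonomy (shared across models):

* ``tumor_free`` — tumor extinct, host and immune cells persist.
* ``dead2``      — host and tumor both extinct (tissue removal).
* ``dead1``      — host extinct, tumor persists.
* ``coexisting`` — all compartments strictly positive.

An :class:`Equilibrium` is *feasible* only when its coordinates are
finite and nonnegative, its label-specific existence conditions hold,
and the scaled RHS residual is below ``RESIDUAL_TOL`` — i.e. it is an
actual fixed point of the implemented vector field.  States that the
closed-form algebra produces but that do not zero the vector field
(notably the estrogen-model tumor-free state for a positive estrogen
source, where the conversion influx sigma2*H*E never vanishes, and the
host-free state built from the published quadratic, whose root is a
pole of the immune coordinate) are still returned, with their failed
conditions and honest residuals attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .models import rhs

#: Scaled-residual threshold below which a state counts as a fixed point.
RESIDUAL_TOL = 1e-10

#: Tolerance on coordinate nonnegativity (root-finding round-off).
NONNEG_TOL = 1e-12

_BRACKET_EPS = 1e-12
_SCAN_POINTS = 2001


@dataclass(frozen=True)
class Condition:
    """A named existence/feasibility check with its signed margin.

    ``margin`` > 0 means the condition holds with room to spare; the
    exact meaning of the number is condition-specific (documented where
    each condition is built).
    """

    name: str
    satisfied: bool
    margin: float


@dataclass
class Equilibrium:
    label: str                 # tumor_free | dead1 | dead2 | coexisting
    model: str                 # estrogen_free | estrogen
    state: np.ndarray          # (H, T, I[, E])
    feasible: bool
    conditions: list[Condition] = field(default_factory=list)
    residual: float = math.nan
    branch: str | None = None  # quadratic-branch tag where applicable

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "model": self.model,
            "state": [float(x) for x in self.state],
            "feasible": bool(self.feasible),
            "residual": float(self.residual),
            "branch": self.branch,
            "conditions": [
                {"name": c.name, "satisfied": bool(c.satisfied), "margin": float(c.margin)}
                for c in self.conditions
            ],
        }


def scaled_residual(state, params) -> float:
    """max |RHS| scaled by max(1, |state|_inf); inf for non-finite states."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        return math.inf
    r = rhs(params.model, state, params)
    return float(np.max(np.abs(r)) / max(1.0, np.max(np.abs(state))))


def _finalize(label, params, state, conditions=(), branch=None, required=None) -> Equilibrium:
    """Assemble an Equilibrium: residual, nonnegativity, feasibility."""
    state = np.asarray(state, dtype=float)
    res = scaled_residual(state, params)
    finite = bool(np.all(np.isfinite(state)))
    nonneg = finite and bool(np.min(state) >= -NONNEG_TOL)
    conditions = list(conditions)
    conditions.append(
        Condition(
            "coordinates_nonnegative",
            nonneg,
            float(np.min(state)) if finite else -math.inf,
        )
    )
    conditions.append(
        Condition("fixed_point_residual", res < RESIDUAL_TOL, RESIDUAL_TOL - res)
    )
    if required is None:
        required = [c.name for c in conditions]
    feasible = nonneg and res < RESIDUAL_TOL and all(
        c.satisfied for c in conditions if c.name in required
    )
    return Equilibrium(label, params.model, state, feasible, conditions, res, branch)


# ---------------------------------------------------------------------------
# scalar root scanning
# ---------------------------------------------------------------------------

def _safe(f, t):
    try:
        v = f(t)
    except (ZeroDivisionError, FloatingPointError, OverflowError):
        return math.nan
    return v if np.isfinite(v) else math.nan


def _scan_roots(f, lo, hi, n=_SCAN_POINTS):
    """All sign-change roots of ``f`` on [lo, hi] from a uniform scan.

    Intervals where f is non-finite (poles of the immune coordinate)
    are skipped; duplicates closer than 1e-9 are merged.
    """
    ts = np.linspace(lo, hi, n)
    vals = np.array([_safe(f, t) for t in ts])
    roots: list[float] = []
    for i in range(n - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(float(ts[i]))
        elif a * b < 0.0:
            roots.append(float(brentq(lambda t: _safe(f, t), ts[i], ts[i + 1],
                                      xtol=1e-12, rtol=8.9e-16)))
    if np.isfinite(vals[-1]) and vals[-1] == 0.0:
        roots.append(float(ts[-1]))
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 1e-9:
            merged.append(r)
    return merged


# ---------------------------------------------------------------------------
# tumor-free equilibrium
# ---------------------------------------------------------------------------

def tumor_free_equilibrium(params) -> Equilibrium:
    """Tumor-free steady state.

    Estrogen-free: (alpha1/beta1, 0, s/mu); always a fixed point.

    Estrogen model: the published closed form E = pi_src/theta,
    H = (alpha1 - sigma1 E)/beta1, I = s(E+upsilon)/(mu(E+upsilon) +
    sigma3 E), T = 0, which requires E <= alpha1/sigma1 for H >= 0.
    For pi_src > 0 this state is a quasi-equilibrium only: the tumor
    influx sigma2*H*E is positive at T = 0, so the residual gate marks
    it infeasible (see the ``zero_tumor_influx`` condition).
    """
    p = params
    if p.model == "estrogen_free":
        state = [p.alpha1 / p.beta1, 0.0, p.s / p.mu]
        return _finalize("tumor_free", p, state, [])
    E = p.pi_src / p.theta
    H = (p.alpha1 - p.sigma1 * E) / p.beta1
    I = p.s * (E + p.upsilon) / (p.mu * (E + p.upsilon) + p.sigma3 * E)
    influx = p.sigma2 * H * E
    bound = math.inf if p.sigma1 == 0 else p.alpha1 / p.sigma1
    conds = [
        Condition("E_le_alpha1_over_sigma1", E <= bound, bound - E),
        Condition("zero_tumor_influx", abs(influx) < RESIDUAL_TOL, -abs(influx)),
    ]
    return _finalize("tumor_free", p, [H, 0.0, I, E], conds)


# ---------------------------------------------------------------------------
# dead equilibria
# ---------------------------------------------------------------------------

def _immune_coordinate_estrogen_free(T, p):
    denom = p.mu - p.rho * T / (p.omega + T) + p.gamma3 * T
    if denom == 0.0:
        return math.inf
    return p.s / denom


def _immune_coordinate_estrogen(T, p, E):
    denom = (
        p.mu
        + p.sigma3 * E / (p.upsilon + E)
        - p.rho * T / (p.omega + T)
        + p.gamma3 * T
    )
    if denom == 0.0:
        return math.inf
    return p.s / denom


def dead_equilibria(params) -> list[Equilibrium]:
    """Host-free steady states, dead2 (tissue removal) first.

    Estrogen-free dead1 follows the published construction: T* is a
    root of u1 T^2 + u2 T + u3 = 0 with u1 = gamma3,
    u2 = mu + omega*gamma3 - rho, u3 = mu*omega (real roots require
    u2 < 0 and u2^2 >= 4 u1 u3), and I* = s / (mu - rho T*/(omega+T*)
    + gamma3 T*).  The quadratic factors as (omega+T) times the
    immune-coordinate denominator, so its root is a pole of I*: the
    published state has no finite immune coordinate and is reported
    infeasible.  Both quadratic branches are returned, the published
    "+sqrt" branch first (``branch="plus"``).

    Estrogen model: dead2 = (0, 0, I, E) with the estrogen-suppressed
    immune level (always a fixed point), and dead1 = (0, T, I, E) with
    T solved self-consistently from T = (alpha3 - gamma2 I(T))/beta2
    (the published form carries a sign flip, recorded in the docs).
    """
    p = params
    out: list[Equilibrium] = []
    if p.model == "estrogen_free":
        out.append(_finalize("dead2", p, [0.0, 0.0, p.s / p.mu], []))
        u1, u2, u3 = p.gamma3, p.mu + p.omega * p.gamma3 - p.rho, p.mu * p.omega
        disc = u2 * u2 - 4.0 * u1 * u3
        conds = [
            Condition("u2_negative", u2 < 0.0, -u2),
            Condition("discriminant_nonnegative", disc >= 0.0, disc),
        ]
        roots: list[tuple[float, str]] = []
        if u1 > 0.0 and disc >= 0.0:
            roots.append(((-u2 + math.sqrt(disc)) / (2.0 * u1), "plus"))
            roots.append(((-u2 - math.sqrt(disc)) / (2.0 * u1), "minus"))
        elif u1 == 0.0 and u2 != 0.0:
            roots.append((-u3 / u2, "linear"))
        if not roots:
            state = [0.0, math.nan, math.nan]
            out.append(
                Equilibrium("dead1", p.model, np.asarray(state), False,
                            conds, math.inf, "plus")
            )
        for T, branch in roots:
            I = _immune_coordinate_estrogen_free(T, p)
            out.append(_finalize("dead1", p, [0.0, T, I], conds, branch=branch))
        return out

    E = p.pi_src / p.theta
    I_removed = p.s * (E + p.upsilon) / (p.mu * (E + p.upsilon) + p.sigma3 * E)
    out.append(_finalize("dead2", p, [0.0, 0.0, I_removed, E]))

    def f(T):
        return T - (p.alpha3 - p.gamma2 * _immune_coordinate_estrogen(T, p, E)) / p.beta2

    roots = _scan_roots(f, _BRACKET_EPS, p.alpha3 / p.beta2)
    if not roots:
        out.append(
            Equilibrium(
                "dead1", p.model, np.array([0.0, math.nan, math.nan, E]), False,
                [Condition("no_root_in_bracket", False, math.nan)], math.inf,
            )
        )
    for T in roots:
        I = _immune_coordinate_estrogen(T, p, E)
        conds = [
            Condition(
                "I_lt_alpha3_over_gamma2",
                I < p.alpha3 / p.gamma2,
                p.alpha3 / p.gamma2 - I,
            ),
        ]
        out.append(_finalize("dead1", p, [0.0, T, I, E], conds,
                             required=["coordinates_nonnegative",
                                       "fixed_point_residual"]))
    return out


# ---------------------------------------------------------------------------
# coexisting equilibria
# ---------------------------------------------------------------------------

def coexisting_equilibria(params) -> list[Equilibrium]:
    """Interior steady states with all compartments positive.

    The tumor and immune coordinates are mutually coupled, so the
    system is reduced to one scalar equation in T and solved by a
    bracketed scan-and-refine (bisection bracketing, Brent refinement):

    * estrogen-free:  T = (alpha2 - gamma2 I(T)) / beta2 with
      I(T) = s / (mu - rho T/(omega+T) + gamma3 T); bracket
      (1e-12, alpha2/beta2].  H = (alpha1 - delta1 T)/beta1.
    * estrogen:  I(T) additionally carries the estrogen suppression
      term; T is the "+sqrt" root of the quadratic
      beta1 beta2 T^2 + B T - sigma2 E (alpha1 - sigma1 E) = 0,
      B = -alpha3 beta1 + beta1 gamma2 I + delta1 sigma2 E, solved
      self-consistently in I(T).  H = (alpha1 - delta1 T - sigma1 E)/beta1.

    Every sign-change root in the bracket is returned (ordered by T);
    when none exists a single infeasible record with condition
    ``no_root_in_bracket`` is returned.
    """
    p = params
    if p.model == "estrogen_free":
        def f(T):
            I = _immune_coordinate_estrogen_free(T, p)
            return T - (p.alpha2 - p.gamma2 * I) / p.beta2

        roots = _scan_roots(f, _BRACKET_EPS, p.alpha2 / p.beta2)
        out = []
        for T in roots:
            I = _immune_coordinate_estrogen_free(T, p)
            H = (p.alpha1 - p.delta1 * T) / p.beta1
            thr = (p.alpha2 * p.delta1 - p.alpha1 * p.beta2) / (p.gamma2 * p.delta1)
            conds = [
                # published lower bound on I* for H* >= 0
                Condition("immune_above_coexistence_threshold", thr <= I, I - thr),
                # published requirement for a positive I*: net tumor growth
                # must exceed net host growth
                Condition(
                    "tumor_net_growth_ge_host",
                    p.alpha2 / p.beta2 >= p.alpha1 / p.delta1,
                    p.alpha2 / p.beta2 - p.alpha1 / p.delta1,
                ),
            ]
            out.append(
                _finalize("coexisting", p, [H, T, I], conds,
                          required=["coordinates_nonnegative",
                                    "fixed_point_residual"])
            )
        if not out:
            out.append(
                Equilibrium(
                    "coexisting", p.model,
                    np.array([math.nan, math.nan, math.nan]), False,
                    [Condition("no_root_in_bracket", False, math.nan)], math.inf,
                )
            )
        return out

    E = p.pi_src / p.theta
    c = -p.sigma2 * E * (p.alpha1 - p.sigma1 * E)
    a = p.beta1 * p.beta2

    def t_quad(I):
        B = -p.alpha3 * p.beta1 + p.beta1 * p.gamma2 * I + p.delta1 * p.sigma2 * E
        disc = B * B - 4.0 * a * c
        if disc < 0.0:
            return math.nan
        return (-B + math.sqrt(disc)) / (2.0 * a)

    def f(T):
        I = _immune_coordinate_estrogen(T, p, E)
        return T - t_quad(I)

    B0 = -p.alpha3 * p.beta1 + p.delta1 * p.sigma2 * E  # I = 0: largest root
    disc0 = B0 * B0 - 4.0 * a * min(c, 0.0)
    t_hi = (-B0 + math.sqrt(max(disc0, 0.0))) / (2.0 * a) + 1.0
    roots = _scan_roots(f, _BRACKET_EPS, max(t_hi, p.alpha3 / p.beta2 + 1.0))
    out = []
    for T in roots:
        I = _immune_coordinate_estrogen(T, p, E)
        H = (p.alpha1 - p.delta1 * T - p.sigma1 * E) / p.beta1
        conds = [
            # published positivity condition on T: E = 0 or E >= alpha1/sigma1
            Condition(
                "E_zero_or_ge_alpha1_over_sigma1",
                E == 0.0 or E >= p.alpha1 / p.sigma1,
                0.0 if E == 0.0 else E - p.alpha1 / p.sigma1,
            ),
            # immune denominator positive (published existence condition)
            Condition(
                "immune_denominator_positive",
                _immune_denominator_estrogen(T, p, E) > 0.0,
                _immune_denominator_estrogen(T, p, E),
            ),
            # H >= 0: alpha1 >= delta1 T + sigma1 E
            Condition(
                "host_growth_covers_losses",
                p.alpha1 >= p.delta1 * T + p.sigma1 * E,
                p.alpha1 - p.delta1 * T - p.sigma1 * E,
            ),
        ]
        out.append(
            _finalize("coexisting", p, [H, T, I, E], conds,
                      required=["coordinates_nonnegative",
                                "fixed_point_residual"])
        )
    if not out:
        out.append(
            Equilibrium(
                "coexisting", p.model,
                np.array([math.nan, math.nan, math.nan, E]), False,
                [Condition("no_root_in_bracket", False, math.nan)], math.inf,
            )
        )
    return out


def _immune_denominator_estrogen(T, p, E):
    return (
        p.mu
        + p.sigma3 * E / (p.upsilon + E)
        - p.rho * T / (p.omega + T)
        + p.gamma3 * T
    )


def all_equilibria(params) -> list[Equilibrium]:
    """All equilibria, fixed order: tumor_free, dead2, dead1..., coexisting...

    Parameter validation errors propagate from the parameter set itself.
    """
    dead = dead_equilibria(params)
    dead2 = [e for e in dead if e.label == "dead2"]
    dead1 = [e for e in dead if e.label == "dead1"]
    return [tumor_free_equilibrium(params), *dead2, *dead1, *coexisting_equilibria(params)]
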