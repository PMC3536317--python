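"""Forward integration and long-run outcome classification.

Trajectories are produced by an adaptive Runge-Kutta 4(5) integrator
(scipy's RK45) at tight default tolerances (rtol 1e-8, atol 1e-10).
The nonnegative orthant is forward-invariant for both vector fields,
so negative values can only come from the solver: undershoot beyond
-1e-8 in any compartment is an error (clipping would mask model or
solver bugs); smaller undershoot is tolerated and recorded in the
trajectory's warnings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium
from .models import InvalidInputError, rhs

#: Solver defaults.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: Terminal tumor burden below which the tumor counts as cleared.
DEFAULT_CLEARANCE_THRESHOLD = 1e-6
#: Relative distance within which a terminal state matches an equilibrium.
DEFAULT_MATCH_TOL = 1e-3
#: Tolerated numerical undershoot below zero.
UNDERSHOOT_TOL = 1e-8
#: Minimum number of saved points.
MIN_SAVED_POINTS = 200


class SolverError(RuntimeError):
    """Integration failure (step underflow or intolerable undershoot)."""


@dataclass
class Trajectory:
    model: str
    params: object
    times: np.ndarray          # days, strictly increasing
    states: np.ndarray         # (n_times, n_compartments)
    solver_meta: dict = field(default_factory=dict)

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]

    def component(self, name: str) -> np.ndarray:
        names = "HTIE"[: self.states.shape[1]]
        return self.states[:, names.index(name)]


@dataclass
class OutcomeLabel:
    label: str                          # tumor_clearance | tumor_escape |
                                        # coexistence | host_extinction | undecided
    terminal_state: np.ndarray
    matched_equilibrium: str | None = None
    distance: float = math.nan


def integrate(
    params,
    init,
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int | None = None,
) -> Trajectory:
    """Integrate the model owned by ``params`` from ``init`` to ``t_end``.

    Saves max(MIN_SAVED_POINTS + 1, n_points) equally spaced points
    including t = 0.  Raises :class:`SolverError` on integrator failure
    (naming the failing time) or when any component undershoots below
    -1e-8.
    """
    model = params.model
    init = np.asarray(init, dtype=float)
    expected = 3 if model == "estrogen_free" else 4
    if init.shape != (expected,):
        raise InvalidInputError(
            f"init must have shape ({expected},) for model {model!r}"
        )
    if not np.all(np.isfinite(init)) or np.min(init) < -UNDERSHOOT_TOL:
        raise InvalidInputError(f"init must be finite and nonnegative: {init}")
    if not t_end > 0:
        raise InvalidInputError(f"t_end must be positive, got {t_end}")
    n = max(MIN_SAVED_POINTS + 1, n_points or 0)
    t_eval = np.linspace(0.0, float(t_end), n)
    sol = solve_ivp(
        lambda t, y: rhs(model, y, params),
        (0.0, float(t_end)),
        init,
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise SolverError(f"integration failed at t = {t_fail:.6g}: {sol.message}")
    states = sol.y.T
    warnings: list[str] = []
    min_val = float(states.min())
    if min_val < -UNDERSHOOT_TOL:
        i, j = np.unravel_index(np.argmin(states), states.shape)
        raise SolverError(
            f"component {'HTIE'[j]} undershot to {min_val:.3e} at "
            f"t = {sol.t[i]:.6g} (beyond tolerated -1e-8)"
        )
    if min_val < 0.0:
        warnings.append(f"numerical undershoot to {min_val:.3e} (within tolerance)")
    meta = {
        "method": "RK45",
        "rtol": rtol,
        "atol": atol,
        "n_steps": int(sol.t.size),
        "n_rhs_evals": int(sol.nfev),
        "warnings": warnings,
    }
    return Trajectory(model, params, sol.t, states, meta)


def estrogen_closed_form(E0: float, pi_src: float, theta: float, t):
    """Exact estrogen level: pi/theta + (E0 - pi/theta) * exp(-theta t).

    The estrogen equation dE/dt = pi - theta E is decoupled and linear,
    so this closed form is an independent oracle for the integrator.
    """
    if not theta > 0:
        raise InvalidInputError(f"theta must be positive, got {theta}")
    t = np.asarray(t, dtype=float)
    Einf = pi_src / theta
    return Einf + (E0 - Einf) * np.exp(-theta * t)


def classify_outcome(
    traj: Trajectory,
    equilibria: list[Equilibrium],
    clearance_threshold: float = DEFAULT_CLEARANCE_THRESHOLD,
    match_tol: float = DEFAULT_MATCH_TOL,
) -> OutcomeLabel:
    """Label the long-run outcome by terminal-state proximity.

    Precedence: tumor_clearance > host_extinction > coexistence >
    tumor_escape > undecided.  ``tumor_escape`` requires the terminal
    tumor burden to exceed every feasible equilibrium's tumor
    coordinate by the match tolerance with a nonnegative dT/dt at the
    end of the run.  With no equilibria supplied the outcome is
    undecided.
    """
    terminal = traj.terminal_state
    T_end = terminal[1]
    feas = [e for e in equilibria if e.feasible and np.all(np.isfinite(e.state))]

    def rel_dist(eq):
        scale = max(1.0, float(np.max(np.abs(eq.state))))
        return float(np.max(np.abs(terminal - eq.state)) / scale)

    by_label: dict[str, tuple[float, Equilibrium]] = {}
    for e in feas:
        d = rel_dist(e)
        if e.label not in by_label or d < by_label[e.label][0]:
            by_label[e.label] = (d, e)

    if "tumor_free" in by_label:
        d, _ = by_label["tumor_free"]
        if T_end < clearance_threshold and d < match_tol:
            return OutcomeLabel("tumor_clearance", terminal, "tumor_free", d)
    for lbl in ("dead2", "dead1"):
        if lbl in by_label:
            d, _ = by_label[lbl]
            if terminal[0] < clearance_threshold and d < match_tol:
                return OutcomeLabel("host_extinction", terminal, lbl, d)
    if "coexisting" in by_label:
        d, _ = by_label["coexisting"]
        if d < match_tol:
            return OutcomeLabel("coexistence", terminal, "coexisting", d)
    if feas:
        exceeds_all = all(
            T_end > e.state[1] + match_tol * max(1.0, abs(e.state[1]))
            for e in feas
        )
        dTdt = rhs(traj.model, terminal, traj.params)[1]
        if exceeds_all and dTdt >= 0.0:
            best = min((rel_dist(e) for e in feas), default=math.nan)
            return OutcomeLabel("tumor_escape", terminal, None, best)
    best = min((rel_dist(e) for e in feas), default=math.nan)
    return OutcomeLabel("undecided", terminal, None, best)
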