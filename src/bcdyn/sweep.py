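"""Parameter sweeps and stability-boundary location.

The primary sweep varies the constant estrogen source rate pi_src over
a grid, re-solving equilibria, the tumor-free linearisation and a full
simulation at every grid point.  The dose-response conclusion under
test: terminal tumor burden grows with the estrogen source while host
and immune levels shrink.

``find_stability_boundary`` bisects on the leading (largest real part)
eigenvalue of the tumor-free Jacobian as a function of one parameter.
For the estrogen-free model varied in alpha2 the boundary has the
closed form alpha2 = s*gamma2/mu, which serves as the analytic check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import all_equilibria, tumor_free_equilibrium
from .models import InvalidInputError, jacobian
from .presets import DEFAULT_PI_GRID, DEFAULT_T_END, IC_ESTROGEN_PAPER
from .simulate import SolverError, classify_outcome, integrate

#: Bisection half-width at which a boundary estimate is accepted.
BOUNDARY_TOL = 1e-8


@dataclass
class SweepResult:
    swept_parameter: str
    grid: np.ndarray
    records: list[dict] = field(default_factory=list)
    boundary_estimates: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def terminal(self) -> pd.DataFrame:
        cols = ["H_end", "T_end", "I_end", "E_end"]
        return self.to_frame()[[self.swept_parameter, *cols]]

    def _terminal_monotone(self, col: str, direction: int) -> bool:
        v = self.to_frame()[col].to_numpy()
        v = v[np.isfinite(v)]
        return bool(np.all(direction * np.diff(v) >= 0))

    @property
    def tumor_nondecreasing(self) -> bool:
        """Whether terminal tumor burden is non-decreasing along the grid."""
        return self._terminal_monotone("T_end", +1)

    @property
    def host_nonincreasing(self) -> bool:
        return self._terminal_monotone("H_end", -1)

    @property
    def immune_nonincreasing(self) -> bool:
        return self._terminal_monotone("I_end", -1)


def leading_tumor_free_eigenvalue(params) -> float:
    """Largest real part over the tumor-free Jacobian's spectrum."""
    eq = tumor_free_equilibrium(params)
    if not np.all(np.isfinite(eq.state)):
        return math.nan
    J = jacobian(params.model, eq.state, params)
    return float(np.max(np.linalg.eigvals(J).real))


def sweep_estrogen_source(
    base_params,
    pi_values=None,
    init=None,
    t_end: float | None = None,
) -> SweepResult:
    """Estrogen-dose sweep: one record per source rate pi.

    Each record carries the tumor-free existence condition
    (E = pi/theta against alpha1/sigma1), the leading tumor-free
    eigenvalue, the simulated outcome label and the terminal state.
    Per-point solver failures are recorded and the sweep continues.
    Boundary estimates are bisection refinements between grid points
    whose leading eigenvalues change sign.
    """
    if base_params.model != "estrogen":
        raise InvalidInputError("sweep_estrogen_source requires estrogen-model params")
    pi_values = np.asarray(
        DEFAULT_PI_GRID if pi_values is None else pi_values, dtype=float
    )
    if pi_values.ndim != 1 or pi_values.size < 2:
        raise InvalidInputError("pi_values must contain at least 2 points")
    if np.any(np.diff(pi_values) <= 0):
        raise InvalidInputError("pi_values must be strictly increasing")
    if pi_values[0] < 0:
        raise InvalidInputError("pi_values must be nonnegative")
    init = IC_ESTROGEN_PAPER if init is None else np.asarray(init, dtype=float)
    t_end = DEFAULT_T_END["estrogen"] if t_end is None else float(t_end)

    records: list[dict] = []
    leading: list[float] = []
    for pi in pi_values:
        p = base_params.replace(pi_src=float(pi))
        eqs = all_equilibria(p)
        tf = next(e for e in eqs if e.label == "tumor_free")
        lead = leading_tumor_free_eigenvalue(p)
        leading.append(lead)
        rec: dict = {
            "pi_src": float(pi),
            "E_star": float(pi / p.theta),
            "tumor_free_feasible": bool(tf.feasible),
            "tumor_free_condition_E_le_alpha1_over_sigma1": bool(
                tf.condition("E_le_alpha1_over_sigma1").satisfied
            ),
            "leading_tumor_free_eigenvalue": lead,
            "n_feasible_equilibria": int(sum(e.feasible for e in eqs)),
        }
        try:
            traj = integrate(p, init, t_end)
        except SolverError as exc:
            rec.update(
                outcome="solver_failure",
                solver_error=str(exc),
                H_end=math.nan,
                T_end=math.nan,
                I_end=math.nan,
                E_end=math.nan,
            )
        else:
            outcome = classify_outcome(traj, eqs)
            H, T, I, E = traj.terminal_state
            rec.update(
                outcome=outcome.label,
                solver_error="",
                H_end=float(H),
                T_end=float(T),
                I_end=float(I),
                E_end=float(E),
            )
        records.append(rec)

    boundaries = _refine_sign_changes(
        lambda pi: leading_tumor_free_eigenvalue(base_params.replace(pi_src=pi)),
        pi_values,
        leading,
    )
    result = SweepResult("pi_src", pi_values, records, boundaries)
    return result


def _refine_sign_changes(f, grid, values) -> list[float]:
    out = []
    for i in range(len(grid) - 1):
        a, b = values[i], values[i + 1]
        if np.isfinite(a) and np.isfinite(b) and a * b < 0:
            out.append(_bisect(f, float(grid[i]), float(grid[i + 1])))
    return out


def _bisect(f, lo, hi, tol=BOUNDARY_TOL) -> float:
    flo = f(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def find_stability_boundary(params, param_name: str, lo: float, hi: float) -> float:
    """Critical parameter value where the tumor-free state changes stability.

    Bisects the leading eigenvalue real part of the tumor-free Jacobian
    in ``param_name`` until the bracket is narrower than 1e-8.  The
    real parts at ``lo`` and ``hi`` must have opposite signs; equal
    endpoints or a sign-free bracket raise :class:`InvalidInputError`.
    """
    if not lo < hi:
        raise InvalidInputError(f"need lo < hi, got [{lo}, {hi}]")

    def f(v):
        return leading_tumor_free_eigenvalue(params.replace(**{param_name: v}))

    flo, fhi = f(lo), f(hi)
    if not (np.isfinite(flo) and np.isfinite(fhi)):
        raise InvalidInputError("leading eigenvalue not finite at bracket ends")
    if flo * fhi > 0:
        raise InvalidInputError(
            f"no stability boundary: leading eigenvalue has the same sign at "
            f"{param_name}={lo} ({flo:.3g}) and {param_name}={hi} ({fhi:.3g})"
        )
    return _bisect(f, float(lo), float(hi))
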