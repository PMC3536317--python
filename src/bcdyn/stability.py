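"""Local and global stability classification of equilibria.

Local stability is decided by the eigenvalues of the analytic Jacobian
evaluated at the equilibrium (Hartman-Grobman: near a hyperbolic fixed
point the flow is topologically equivalent to its linearisation).  A
marginality band of EPS = 1e-9 on real parts guards double-precision
eigensolves near bifurcations: stable iff every real part < -EPS,
unstable iff some real part > +EPS, marginal otherwise.

Global stability of the tumor-free state uses the two-condition
compartment-splitting method (undamaged compartments X, damaged
compartment Z = T):

  H1: the tumor-free subsystem dX/dt = F(X, 0) is globally
      asymptotically stable at X*;
  H2: writing dZ/dt = G(X, Z) = A Z - G*(X, Z) with
      A = D_Z G(X*, 0), the remainder satisfies G*(X, Z) >= 0 on the
      biologically admissible region.

For the estrogen-free model G* evaluated at the tumor-free state is
-beta2 T* = 0, so H2 holds and the tumor-free state is the globally
stable one.  With estrogen, G* = -(beta2 T + sigma2 H E) is strictly
negative whenever estrogen is sourced (pi_src > 0), so H2 fails: no
amount of immune competence restores global stability once excess
estrogen is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import Equilibrium, tumor_free_equilibrium
from .models import EstrogenFreeParams, InvalidInputError, jacobian

#: Marginality band on eigenvalue real parts (per day).
EPS = 1e-9


@dataclass
class StabilityReport:
    equilibrium: Equilibrium
    eigenvalues: np.ndarray          # complex, day^-1
    classification: str              # stable | unstable | marginal
    diagnostics: dict = field(default_factory=dict)
    hypothetical: bool = False       # True when the equilibrium is infeasible

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def to_dict(self) -> dict:
        return {
            "label": self.equilibrium.label,
            "eigenvalues": [[float(z.real), float(z.imag)] for z in self.eigenvalues],
            "classification": self.classification,
            "hypothetical": self.hypothetical,
            "diagnostics": _jsonable(self.diagnostics),
        }


@dataclass
class GlobalStabilityReport:
    model: str
    A: float                 # 1x1 M-matrix D_Z G(X*, 0)
    Gstar: float             # remainder term at the tumor-free state
    H1_holds: bool
    H2_holds: bool
    verdict: str             # globally_stable | not_globally_stable

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "A": self.A,
            "Gstar": self.Gstar,
            "H1_holds": self.H1_holds,
            "H2_holds": self.H2_holds,
            "global_verdict": self.verdict,
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return [obj.real, obj.imag]
    return obj


def classify_eigenvalues(eigenvalues, eps: float = EPS) -> str:
    re = np.asarray(eigenvalues).real
    if np.all(re < -eps):
        return "stable"
    if np.any(re > eps):
        return "unstable"
    return "marginal"


def local_stability(eq: Equilibrium, params) -> StabilityReport:
    """Eigenvalue classification of an equilibrium of either model.

    Infeasible equilibria with finite coordinates are analysed anyway
    and flagged ``hypothetical`` (their linearisation is still well
    defined even though the point is not admissible or, for the
    estrogen-model tumor-free state with a positive source, not an
    exact fixed point).  Non-finite coordinates raise.
    """
    state = np.asarray(eq.state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise InvalidInputError(
            f"cannot linearise at non-finite state {state} (label={eq.label})"
        )
    J = jacobian(eq.model, state, params)
    eigs = np.linalg.eigvals(J)
    order = np.argsort(-eigs.real)
    eigs = eigs[order]
    diag: dict = {"real_parts": eigs.real.tolist()}
    p = params
    if eq.model == "estrogen_free" and eq.label == "tumor_free":
        diag["closed_form_eigenvalues"] = [
            -p.alpha1,
            p.alpha2 - p.gamma2 * p.s / p.mu,
            -p.mu,
        ]
        diag["resistance_coefficient"] = p.s * p.gamma2 / p.mu
    if eq.model == "estrogen_free" and eq.label == "coexisting":
        diag.update(_coexisting_block_diag(state, p))
    if eq.model == "estrogen" and eq.label == "coexisting":
        diag["lambda2_coefficient"] = _printed_cubic_lambda2_coefficient(state, p)
    report = StabilityReport(
        eq, eigs, classify_eigenvalues(eigs), diag, hypothetical=not eq.feasible
    )
    return report


def _coexisting_block_diag(state, p) -> dict:
    """Trace/determinant of the 2x2 tumor-immune block at coexistence.

    After the host eigenvalue -(alpha1 - delta1 T*) splits off, local
    stability is decided by the T-I block: trace < 0 and det > 0.
    """
    _, T, I = state
    a11 = p.alpha2 - 2.0 * p.beta2 * T - p.gamma2 * I
    a12 = -p.gamma2 * T
    a21 = p.rho * I * p.omega / (p.omega + T) ** 2 - p.gamma3 * I
    a22 = p.rho * T / (p.omega + T) - p.gamma3 * T - p.mu
    tau = a11 + a22
    delta = a11 * a22 - a12 * a21
    return {
        "block_trace": tau,
        "block_determinant": delta,
        "trace_negative": bool(tau < 0),
        "determinant_positive": bool(delta > 0),
    }


def _printed_cubic_lambda2_coefficient(state, p) -> float:
    """The published lambda^2 coefficient of the coexistence cubic.

    Reported as a diagnostic only: the published cubic is truncated in
    the source text, so eigenvalues always come from the Jacobian.
    """
    H, T, I, E = state
    return (
        p.alpha1
        + p.alpha3
        - 2.0 * H * p.beta1
        - 2.0 * T * p.beta2
        - I * p.gamma2
        - T * p.delta1
        - 2.0 * T * T * p.beta2 * p.delta1
        - p.sigma1 * E
        - p.s * I
    )


def tumor_free_stability_condition(params: EstrogenFreeParams):
    """Resistance coefficient s*gamma2/mu and the bound alpha2 < s*gamma2/mu.

    The tumor-free state of the estrogen-free model is locally stable
    exactly when the immune resistance coefficient exceeds the tumor
    growth rate (the middle eigenvalue alpha2 - gamma2 s/mu of the
    tumor-free Jacobian is then negative).
    """
    p = params
    resistance = p.s * p.gamma2 / p.mu
    return resistance, bool(p.alpha2 < resistance)


def routh_hurwitz(coeffs):
    """Routh-Hurwitz test for monic polynomials of degree 2 or 3.

    ``coeffs`` are [1, a, b] (lambda^2 + a lambda + b) or [1, a, b, c]
    (lambda^3 + a lambda^2 + b lambda + c).  Degree 2 is stable iff
    a > 0 and b > 0; degree 3 iff a > 0, c > 0 and a*b > c.  Returns
    (stable, condition_table) with each sub-condition and its margin.
    """
    coeffs = [float(c) for c in coeffs]
    if len(coeffs) not in (3, 4):
        raise InvalidInputError(
            f"unsupported degree {len(coeffs) - 1}; expected 2 or 3"
        )
    if abs(coeffs[0] - 1.0) > 1e-12:
        raise InvalidInputError("leading coefficient must be normalized to 1")
    if len(coeffs) == 3:
        _, a, b = coeffs
        table = [("a_positive", a > 0, a), ("b_positive", b > 0, b)]
    else:
        _, a, b, c = coeffs
        table = [
            ("a_positive", a > 0, a),
            ("c_positive", c > 0, c),
            ("ab_gt_c", a * b > c, a * b - c),
        ]
    return all(t[1] for t in table), table


def monitor_tumor_free_instability(
    n_draws: int = 500, seed: int = 0, ranges=None
) -> dict:
    """Monitored invariant: instability of the estrogen-model tumor-free state.

    The published analysis concludes that with a positive estrogen
    source the tumor-free state is always unstable.  That conclusion
    rests on a lambda-coefficient that does not follow from the
    Jacobian of the implemented vector field, so it is *monitored*
    rather than asserted: over random valid estrogen parameter sets
    satisfying alpha3 > alpha1 and the existence bound
    pi_src/theta <= alpha1/sigma1, count how often the leading
    eigenvalue at the tumor-free state is positive.  Violations
    (stable draws) are counted and returned, never dropped.
    """
    from .synthetic import sample_parameter_set

    n_unstable = 0
    checked = 0
    attempts = 0
    while checked < n_draws and attempts < 100 * n_draws:
        attempts += 1
        try:
            p = sample_parameter_set(ranges, model="estrogen", seed=seed + attempts)
        except InvalidInputError:
            continue
        E = p.pi_src / p.theta
        if not (p.alpha3 > p.alpha1 and p.pi_src > 0 and E <= p.alpha1 / p.sigma1):
            continue
        checked += 1
        eq = tumor_free_equilibrium(p)
        rep = local_stability(eq, p)
        if rep.max_real_part > EPS:
            n_unstable += 1
    return {
        "n_checked": checked,
        "n_unstable": n_unstable,
        "n_stable_violations": checked - n_unstable,
        "claim_holds": checked > 0 and n_unstable == checked,
    }


def castillo_chavez_global(
    params, growth_rate_option: str = "alpha3_consistent"
) -> GlobalStabilityReport:
    """Global-stability verdict for the tumor-free state of either model.

    ``growth_rate_option`` resolves which tumor growth rate enters the
    1x1 matrix A for the estrogen model: "alpha3_consistent" (default;
    matches the implemented vector field) or "alpha2_as_printed" (the
    published text).  The verdict is insensitive to this choice: it is
    decided by the sign of G* at the tumor-free state.
    """
    p = params
    eq = tumor_free_equilibrium(p)
    if p.model == "estrogen_free":
        H, T, I = eq.state
        A = p.alpha2 - 2.0 * p.beta2 * T - p.gamma2 * I
        Gstar = -p.beta2 * T  # zero at the tumor-free state
        # F(X,0): dH = alpha1 H - beta1 H^2 (logistic), dI = s - mu I
        # (linear): both globally stable for positive rates.
        H1 = True
    elif p.model == "estrogen":
        if growth_rate_option == "alpha3_consistent":
            growth = p.alpha3
        elif growth_rate_option == "alpha2_as_printed":
            growth = p.alpha2
        else:
            raise InvalidInputError(
                f"unknown growth_rate_option {growth_rate_option!r}"
            )
        H, T, I, E = eq.state
        A = growth - 2.0 * p.beta2 * T - p.gamma2 * I
        Gstar = -(p.beta2 * T + p.sigma2 * H * E)
        # F(X,0): E relaxes to pi/theta, H is logistic with effective
        # growth alpha1 - sigma1 E*, I is linear and stable; global
        # stability of the subsystem needs alpha1 - sigma1 E* > 0.
        H1 = bool(p.alpha1 - p.sigma1 * E > 0.0)
    else:  # pragma: no cover
        raise InvalidInputError(f"unknown model {p.model!r}")
    H2 = bool(Gstar >= 0.0)
    verdict = "globally_stable" if (H1 and H2) else "not_globally_stable"
    return GlobalStabilityReport(p.model, float(A), float(Gstar), H1, H2, verdict)
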