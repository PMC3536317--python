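"""Canonical parameter values and initial-condition presets.

``TABLE1_PARAMS`` carries the published estrogen-free rates (all per
day): host growth 0.70 and self-limitation 0.30, tumor growth 0.98 and
self-limitation 0.40, competition 1.0, immune predation 0.9, immune
source 0.4, immune response 0.2 with half-saturation 0.3, and immune
death 0.29.  The immune inactivation rate gamma3 has no published
value; the package default is 0.1/day, small against the predation
rate 0.9 so that predation dominates inactivation (configurable).

None of the estrogen-specific rates have published values.  The
defaults in ``DEFAULT_ESTROGEN_PARAMS`` are package choices that
respect the stated orderings (sigma2 < sigma1, alpha3 > alpha2) and
keep the steady estrogen level pi_src/theta below alpha1/sigma1 at
small source rates so the tumor-free state remains feasible there.

Two initial-condition presets are shipped.  The source text states
both T(0) = 1e-5 (estrogen-free sections) and T(0) = 10 (estrogen
section); both are preserved as distinct presets rather than silently
reconciled.
"""

from __future__ import annotations

import numpy as np

from .models import EstrogenFreeParams, EstrogenParams

#: Published estrogen-free rates plus the package default gamma3 = 0.1.
TABLE1_PARAMS = EstrogenFreeParams(
    alpha1=0.70,
    beta1=0.30,
    delta1=1.0,
    alpha2=0.98,
    beta2=0.40,
    gamma2=0.9,
    gamma3=0.1,
    s=0.4,
    rho=0.2,
    omega=0.3,
    mu=0.29,
)

#: Estrogen-model defaults: Table-1 core plus package-chosen estrogen rates.
DEFAULT_ESTROGEN_PARAMS = EstrogenParams(
    **TABLE1_PARAMS.to_dict(),
    alpha3=1.0,
    sigma1=0.3,
    sigma2=0.2,
    sigma3=0.1,
    upsilon=0.5,
    pi_src=0.2,
    theta=0.97,
)

#: H(0)=1, T(0)=1e-5, I(0)=s/mu (estrogen-free sections).
IC_ESTROGEN_FREE_PAPER = np.array([1.0, 1e-5, TABLE1_PARAMS.s / TABLE1_PARAMS.mu])

#: H(0)=1, T(0)=10, I(0)=s/mu, E(0)=2 (estrogen section).
IC_ESTROGEN_PAPER = np.array(
    [1.0, 10.0, TABLE1_PARAMS.s / TABLE1_PARAMS.mu, 2.0]
)

#: Default estrogen-source sweep grid: 11 points spanning [0, 1] / day.
DEFAULT_PI_GRID = np.linspace(0.0, 1.0, 11)

#: Default integration horizons (days) per model.
DEFAULT_T_END = {"estrogen_free": 200.0, "estrogen": 100.0}

IC_PRESETS = {
    "ic_estrogen_free_paper": IC_ESTROGEN_FREE_PAPER,
    "ic_estrogen_paper": IC_ESTROGEN_PAPER,
}
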