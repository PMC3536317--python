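"""Equilibrium coordinates, feasibility conditions and residuals."""

import numpy as np
import pytest

from bcdyn import (
    all_equilibria,
    coexisting_equilibria,
    dead_equilibria,
    tumor_free_equilibrium,
)
from bcdyn.equilibria import RESIDUAL_TOL, scaled_residual
from conftest import draw_params


class TestTumorFree:
    def test_immune_level_is_source_over_death(self, table1):
        eq = tumor_free_equilibrium(table1)
        assert eq.state[2] == pytest.approx(1.379310345, abs=5e-10)
        assert eq.state[0] == pytest.approx(0.7 / 0.3, rel=1e-14)
        assert eq.state[1] == 0.0
        assert eq.feasible

    def test_always_feasible_for_estrogen_free_params(self):
        for i in range(200):
            p = draw_params("estrogen_free", seed=500 + i)
            assert tumor_free_equilibrium(p).feasible

    def test_estrogen_existence_bound_on_estrogen_level(self, estro):
        # push the source rate past theta * alpha1 / sigma1
        pi_big = estro.theta * estro.alpha1 / estro.sigma1 * 1.5
        eq = tumor_free_equilibrium(estro.replace(pi_src=pi_big))
        assert not eq.feasible
        assert not eq.condition("E_le_alpha1_over_sigma1").satisfied

    def test_existence_flag_tracks_printed_inequality(self):
        for i in range(300):
            p = draw_params("estrogen", seed=700 + i)
            eq = tumor_free_equilibrium(p)
            expected = p.pi_src / p.theta <= p.alpha1 / p.sigma1
            assert eq.condition("E_le_alpha1_over_sigma1").satisfied == expected
            # feasibility additionally needs an actual fixed point
            if eq.feasible:
                assert expected and eq.residual < RESIDUAL_TOL

    def test_positive_source_leaves_tumor_influx(self, estro):
        # with pi_src > 0 the conversion influx sigma2*H*E is positive at
        # T = 0, so the printed closed form is a quasi-equilibrium only
        eq = tumor_free_equilibrium(estro)
        assert not eq.feasible
        assert not eq.condition("zero_tumor_influx").satisfied
        H, _, _, E = eq.state
        assert eq.residual == pytest.approx(
            estro.sigma2 * H * E / max(1.0, np.max(np.abs(eq.state))), rel=1e-12
        )

    def test_estrogen_model_without_source_is_true_fixed_point(self, estro):
        eq = tumor_free_equilibrium(estro.replace(pi_src=0.0))
        assert eq.feasible and eq.residual < RESIDUAL_TOL
        np.testing.assert_allclose(
            eq.state, [estro.alpha1 / estro.beta1, 0.0, estro.s / estro.mu, 0.0],
            rtol=1e-12,
        )


class TestDeadEquilibria:
    def test_dead2_is_always_a_fixed_point(self):
        for i in range(100):
            p = draw_params("estrogen_free", seed=900 + i)
            d2 = next(e for e in dead_equilibria(p) if e.label == "dead2")
            assert d2.feasible
            np.testing.assert_allclose(d2.state, [0.0, 0.0, p.s / p.mu], rtol=1e-14)
            assert d2.residual < RESIDUAL_TOL

    def test_dead1_infeasible_at_canonical_values(self, table1):
        # u2 = mu + omega*gamma3 - rho = 0.29 + 0.03 - 0.2 = 0.12 > 0
        d1 = [e for e in dead_equilibria(table1) if e.label == "dead1"]
        assert d1 and all(not e.feasible for e in d1)
        assert not d1[0].condition("u2_negative").satisfied
        assert d1[0].condition("u2_negative").margin == pytest.approx(-0.12, rel=1e-12)

    def test_dead1_tumor_coordinate_matches_bruteforce_root(self, table1):
        p = table1.replace(rho=1.0)  # mu + omega*gamma3 < rho
        # brute-force sign scan of gamma3 T^2 + u2 T + u3 over [0, 100]
        u2 = p.mu + p.omega * p.gamma3 - p.rho
        grid = np.arange(0.0, 100.0, 1e-4)
        q = p.gamma3 * grid**2 + u2 * grid + p.mu * p.omega
        crossings = grid[:-1][np.diff(np.sign(q)) != 0]
        d1 = [e for e in dead_equilibria(p) if e.label == "dead1"]
        primary = next(e for e in d1 if e.branch == "plus")
        assert primary.state[1] == pytest.approx(max(crossings), abs=2e-4)
        secondary = next(e for e in d1 if e.branch == "minus")
        assert secondary.state[1] == pytest.approx(min(crossings), abs=2e-4)

    def test_dead1_feasibility_implies_printed_conditions(self):
        # the published root is a pole of the immune coordinate, so
        # feasibility can only occur with the printed conditions true
        for i in range(300):
            p = draw_params("estrogen_free", seed=1100 + i)
            for e in dead_equilibria(p):
                if e.label == "dead1" and e.feasible:
                    u2 = p.mu + p.omega * p.gamma3 - p.rho
                    assert u2 < 0
                    assert u2**2 > 4 * p.gamma3 * p.omega * p.mu

    def test_estrogen_dead2_under_immune_suppression(self, estro):
        d2 = next(e for e in dead_equilibria(estro) if e.label == "dead2")
        E = estro.pi_src / estro.theta
        I = estro.s * (E + estro.upsilon) / (
            estro.mu * (E + estro.upsilon) + estro.sigma3 * E
        )
        np.testing.assert_allclose(d2.state, [0.0, 0.0, I, E], rtol=1e-12)
        assert d2.feasible
        assert I < estro.s / estro.mu  # suppression lowers the immune level


class TestCoexistence:
    def test_every_feasible_equilibrium_is_a_fixed_point(self):
        for model in ("estrogen_free", "estrogen"):
            for i in range(150):
                p = draw_params(model, seed=1300 + i)
                for e in all_equilibria(p):
                    if e.feasible:
                        assert e.residual < RESIDUAL_TOL, (model, e.label)
                        assert scaled_residual(e.state, p) < RESIDUAL_TOL

    def test_tumor_coordinate_matches_grid_search(self, table1):
        p = table1
        # independent oracle: grid minimization of |T - (alpha2 - g2 I(T))/b2|
        grid = np.arange(1e-6, p.alpha2 / p.beta2, 1e-6)
        I = p.s / (p.mu - p.rho * grid / (p.omega + grid) + p.gamma3 * grid)
        mismatch = np.abs(grid - (p.alpha2 - p.gamma2 * I) / p.beta2)
        eqs = coexisting_equilibria(p)
        if np.min(mismatch) > 1e-3:  # no interior fixed point at Table-1 rates
            assert all(not e.feasible for e in eqs)
            assert eqs[0].conditions[0].name == "no_root_in_bracket"
        else:
            assert any(
                e.state[1] == pytest.approx(grid[np.argmin(mismatch)], abs=1e-5)
                for e in eqs
            )

    def test_interior_root_found_when_immunity_is_weak(self, table1):
        # lowering the immune source weakens predation enough to open an
        # interior equilibrium (alpha2 - gamma2 I(T) becomes positive);
        # weaker competition keeps the host coordinate positive there
        p = table1.replace(s=0.05, delta1=0.2)
        eqs = [e for e in coexisting_equilibria(p) if e.feasible]
        assert eqs
        for e in eqs:
            assert np.all(e.state > 0)
            assert e.residual < RESIDUAL_TOL

    def test_failed_growth_ordering_reported(self, table1):
        # alpha2/beta2 = 2.45 < alpha1/delta1 = 3.5 negates the printed
        # existence remark while an interior root still exists
        p = table1.replace(delta1=0.2, s=0.05)
        eqs = coexisting_equilibria(p)
        with_root = [e for e in eqs if np.all(np.isfinite(e.state))]
        assert with_root, "expected an interior root to inspect"
        for e in with_root:
            assert not e.condition("tumor_net_growth_ge_host").satisfied

    def test_estrogen_model_reduces_at_zero_source(self, estro, table1):
        # pi = 0: estrogen equilibria coincide with the estrogen-free
        # model's once alpha2 is replaced by alpha3
        p0 = estro.replace(pi_src=0.0)
        ef = table1.replace(alpha2=estro.alpha3)
        for e4, e3 in zip(all_equilibria(p0), all_equilibria(ef)):
            assert e4.label == e3.label
            if np.all(np.isfinite(e4.state)) and np.all(np.isfinite(e3.state)):
                np.testing.assert_allclose(e4.state[:3], e3.state, atol=1e-10)
                assert e4.state[3] == 0.0

    def test_all_equilibria_order_and_count(self, table1):
        eqs = all_equilibria(table1)
        assert [e.label for e in eqs[:2]] == ["tumor_free", "dead2"]
        assert eqs[2].label == "dead1"
        assert eqs[-1].label == "coexisting"
        feasible = {e.label for e in eqs if e.feasible}
        assert feasible == {"tumor_free", "dead2"}
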