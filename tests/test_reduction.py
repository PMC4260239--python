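"""Tropical truncation, timescale ordering and pool detection.

The reduced Michaelis-Menten system has five known truncated models, one per
branch of tropical solutions: the quasi-equilibrium pair (truncation keeping
the binding/unbinding terms, with the new conserved pool z = x1 + x2), the
enzyme-saturated variant, and the quasi-stationarity truncations in which the
complex decays through catalysis alone.
"""

import pytest

import tropicalize as tz
from tropicalize.fixtures import FixtureSpec, michaelis_menten_reduced, random_network
from tropicalize.polynomial_system import Monomial, build_odes


def truncate_at(system, orders):
    return tz.truncate(system, tz.classify_solution(system, orders))


def keys(monomials):
    return {m.key() for m in monomials}


X1 = (("x1", 1),)
X2 = (("x2", 1),)
X1X2 = (("x1", 1), ("x2", 1))


class TestTruncationFidelity:
    """Monomial-for-monomial agreement with the five known truncations."""

    def test_quasi_equilibrium(self, reduced_a):
        # oblique branch, g_-1 < g2: x1' = -k1 e0 x1 + k_1 x2, x2' mirrored
        t = truncate_at(reduced_a, {"x1": 2, "x2": 3})
        assert keys(t.retained["x1"]) == {(-1, 1, X1), (1, 0, X2)}
        assert keys(t.retained["x2"]) == {(1, 1, X1), (-1, 0, X2)}

    def test_enzyme_saturation(self, reduced_a):
        # horizontal branch a2 = ge: x1' = -k1 x1 (e0 - x2), x2' mirrored
        t = truncate_at(reduced_a, {"x1": -2, "x2": 1})
        assert keys(t.retained["x1"]) == {(-1, 1, X1), (1, 0, X1X2)}
        assert keys(t.retained["x2"]) == {(1, 1, X1), (-1, 0, X1X2)}

    def test_quasi_stationarity_of_complex(self, reduced_b):
        # branch a2 = a1 + g1 + ge - g2: x1' = -k1 e0 x1, x2' = k1 e0 x1 - k2 x2
        t = truncate_at(reduced_b, {"x1": 2, "x2": 3})
        assert keys(t.retained["x1"]) == {(-1, 1, X1)}
        assert keys(t.retained["x2"]) == {(1, 1, X1), (-1, 0, X2)}

    def test_quasi_stationarity_of_substrate(self, reduced_b):
        # branch a2 = a1 + g1 + ge - g_-1: x1' = -k1 e0 x1 + k_1 x2, x2' = -k2 x2
        t = truncate_at(reduced_b, {"x1": 4, "x2": 3})
        assert keys(t.retained["x1"]) == {(-1, 1, X1), (1, 2, X2)}
        assert keys(t.retained["x2"]) == {(-1, 0, X2)}

    def test_saturated_decay_branch(self, reduced_b):
        # horizontal branch between the junctions: x1' = -k1 x1 (e0 - x2),
        # x2' = -k2 x2 (equilibrates x1 but fails permanency; still reported)
        t = truncate_at(reduced_b, {"x1": 1, "x2": 1})
        assert keys(t.retained["x1"]) == {(-1, 1, X1), (1, 0, X1X2)}
        assert keys(t.retained["x2"]) == {(-1, 0, X2)}

    def test_identity_truncation(self):
        net = tz.parse_reaction_text(" -> x ; k=1.0\nx -> ; k=1.0")
        system = build_odes(net, 0.1)
        t = truncate_at(system, {"x": 0})
        assert keys(t.retained["x"]) == keys(system.equations["x"])
        assert t.pools == []


class TestPools:
    def test_quasi_equilibrium_pool(self, reduced_a):
        """z = x1 + x2 is conserved by the truncation only; its residual
        derivative is the dominated catalytic term -k2 x2."""
        t = truncate_at(reduced_a, {"x1": 2, "x2": 3})
        (pool,) = t.pools
        assert pool.coefficients == {"x1": 1, "x2": 1}
        assert keys(pool.residual) == {(-1, 1, X2)}
        assert pool.residual[0].magnitude == pytest.approx(0.1)  # k2

    def test_saturation_pool(self, reduced_a):
        t = truncate_at(reduced_a, {"x1": -2, "x2": 1})
        (pool,) = t.pools
        assert pool.coefficients == {"x1": 1, "x2": 1}
        assert keys(pool.residual) == {(-1, 1, X2)}

    @pytest.mark.parametrize("orders", [
        {"x1": 2, "x2": 3},   # quasi-stationarity of the complex
        {"x1": 4, "x2": 3},   # quasi-stationarity of the substrate
        {"x1": 1, "x2": 1},   # saturated decay
    ])
    def test_no_pool_on_quasi_stationarity_branches(self, reduced_b, orders):
        assert truncate_at(reduced_b, orders).pools == []

    def test_pool_kernel_property(self, reduced_a):
        """Pool vectors annihilate the truncated coefficient matrix but not
        the full one."""
        import numpy as np
        t = truncate_at(reduced_a, {"x1": 2, "x2": 3})
        (pool,) = t.pools
        b = np.array([pool.coefficients.get(s, 0) for s in reduced_a.species])
        _, tmat = t.as_system().coefficient_matrix()
        _, fmat = reduced_a.coefficient_matrix()
        assert np.allclose(b @ tmat, 0.0)
        assert not np.allclose(b @ fmat, 0.0)


class TestInvariantsOfTruncation:
    @pytest.mark.parametrize("seed", range(6))
    def test_retained_dominate_dropped(self, seed):
        import numpy as np
        rng = np.random.default_rng(seed)
        net = random_network(n_species=4, n_reactions=6, seed=seed)
        system = build_odes(net, 0.1)
        orders = {s: int(rng.integers(-4, 5)) for s in system.species}
        t = truncate_at(system, orders)
        for s in system.species:
            if not system.equations[s]:
                continue
            mn = t.orders.achieved_minimum[s]
            for m in t.retained[s]:
                assert tz.monomial_degree(m, orders) == mn
            for m in t.dropped[s]:
                assert tz.monomial_degree(m, orders) > mn

    def test_truncation_is_idempotent(self, reduced_a):
        eq = tz.classify_solution(reduced_a, {"x1": 2, "x2": 3})
        once = tz.truncate(reduced_a, eq)
        twice = tz.truncate(once.as_system(), eq)
        for s in reduced_a.species:
            assert keys(twice.retained[s]) == keys(once.retained[s])
        assert twice.timescale_exponents == once.timescale_exponents


class TestTimescales:
    def test_low_enzyme_concentration_ordering(self):
        """Quasi-stationarity branch with g1+ge > g2: the complex is the
        fast variable (exponents x1: g1+ge = 2, x2: g2 = 1)."""
        spec = FixtureSpec(parameter_orders={"k1": 0, "k_1": 3, "k2": 1, "e": 2})
        system = michaelis_menten_reduced(spec)
        # on a2 = a1 + g1 + ge - g2, a1 > g2 - g1
        t = truncate_at(system, {"x1": 2, "x2": 3})
        assert dict(tz.order_timescales(t)) == {"x1": 2, "x2": 1}
        assert tz.order_timescales(t)[0][0] == "x2"  # faster first

    def test_high_enzyme_concentration_ordering(self):
        """With g1+ge < g2 the substrate is the fast variable."""
        spec = FixtureSpec(parameter_orders={"k1": 0, "k_1": 3, "k2": 2, "e": 1})
        system = michaelis_menten_reduced(spec)
        # substrate quasi-stationarity branch: a2 = a1 + g1 + ge - g_-1
        t = truncate_at(system, {"x1": 4, "x2": 2})
        exps = dict(tz.order_timescales(t))
        assert exps["x1"] < exps["x2"]

    def test_empty_system_empty_ordering(self):
        from tropicalize.polynomial_system import PolynomialSystem
        system = PolynomialSystem(species=["z"], equations={"z": []},
                                  epsilon=0.1)
        t = tz.truncate(system, tz.classify_solution(system, {"z": 0}))
        assert tz.order_timescales(t) == []
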