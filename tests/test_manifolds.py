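"""Constant-curvature spaces: constraints, exp/log maps, distances."""

import numpy as np
import pytest

from pathcurv import manifolds as mf
from pathcurv.manifolds import Component, Signature


S1 = Component(mf.SPHERICAL, 1, 1.0)
H1 = Component(mf.HYPERBOLIC, 1, 1.0)
E2 = Component(mf.EUCLIDEAN, 2)


class TestSignature:
    def test_parse_format_round_trip(self):
        sig = Signature.parse("H2_1.0 x S3_1.0 x E2")
        assert [c.space_type for c in sig] == [mf.HYPERBOLIC, mf.SPHERICAL, mf.EUCLIDEAN]
        assert sig.total_dim == 7
        assert sig.ambient_dims == (3, 4, 2)
        assert Signature.parse(str(sig)) == sig

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            Component(mf.SPHERICAL, 0, 1.0)
        with pytest.raises(ValueError):
            Component(mf.HYPERBOLIC, 2, -1.0)
        with pytest.raises(ValueError):
            Signature(())


class TestPointsAndConstraints:
    def test_random_point_on_manifold_and_reproducible(self, component3):
        p1 = mf.random_point(component3, 42)
        p2 = mf.random_point(component3, 42)
        assert np.array_equal(p1, p2)
        assert mf.constraint_residual(p1, component3) <= 1e-8
        if component3.space_type == mf.HYPERBOLIC:
            assert p1[0] >= np.sqrt(component3.curvature_scale)

    def test_origin_satisfies_constraint_exactly(self):
        assert np.array_equal(mf.origin(Component(mf.HYPERBOLIC, 2, 4.0)), [2.0, 0.0, 0.0])
        assert np.array_equal(mf.origin(Component(mf.SPHERICAL, 2, 1.0)), [1.0, 0.0, 0.0])
        assert np.array_equal(mf.origin(Component(mf.EUCLIDEAN, 3)), np.zeros(3))

    def test_project_to_tangent_idempotent(self, component3):
        x = mf.random_point(component3, 1)
        w = np.random.default_rng(2).standard_normal(component3.ambient_dim)
        v = mf.project_to_tangent(x, w, component3)
        v2 = mf.project_to_tangent(x, v, component3)
        np.testing.assert_allclose(v, v2, atol=1e-12)

    def test_project_to_tangent_examples(self):
        # removing the radial part on the circle
        out = mf.project_to_tangent(np.array([1.0, 0.0]), np.array([1.0, 1.0]), S1)
        np.testing.assert_allclose(out, [0.0, 1.0], atol=1e-12)
        w = np.array([0.3, -0.7])
        assert np.array_equal(mf.project_to_tangent(np.zeros(2), w, E2), w)


class TestExpLog:
    def test_exp_quarter_circle(self):
        out = mf.exp_map(np.array([1.0, 0.0]), np.array([0.0, np.pi / 2]), S1)
        np.testing.assert_allclose(out, [0.0, 1.0], atol=1e-12)

    def test_exp_unit_hyperbolic_geodesic(self):
        out = mf.exp_map(np.array([1.0, 0.0]), np.array([0.0, 1.0]), H1)
        np.testing.assert_allclose(out, [np.cosh(1.0), np.sinh(1.0)], atol=1e-12)

    def test_exp_zero_tangent_is_identity(self, component3):
        x = mf.random_point(component3, 5)
        assert np.array_equal(mf.exp_map(x, np.zeros_like(x), component3), x)

    def test_exp_rejects_non_tangent(self):
        with pytest.raises(ValueError):
            mf.exp_map(np.array([1.0, 0.0]), np.array([1.0, 0.0]), S1)

    def test_log_quarter_circle_norm(self):
        v = mf.log_map(np.array([1.0, 0.0]), np.array([0.0, 1.0]), S1)
        assert mf.tangent_norm(v, S1) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_log_identical_points_is_zero(self, component3):
        x = mf.random_point(component3, 6)
        np.testing.assert_allclose(mf.log_map(x, x, component3), 0.0, atol=1e-7)

    def test_log_inverts_hyperbolic_exp(self):
        y = np.array([np.cosh(1.0), np.sinh(1.0)])
        v = mf.log_map(np.array([1.0, 0.0]), y, H1)
        assert mf.tangent_norm(v, H1) == pytest.approx(1.0, abs=1e-12)

    def test_log_antipodal_raises(self):
        with pytest.raises(ValueError):
            mf.log_map(np.array([1.0, 0.0]), np.array([-1.0, 0.0]), S1)

    def test_exp_log_inversion(self, component3):
        """log(x, exp(x, v)) recovers v to 1e-6 relative error."""
        rng = np.random.default_rng(7)
        X = mf.random_points(component3, 20, rng)
        V = mf.project_to_tangent(X, rng.standard_normal(X.shape), component3)
        norms = mf.tangent_norm(V, component3)[:, None]
        V = V / np.maximum(norms, 1.0)  # keep within injectivity radius
        Y = mf.exp_map(X, V, component3)
        V2 = mf.log_map(X, Y, component3)
        assert np.abs(V - V2).max() <= 1e-6 * max(1.0, np.abs(V).max())

    def test_constraint_preserved_over_random_walk(self, component3):
        """1,000 exp-map steps never drift off the constraint surface.

        Hyperbolic random walks have outward drift and the constraint involves
        a difference of exponentially growing squares, so the walk is kept in
        a bounded neighborhood of the origin where the absolute residual is
        meaningful.
        """
        rng = np.random.default_rng(11)
        x = mf.random_point(component3, rng)
        o = mf.origin(component3)
        worst = 0.0
        for _ in range(1000):
            v = mf.project_to_tangent(x, rng.standard_normal(x.shape), component3)
            norm = float(mf.tangent_norm(v, component3))
            v = 0.1 * v / max(norm, 1e-12)
            x = mf.exp_map(x, v, component3)
            worst = max(worst, float(mf.constraint_residual(x, component3)))
            if component3.is_curved and float(mf.component_distance(x, o, component3)) > 3.0:
                x = mf.exp_map(o, mf.log_map(o, x, component3) * 0.5, component3)
        assert worst <= 1e-8


class TestDistances:
    def test_antipodal_circle_distance(self):
        d = mf.component_distance(np.array([1.0, 0.0]), np.array([-1.0, 0.0]), S1)
        assert d == pytest.approx(np.pi, abs=1e-12)

    def test_zero_iff_same_point(self, component3):
        x = mf.random_point(component3, 3)
        assert mf.component_distance(x, x, component3) <= 1e-7
        y = mf.random_point(component3, 4)
        assert mf.component_distance(x, y, component3) > 0

    def test_euclidean_pythagoras(self):
        assert mf.component_distance(np.zeros(2), np.array([3.0, 4.0]), E2) == pytest.approx(5.0)

    def test_mismatched_dims_raise(self):
        with pytest.raises(ValueError):
            mf.component_distance(np.zeros(2), np.zeros(3), E2)

    def test_distance_equals_log_norm(self, component3):
        rng = np.random.default_rng(8)
        X = mf.random_points(component3, 10, rng)
        Y = mf.random_points(component3, 10, rng)
        d = mf.component_distance(X, Y, component3)
        v = mf.log_map(X, Y, component3)
        np.testing.assert_allclose(mf.tangent_norm(v, component3), d, atol=1e-8)

    def test_pairwise_matches_elementwise(self, component3):
        X = mf.random_points(component3, 12, np.random.default_rng(9))
        D = mf.pairwise_component_distance(X, component3)
        for i in range(12):
            # d(x, x) only vanishes up to arccos/arcosh rounding (~sqrt(eps),
            # amplified by the point magnitude on the hyperboloid)
            assert float(mf.component_distance(X[i], X[i], component3)) <= 1e-6
            for j in range(12):
                if i == j:
                    assert D[i, j] == 0.0
                    continue
                assert D[i, j] == pytest.approx(
                    float(mf.component_distance(X[i], X[j], component3)), abs=1e-8
                )

    def test_product_distance_decomposition(self):
        # component distances 3 and 4 compose to 5
        sig = Signature((E2, E2))
        u = [np.zeros(2), np.zeros(2)]
        v = [np.array([3.0, 0.0]), np.array([4.0, 0.0])]
        assert mf.product_distance(u, v, sig) == pytest.approx(5.0)

    def test_product_distance_circle_times_line(self):
        sig = Signature((S1, Component(mf.EUCLIDEAN, 1)))
        u = [np.array([1.0, 0.0]), np.zeros(1)]
        v = [np.array([0.0, 1.0]), np.ones(1)]
        assert mf.product_distance(u, v, sig) == pytest.approx(np.sqrt(np.pi**2 / 4 + 1))

    def test_single_component_product_equals_component(self):
        sig = Signature((E2,))
        u, v = [np.zeros(2)], [np.array([3.0, 4.0])]
        assert mf.product_distance(u, v, sig) == pytest.approx(5.0)

    def test_signature_mismatch_raises(self):
        with pytest.raises(ValueError):
            mf.product_distance([np.zeros(2)], [np.zeros(2), np.zeros(2)], Signature((E2, E2)))

    def test_triangle_inequality_sampled(self):
        """No violation beyond 1e-9 on 1,000 random triples per signature."""
        for sig in [
            Signature((Component(mf.SPHERICAL, 3, 2.0), Component(mf.EUCLIDEAN, 2))),
            Signature((Component(mf.HYPERBOLIC, 3, 0.5),)),
            Signature((Component(mf.HYPERBOLIC, 2, 1.0), Component(mf.SPHERICAL, 2, 1.0))),
        ]:
            rng = np.random.default_rng(13)
            pts = {k: [mf.random_points(c, 1000, rng) for c in sig] for k in "abc"}

            def dist(k1, k2):
                total = 0.0
                for Xa, Xb, comp in zip(pts[k1], pts[k2], sig):
                    total = total + mf.component_distance(Xa, Xb, comp) ** 2
                return np.sqrt(total)

            dab, dbc, dac = dist("a", "b"), dist("b", "c"), dist("a", "c")
            assert np.all(dac <= dab + dbc + 1e-9)
            np.testing.assert_allclose(dab, dist("b", "a"), atol=0)


class TestOriginMaps:
    """Origin-based tangent coordinates used by the GCN layers."""

    def test_exp_origin_matches_exp_map(self, component3):
        rng = np.random.default_rng(21)
        if component3.space_type == mf.EUCLIDEAN:
            V = rng.standard_normal((5, component3.dim))
            assert np.array_equal(mf.exp_origin(V, component3), V)
            return
        V = rng.standard_normal((5, component3.dim))
        full = np.concatenate([np.zeros((5, 1)), V], axis=1)
        base = np.broadcast_to(mf.origin(component3), full.shape)
        expected = mf.exp_map(base, full, component3)
        np.testing.assert_allclose(mf.exp_origin(V, component3), expected, atol=1e-9)

    def test_log_origin_inverts_exp_origin(self, component3):
        rng = np.random.default_rng(22)
        V = 0.5 * rng.standard_normal((6, component3.dim))
        back = mf.log_origin(mf.exp_origin(V, component3), component3)
        np.testing.assert_allclose(back, V, atol=1e-8)

    @pytest.mark.parametrize("which", ["exp", "log"])
    def test_origin_map_vjps_match_finite_differences(self, component3, which):
        rng = np.random.default_rng(23)
        # tangent samples stay well inside the smallest injectivity radius
        # (pi * sqrt(0.5) for the tightest sphere)
        if which == "exp":
            X = 0.3 * rng.standard_normal((4, component3.dim))
            fn = lambda A: mf.exp_origin(A, component3)
            vjp = lambda A, G: mf.exp_origin_vjp(A, component3, G)
        else:
            X = mf.exp_origin(0.3 * rng.standard_normal((4, component3.dim)), component3)
            fn = lambda A: mf.log_origin(A, component3)
            vjp = lambda A, G: mf.log_origin_vjp(A, component3, G)
        G = rng.standard_normal(fn(X).shape)
        analytic = vjp(X, G)
        num = np.zeros_like(X)
        for i in range(X.shape[0]):
            for j in range(X.shape[1]):
                for sgn in (1.0, -1.0):
                    Xp = X.copy()
                    Xp[i, j] += sgn * 1e-6
                    num[i, j] += sgn * float((fn(Xp) * G).sum()) / 2e-6
        np.testing.assert_allclose(analytic, num, atol=1e-5)
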