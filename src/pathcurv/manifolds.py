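"""Constant-curvature model spaces and their Cartesian products.

Three model spaces of constant curvature are supported:

* spherical  — the sphere ``<x, x> = C`` in R^(d+1) (radius ``sqrt(C)``),
* hyperbolic — the upper sheet of the hyperboloid ``<x, x>_L = -C`` in
  Minkowski space R^(d+1), where ``<u, v>_L = -u_0 v_0 + sum_{i>=1} u_i v_i``,
* euclidean  — flat R^d.

A product manifold is described by a :class:`Signature`, an ordered list of
:class:`Component` entries; squared geodesic distances on the product
decompose as the sum of squared component distances.  All point-valued
functions accept either a single ambient vector of shape ``(a,)`` or a batch
of points of shape ``(n, a)`` and are fully vectorized in the batch case.

The curvature scale ``C`` parameterizes the squared radius: spherical and
hyperbolic distances carry a ``sqrt(C)`` factor, e.g. the spherical distance
is ``sqrt(C) * arccos(<x, y> / C)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SPHERICAL = "spherical"
HYPERBOLIC = "hyperbolic"
EUCLIDEAN = "euclidean"
_SPACE_CODES = {"S": SPHERICAL, "H": HYPERBOLIC, "E": EUCLIDEAN}
_CODE_OF = {v: k for k, v in _SPACE_CODES.items()}

#: absolute tolerance on the constraint residual for "on manifold" checks
ON_MANIFOLD_TOL = 1e-6
#: vectors shorter than this are treated as exactly zero tangents
ZERO_TANGENT_TOL = 1e-12
#: clamp width for arccos/arcosh argument drift
CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class Component:
    """One constant-curvature factor of a product manifold.

    ``dim`` is the manifold dimension; spherical and hyperbolic components
    occupy ``dim + 1`` ambient coordinates, euclidean components ``dim``.
    ``curvature_scale`` is the squared radius ``C`` (ignored for euclidean).
    """

    space_type: str
    dim: int
    curvature_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.space_type not in (SPHERICAL, HYPERBOLIC, EUCLIDEAN):
            raise ValueError(f"unknown space type {self.space_type!r}")
        if self.dim < 1:
            raise ValueError("component dimension must be >= 1")
        if self.space_type != EUCLIDEAN and self.curvature_scale <= 0:
            raise ValueError("curvature_scale must be positive")

    @property
    def ambient_dim(self) -> int:
        return self.dim if self.space_type == EUCLIDEAN else self.dim + 1

    @property
    def is_curved(self) -> bool:
        return self.space_type != EUCLIDEAN

    def __str__(self) -> str:
        code = _CODE_OF[self.space_type]
        if self.space_type == EUCLIDEAN:
            return f"{code}{self.dim}"
        return f"{code}{self.dim}_{self.curvature_scale:g}"


@dataclass(frozen=True)
class Signature:
    """Ordered decomposition of a product manifold into components."""

    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError("signature needs at least one component")
        object.__setattr__(self, "components", comps)

    @property
    def total_dim(self) -> int:
        """Total manifold dimension (sum of component dims)."""
        return sum(c.dim for c in self.components)

    @property
    def ambient_dims(self) -> tuple[int, ...]:
        return tuple(c.ambient_dim for c in self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def __str__(self) -> str:
        return " x ".join(str(c) for c in self.components)

    @classmethod
    def parse(cls, text: str) -> "Signature":
        """Parse a compact signature string such as ``"H2_1.0 x S3_1.0 x E2"``."""
        comps = []
        for token in text.replace("*", "x").split("x"):
            token = token.strip()
            if not token:
                continue
            code, rest = token[0].upper(), token[1:]
            if code not in _SPACE_CODES:
                raise ValueError(f"bad component token {token!r}")
            if "_" in rest:
                dim_s, curv_s = rest.split("_", 1)
                curv = float(curv_s)
            else:
                dim_s, curv = rest, 1.0
            comps.append(Component(_SPACE_CODES[code], int(dim_s), curv))
        return cls(tuple(comps))


# ---------------------------------------------------------------------------
# inner products and constraints


def minkowski_inner(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Lorentzian inner product with the time-like coordinate at index 0."""
    uv = u * v
    return -uv[..., 0] + uv[..., 1:].sum(axis=-1)


def constraint_residual(x: np.ndarray, component: Component) -> np.ndarray:
    """Absolute deviation of ``x`` from the component's constraint surface."""
    C = component.curvature_scale
    if component.space_type == SPHERICAL:
        return np.abs((x * x).sum(axis=-1) - C)
    if component.space_type == HYPERBOLIC:
        return np.abs(minkowski_inner(x, x) + C)
    return np.zeros(x.shape[:-1])


def is_on_manifold(x: np.ndarray, component: Component, tol: float = ON_MANIFOLD_TOL) -> bool:
    if component.space_type == HYPERBOLIC and np.any(x[..., 0] <= 0):
        return False
    return bool(np.all(constraint_residual(x, component) <= tol))


def project_to_manifold(x: np.ndarray, component: Component) -> np.ndarray:
    """Renormalize onto the constraint surface.

    Spheres rescale radially; hyperboloids recompute the time-like coordinate
    from the spatial part.  Used after optimizer retractions to stop
    floating-point drift from accumulating.
    """
    C = component.curvature_scale
    if component.space_type == SPHERICAL:
        norm = np.linalg.norm(x, axis=-1, keepdims=True)
        return np.sqrt(C) * x / np.maximum(norm, ZERO_TANGENT_TOL)
    if component.space_type == HYPERBOLIC:
        out = np.array(x, dtype=float, copy=True)
        spatial_sq = (out[..., 1:] ** 2).sum(axis=-1)
        out[..., 0] = np.sqrt(C + spatial_sq)
        return out
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# basepoints and random points


def origin(component: Component) -> np.ndarray:
    """Canonical basepoint: ``(sqrt(C), 0, ..., 0)`` or the zero vector."""
    p = np.zeros(component.ambient_dim)
    if component.is_curved:
        p[0] = np.sqrt(component.curvature_scale)
    return p


def random_point(component: Component, rng_seed) -> np.ndarray:
    """A single seeded random point satisfying the component constraint."""
    return random_points(component, 1, rng_seed)[0]


def random_points(component: Component, n: int, rng_seed) -> np.ndarray:
    """``n`` seeded random points, one per row.

    Spherical points are uniform on the sphere; hyperbolic points are the
    image under the exponential map at the origin of Gaussian tangent noise
    (sigma = 1); euclidean points are standard Gaussian.
    """
    rng = np.random.default_rng(rng_seed)
    C = component.curvature_scale
    if component.space_type == SPHERICAL:
        g = rng.standard_normal((n, component.ambient_dim))
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        return np.sqrt(C) * g / np.maximum(norm, ZERO_TANGENT_TOL)
    if component.space_type == HYPERBOLIC:
        v = np.zeros((n, component.ambient_dim))
        v[:, 1:] = rng.standard_normal((n, component.dim))
        base = np.broadcast_to(origin(component), v.shape)
        return exp_map(base, v, component)
    return rng.standard_normal((n, component.dim))


# ---------------------------------------------------------------------------
# tangent spaces


def project_to_tangent(x: np.ndarray, w: np.ndarray, component: Component) -> np.ndarray:
    """Orthogonal projection of an ambient vector onto the tangent space at x.

    Spherical projection uses the Euclidean inner product, hyperbolic the
    Minkowski one (``proj(w) = w + <x, w>_L x / C``); euclidean is identity.
    Idempotent.
    """
    C = component.curvature_scale
    if component.space_type == SPHERICAL:
        coef = (x * w).sum(axis=-1, keepdims=True) / C
        return w - coef * x
    if component.space_type == HYPERBOLIC:
        coef = minkowski_inner(x, w)[..., None] / C
        return w + coef * x
    return np.asarray(w, dtype=float)


def riemannian_gradient(x: np.ndarray, ambient_grad: np.ndarray, component: Component) -> np.ndarray:
    """Convert a Euclidean ambient gradient into the Riemannian gradient.

    On the hyperboloid the Minkowski metric correction (flip the sign of the
    time-like coordinate) is applied before tangent projection.
    """
    if component.space_type == HYPERBOLIC:
        g = np.array(ambient_grad, dtype=float, copy=True)
        g[..., 0] = -g[..., 0]
        return project_to_tangent(x, g, component)
    if component.space_type == SPHERICAL:
        return project_to_tangent(x, ambient_grad, component)
    return np.asarray(ambient_grad, dtype=float)


def tangent_norm(v: np.ndarray, component: Component) -> np.ndarray:
    """Riemannian norm of a tangent vector (Minkowski norm on hyperboloids)."""
    if component.space_type == HYPERBOLIC:
        sq = minkowski_inner(v, v)
        return np.sqrt(np.maximum(sq, 0.0))
    return np.linalg.norm(v, axis=-1)


def _check_tangent(x: np.ndarray, v: np.ndarray, component: Component) -> None:
    if component.space_type == SPHERICAL:
        resid = np.abs((x * v).sum(axis=-1))
    elif component.space_type == HYPERBOLIC:
        resid = np.abs(minkowski_inner(x, v))
    else:
        return
    scale = 1.0 + np.linalg.norm(v, axis=-1)
    if np.any(resid > 1e-4 * scale):
        raise ValueError("vector is not tangent at the given basepoint")


# ---------------------------------------------------------------------------
# exp / log / distance


def exp_map(x: np.ndarray, v: np.ndarray, component: Component) -> np.ndarray:
    """Exponential map: follow the geodesic from ``x`` with initial velocity ``v``.

    ``exp_x(v) = cos(r/sqrt(C)) x + sqrt(C) sin(r/sqrt(C)) v/r`` on spheres and
    ``cosh``/``sinh`` on hyperboloids, where ``r`` is the tangent norm of ``v``.
    Zero tangents return ``x`` exactly; non-tangent ``v`` raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if component.space_type == EUCLIDEAN:
        return x + v
    _check_tangent(x, v, component)
    C = component.curvature_scale
    sqrt_c = np.sqrt(C)
    r = tangent_norm(v, component)[..., None]
    small = r < ZERO_TANGENT_TOL
    r_safe = np.where(small, 1.0, r)
    t = r_safe / sqrt_c
    if component.space_type == SPHERICAL:
        out = np.cos(t) * x + sqrt_c * np.sin(t) * v / r_safe
    else:
        out = np.cosh(t) * x + sqrt_c * np.sinh(t) * v / r_safe
    # zero tangents return x exactly (the closed forms divide by ||v||)
    return np.where(small, x, project_to_manifold(out, component))


def _clamped(arg: np.ndarray, kind: str) -> np.ndarray:
    """Clamp arccos arguments into [-1, 1] and arcosh arguments into [1, inf)."""
    if kind == "acos":
        bad = (arg < -1.0 - CLAMP_TOL * 10) | (arg > 1.0 + CLAMP_TOL * 10)
        clamped = np.clip(arg, -1.0, 1.0)
    else:
        bad = arg < 1.0 - CLAMP_TOL * 10
        clamped = np.maximum(arg, 1.0)
    if np.any(bad):
        logger.debug("clamped %d %s argument(s) beyond drift tolerance", int(np.sum(bad)), kind)
    return clamped


def log_map(x: np.ndarray, y: np.ndarray, component: Component) -> np.ndarray:
    """Logarithmic map: the tangent vector at ``x`` pointing to ``y``.

    Inverse of :func:`exp_map`; its tangent norm equals the geodesic distance.
    Spherical antipodal pairs have no well-defined direction and raise
    ``ValueError``; identical points return the zero vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if component.space_type == EUCLIDEAN:
        return y - x
    C = component.curvature_scale
    d = component_distance(x, y, component)[..., None]
    if component.space_type == SPHERICAL:
        u = y - ((x * y).sum(axis=-1, keepdims=True) / C) * x
        un = np.linalg.norm(u, axis=-1, keepdims=True)
        antipodal = (un < 1e-9) & (d > 1e-6)
        if np.any(antipodal):
            raise ValueError("log map undefined for antipodal points on the sphere")
    else:
        u = y + (minkowski_inner(x, y)[..., None] / C) * x
        un = np.sqrt(np.maximum(minkowski_inner(u, u), 0.0))[..., None]
    small = un < ZERO_TANGENT_TOL
    out = d * u / np.where(small, 1.0, un)
    return np.where(small, 0.0, out)


def component_distance(x: np.ndarray, y: np.ndarray, component: Component) -> np.ndarray:
    """Geodesic distance within a single component.

    ``sqrt(C) arccos(<x,y>/C)`` on spheres, ``sqrt(C) arcosh(-<x,y>_L/C)`` on
    hyperboloids, the Euclidean norm of the difference otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError("ambient dimensions do not match")
    C = component.curvature_scale
    if component.space_type == SPHERICAL:
        arg = _clamped((x * y).sum(axis=-1) / C, "acos")
        return np.sqrt(C) * np.arccos(arg)
    if component.space_type == HYPERBOLIC:
        arg = _clamped(-minkowski_inner(x, y) / C, "acosh")
        return np.sqrt(C) * np.arccosh(arg)
    return np.linalg.norm(x - y, axis=-1)


def pairwise_component_distance(X: np.ndarray, component: Component) -> np.ndarray:
    """All-pairs component distances between the rows of ``X`` (n x n matrix)."""
    X = np.asarray(X, dtype=float)
    C = component.curvature_scale
    if component.space_type == SPHERICAL:
        arg = _clamped((X @ X.T) / C, "acos")
        D = np.sqrt(C) * np.arccos(arg)
    elif component.space_type == HYPERBOLIC:
        G = X @ X.T - 2.0 * np.outer(X[:, 0], X[:, 0])
        arg = _clamped(-G / C, "acosh")
        D = np.sqrt(C) * np.arccosh(arg)
    else:
        sq = (X * X).sum(axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
        D = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    return D


def product_distance(u, v, signature: Signature) -> float | np.ndarray:
    """Distance on the product manifold: sqrt of the sum of squared component
    distances (the product-metric decomposition)."""
    u, v = list(u), list(v)
    if len(u) != len(signature) or len(v) != len(signature):
        raise ValueError("point does not conform to signature")
    total = 0.0
    for xu, xv, comp in zip(u, v, signature):
        total = total + component_distance(np.asarray(xu), np.asarray(xv), comp) ** 2
    return np.sqrt(total)


# ---------------------------------------------------------------------------
# product points


def random_product_point(signature: Signature, rng_seed) -> list[np.ndarray]:
    rng = np.random.default_rng(rng_seed)
    return [random_point(c, rng) for c in signature]


def product_origin(signature: Signature) -> list[np.ndarray]:
    return [origin(c) for c in signature]


# ---------------------------------------------------------------------------
# origin-based tangent coordinates (used by tangent-space GCN layers)
#
# The tangent space at the origin of a curved component consists of ambient
# vectors with first coordinate zero, so tangent vectors are stored as their
# spatial part only (shape (n, dim)).  Each map comes with a vector-Jacobian
# product for reverse-mode differentiation through GCN layers.


def exp_origin(tangent: np.ndarray, component: Component) -> np.ndarray:
    """Exponential map at the origin from spatial tangent coordinates.

    Returns full ambient points of shape ``(n, ambient_dim)``.
    """
    V = np.asarray(tangent, dtype=float)
    if component.space_type == EUCLIDEAN:
        return V
    C = component.curvature_scale
    sqrt_c = np.sqrt(C)
    r = np.linalg.norm(V, axis=-1, keepdims=True)
    r_safe = np.maximum(r, ZERO_TANGENT_TOL)
    t = r_safe / sqrt_c
    out = np.empty(V.shape[:-1] + (component.ambient_dim,))
    if component.space_type == SPHERICAL:
        out[..., 0:1] = sqrt_c * np.cos(t)
        out[..., 1:] = sqrt_c * np.sin(t) * V / r_safe
    else:
        out[..., 0:1] = sqrt_c * np.cosh(t)
        out[..., 1:] = sqrt_c * np.sinh(t) * V / r_safe
    return out


def exp_origin_vjp(tangent: np.ndarray, component: Component, grad_out: np.ndarray) -> np.ndarray:
    """Backpropagate an ambient cotangent through :func:`exp_origin`."""
    V = np.asarray(tangent, dtype=float)
    if component.space_type == EUCLIDEAN:
        return np.asarray(grad_out, dtype=float)
    C = component.curvature_scale
    sqrt_c = np.sqrt(C)
    r = np.linalg.norm(V, axis=-1, keepdims=True)
    r_safe = np.maximum(r, 1e-9)
    t = r_safe / sqrt_c
    g0 = grad_out[..., 0:1]
    gs = grad_out[..., 1:]
    if component.space_type == SPHERICAL:
        d0 = -np.sin(t)            # d p0 / d r
        f = sqrt_c * np.sin(t) / r_safe
        fp = (np.cos(t) - f) / r_safe
    else:
        d0 = np.sinh(t)
        f = sqrt_c * np.sinh(t) / r_safe
        fp = (np.cosh(t) - f) / r_safe
    unit = V / r_safe
    dot = (gs * V).sum(axis=-1, keepdims=True)
    return g0 * d0 * unit + f * gs + fp * dot * unit


def log_origin(points: np.ndarray, component: Component) -> np.ndarray:
    """Log map at the origin, returned as spatial tangent coordinates."""
    P = np.asarray(points, dtype=float)
    if component.space_type == EUCLIDEAN:
        return P
    C = component.curvature_scale
    sqrt_c = np.sqrt(C)
    p0 = P[..., 0:1]
    ps = P[..., 1:]
    s = np.linalg.norm(ps, axis=-1, keepdims=True)
    if component.space_type == SPHERICAL:
        d = sqrt_c * np.arccos(_clamped(p0 / sqrt_c, "acos"))
    else:
        d = sqrt_c * np.arccosh(_clamped(p0 / sqrt_c, "acosh"))
    s_safe = np.maximum(s, ZERO_TANGENT_TOL)
    return np.where(s < ZERO_TANGENT_TOL, 0.0, d * ps / s_safe)


def log_origin_vjp(points: np.ndarray, component: Component, grad_out: np.ndarray) -> np.ndarray:
    """Backpropagate a spatial cotangent through :func:`log_origin`."""
    P = np.asarray(points, dtype=float)
    if component.space_type == EUCLIDEAN:
        return np.asarray(grad_out, dtype=float)
    C = component.curvature_scale
    sqrt_c = np.sqrt(C)
    p0 = P[..., 0:1]
    ps = P[..., 1:]
    s = np.linalg.norm(ps, axis=-1, keepdims=True)
    s_safe = np.maximum(s, 1e-9)
    u = p0 / sqrt_c
    if component.space_type == SPHERICAL:
        d = sqrt_c * np.arccos(np.clip(u, -1.0, 1.0))
        dd_dp0 = -1.0 / np.sqrt(np.maximum(1.0 - u * u, 1e-12))
    else:
        d = sqrt_c * np.arccosh(np.maximum(u, 1.0))
        dd_dp0 = 1.0 / np.sqrt(np.maximum(u * u - 1.0, 1e-12))
    dot = (grad_out * ps).sum(axis=-1, keepdims=True)
    grad = np.empty_like(P)
    grad[..., 0:1] = dd_dp0 * dot / s_safe
    grad[..., 1:] = (d / s_safe) * grad_out - (d / s_safe**3) * dot * ps
    return grad
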