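"""Distortion-minimizing node embeddings on product manifolds.

An embedding maps every graph node to a point of a fixed-signature product
manifold.  Training minimizes the relative squared-distance deviation

    L(f) = sum_{u<v} ( (d_P(f(u), f(v)) / d_G(u, v))^2 - 1 )^2

over unordered node pairs by Riemannian stochastic gradient descent: ambient
gradients are converted to Riemannian gradients (tangent projection, with the
Minkowski metric correction on hyperboloids), scaled by the learning rate and
retracted through the exponential map.  Quality is reported as the average
graph-distance distortion

    D(f) = (1/P) sum_{u != v} |d_P(f(u), f(v)) - d_G(u, v)| / d_G(u, v),

zero for an isometric embedding.  A signature sweep enumerates product-space
signatures under a total-dimension budget (default 100) with up to three
components per space type and selects the one of minimum distortion,
flagging ties, for which no canonical representative space exists.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import manifolds as mf
from .graphs import GraphDistances, PathwayGraph, UNREACHABLE, is_connected, largest_component, shortest_path_distances
from .manifolds import Component, Signature

logger = logging.getLogger(__name__)

FULL_BATCH_MAX_NODES = 200
TIE_TOL = 1e-4


@dataclass(frozen=True)
class EmbeddingConfig:
    signature: Signature
    learning_rate: float = 0.1
    epochs: int = 1000
    batch_pairs: int | None = None  # None = full batch (all pairs)
    seed: int = 0
    #: learning rate decays exponentially to this fraction of its initial
    #: value over the run; 1.0 disables the schedule
    final_lr_fraction: float = 0.1


@dataclass
class NodeEmbedding:
    """The learned function f: one on-manifold point block per component.

    ``parts[i]`` has shape ``(n_nodes, ambient_dim_i)`` with rows in node
    order.
    """

    nodes: tuple[str, ...]
    signature: Signature
    parts: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.parts) != len(self.signature):
            raise ValueError("part count does not match signature")
        for X, comp in zip(self.parts, self.signature):
            if X.shape != (len(self.nodes), comp.ambient_dim):
                raise ValueError("part shape does not match signature")

    def point(self, node: str) -> list[np.ndarray]:
        i = self.nodes.index(node)
        return [X[i] for X in self.parts]

    def pairwise_distance(self) -> np.ndarray:
        """All-pairs product-manifold distances (n x n)."""
        total = np.zeros((len(self.nodes), len(self.nodes)))
        for X, comp in zip(self.parts, self.signature):
            total += mf.pairwise_component_distance(X, comp) ** 2
        return np.sqrt(total)

    def flat(self) -> np.ndarray:
        return np.concatenate(self.parts, axis=1)

    def max_constraint_residual(self) -> float:
        return max(
            float(np.max(mf.constraint_residual(X, comp), initial=0.0))
            for X, comp in zip(self.parts, self.signature)
        )

    @classmethod
    def random(cls, nodes, signature: Signature, seed: int) -> "NodeEmbedding":
        rng = np.random.default_rng(seed)
        parts = [mf.random_points(c, len(nodes), rng) for c in signature]
        return cls(tuple(nodes), signature, parts)


@dataclass
class EmbeddingResult:
    embedding: NodeEmbedding
    final_loss: float
    distortion: float
    loss_trace: list[float] = field(default_factory=list)
    diverged: bool = False


# ---------------------------------------------------------------------------
# serialization: TSV with a signature header


def write_embedding(emb: NodeEmbedding, path) -> None:
    flat = emb.flat()
    with open(path, "w") as fh:
        fh.write(f"# signature: {emb.signature}\n")
        for node, row in zip(emb.nodes, flat):
            coords = "\t".join(repr(float(x)) for x in row)
            fh.write(f"{node}\t{coords}\n")


def read_embedding(path) -> NodeEmbedding:
    nodes, rows = [], []
    signature = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# signature:"):
                signature = Signature.parse(line.split(":", 1)[1])
                continue
            if not line:
                continue
            parts = line.split("\t")
            nodes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if signature is None:
        raise ValueError(f"{path}: missing signature header")
    flat = np.asarray(rows)
    parts_out, start = [], 0
    for comp in signature:
        parts_out.append(flat[:, start : start + comp.ambient_dim])
        start += comp.ambient_dim
    return NodeEmbedding(tuple(nodes), signature, parts_out)


# ---------------------------------------------------------------------------
# loss and distortion


def _check_cover(emb: NodeEmbedding, d: GraphDistances) -> np.ndarray:
    if emb.nodes != d.nodes:
        raise ValueError("embedding and distance matrix cover different nodes")
    DG = d.matrix.astype(float)
    if np.any(DG == UNREACHABLE):
        raise ValueError("unreachable pair: restrict to a connected component first")
    return DG


def distortion_loss(f: NodeEmbedding, d: GraphDistances, form: str = "squared") -> float:
    """Relative squared-distance loss summed over unordered node pairs.

    ``form="squared"`` uses ((d_P/d_G)^2 - 1)^2 per pair; ``form="abs"`` uses
    |(d_P/d_G)^2 - 1|.
    """
    DG = _check_cover(f, d)
    DP = f.pairwise_distance()
    iu = np.triu_indices(len(f.nodes), k=1)
    dev = (DP[iu] / DG[iu]) ** 2 - 1.0
    if form == "squared":
        return float(np.sum(dev**2))
    if form == "abs":
        return float(np.sum(np.abs(dev)))
    raise ValueError(f"unknown loss form {form!r}")


def average_distortion(f: NodeEmbedding, d: GraphDistances, normalization: str = "pairs") -> float:
    """Mean relative distance deviation |d_P - d_G| / d_G.

    ``normalization="pairs"`` averages over the ordered pairs u != v;
    ``"v_squared"`` divides the same sum by |V|^2 instead.
    """
    DG = _check_cover(f, d)
    DP = f.pairwise_distance()
    n = len(f.nodes)
    iu = np.triu_indices(n, k=1)
    total = 2.0 * float(np.sum(np.abs(DP[iu] - DG[iu]) / DG[iu]))
    if normalization == "pairs":
        return total / (n * n - n)
    if normalization == "v_squared":
        return total / (n * n)
    raise ValueError(f"unknown normalization {normalization!r}")


# ---------------------------------------------------------------------------
# gradients


def _pair_weight(DP2: np.ndarray, DG: np.ndarray, form: str) -> np.ndarray:
    """d loss / d (component distance) shared factor: returns W with
    W[u,v] = d l_uv / d rho_uv * 2 / d_G^2, so that the per-component
    contribution is W * D_c (chain through rho = sum_c D_c^2 / d_G^2)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = DP2 / DG**2
        dev = rho - 1.0
        if form == "squared":
            dl_drho = 2.0 * dev
        else:
            dl_drho = np.sign(dev)
        W = dl_drho * 2.0 / DG**2
    W[~np.isfinite(W)] = 0.0
    np.fill_diagonal(W, 0.0)
    return W


def _component_grads(parts, signature, W) -> list[np.ndarray]:
    """Ambient gradients per component given the shared pair weights W.

    W is symmetric with zero diagonal; grad for node u sums over all v != u,
    matching the unordered-pair loss.  Overflow in a diverging run is caught
    by the trainer's finite-loss check, so warnings are suppressed here.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        return _component_grads_inner(parts, signature, W)


def _component_grads_inner(parts, signature, W) -> list[np.ndarray]:
    grads = []
    for X, comp in zip(parts, signature):
        C = comp.curvature_scale
        if comp.space_type == mf.SPHERICAL:
            g = np.clip((X @ X.T) / C, -1.0, 1.0)
            D = np.sqrt(C) * np.arccos(g)
            S = 1.0 / np.sqrt(np.maximum(1.0 - g * g, 1e-12))
            S[np.abs(g) > 1.0 - 1e-9] = 0.0  # cut locus / coincident: subgradient 0
            M = W * D * S
            np.fill_diagonal(M, 0.0)
            grads.append(-(M @ X) / np.sqrt(C))
        elif comp.space_type == mf.HYPERBOLIC:
            G = X @ X.T - 2.0 * np.outer(X[:, 0], X[:, 0])
            w_arg = np.maximum(-G / C, 1.0)
            D = np.sqrt(C) * np.arccosh(w_arg)
            S = 1.0 / np.sqrt(np.maximum(w_arg * w_arg - 1.0, 1e-12))
            S[w_arg < 1.0 + 1e-12] = 0.0
            M = W * D * S
            np.fill_diagonal(M, 0.0)
            grad = -(M @ X) / np.sqrt(C)
            grad[:, 0] = -grad[:, 0]  # d<x,y>_L/dx carries the Minkowski sign
            grads.append(grad)
        else:
            D = mf.pairwise_component_distance(X, comp)
            with np.errstate(divide="ignore", invalid="ignore"):
                R = W  # dl/d(D^2) pairwise; euclidean d(D^2)/dx = 2(x - y)
            M = R.copy()
            np.fill_diagonal(M, 0.0)
            grads.append(M.sum(axis=1, keepdims=True) * X - M @ X)
    return grads


def loss_and_gradients(
    emb: NodeEmbedding, DG: np.ndarray, form: str = "squared"
) -> tuple[float, list[np.ndarray]]:
    """Pair loss summed over unordered pairs, with its ambient gradients."""
    n = len(emb.nodes)
    DP2 = np.zeros((n, n))
    for X, comp in zip(emb.parts, emb.signature):
        DP2 += mf.pairwise_component_distance(X, comp) ** 2
    W = _pair_weight(DP2, DG, form)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = DP2[iu] / DG[iu] ** 2 - 1.0
    loss = float(np.sum(dev**2 if form == "squared" else np.abs(dev)))
    grads = _component_grads(emb.parts, emb.signature, W)
    return loss, grads


def riemannian_sgd_step(
    f: NodeEmbedding, gradients: list[np.ndarray], lr: float, max_step_norm: float = 1.0
) -> NodeEmbedding:
    """One Riemannian SGD step: project ambient gradients to the tangent
    space, step along -lr * grad through the exponential map, re-project.

    Per-point step lengths are clipped to ``max_step_norm`` geodesic units;
    gradients blow up near the spherical cut locus and an uncapped step can
    overshoot the injectivity radius.
    """
    new_parts = []
    for X, G, comp in zip(f.parts, gradients, f.signature):
        if G.shape != X.shape:
            raise ValueError("gradient shape mismatch")
        if not np.all(np.isfinite(G)):
            raise FloatingPointError("NaN/inf in gradient")
        h = mf.riemannian_gradient(X, G, comp)
        step = -lr * h
        if max_step_norm is not None:
            norms = mf.tangent_norm(step, comp)[..., None]
            scale = np.minimum(1.0, max_step_norm / np.maximum(norms, 1e-12))
            step = step * scale
        new_parts.append(mf.exp_map(X, step, comp))
    return NodeEmbedding(f.nodes, f.signature, new_parts)


def train_embedding(g: PathwayGraph, config: EmbeddingConfig, loss_form: str = "squared") -> EmbeddingResult:
    """Random-initialize and train an embedding to minimize distance distortion.

    Full-batch pair gradients for graphs of up to ~200 nodes, sampled pair
    minibatches above (``config.batch_pairs``).  On divergence the last
    finite state is returned with ``diverged=True``.
    """
    if not is_connected(g):
        logger.warning("graph not connected; embedding the largest component")
        g = largest_component(g)
    d = shortest_path_distances(g)
    DG = d.matrix.astype(float)
    emb = NodeEmbedding.random(g.nodes, config.signature, config.seed)
    n = g.n_nodes
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), 7]))
    use_full = config.batch_pairs is None and n <= FULL_BATCH_MAX_NODES
    decay = (
        config.final_lr_fraction ** (1.0 / max(config.epochs, 1))
        if 0 < config.final_lr_fraction < 1
        else 1.0
    )
    lr = config.learning_rate
    trace: list[float] = []
    for _ in range(config.epochs):
        if use_full:
            loss, grads = loss_and_gradients(emb, DG, loss_form)
        else:
            loss, grads = _minibatch_loss_and_gradients(emb, DG, config, rng, loss_form)
        if not np.isfinite(loss):
            logger.warning("loss diverged; returning last finite state")
            return EmbeddingResult(emb, trace[-1] if trace else float("nan"),
                                   average_distortion(emb, d), trace, diverged=True)
        trace.append(loss)
        emb = riemannian_sgd_step(emb, grads, lr)
        lr *= decay
    final_loss, _ = loss_and_gradients(emb, DG, loss_form)
    return EmbeddingResult(emb, final_loss, average_distortion(emb, d), trace)


def _minibatch_loss_and_gradients(emb, DG, config, rng, form):
    n = len(emb.nodes)
    k = config.batch_pairs or 4 * n
    i = rng.integers(0, n, size=2 * k)
    j = rng.integers(0, n, size=2 * k)
    keep = i != j
    i, j = i[keep][:k], j[keep][:k]
    mask = np.zeros((n, n), dtype=bool)
    mask[i, j] = True
    mask |= mask.T
    DP2 = np.zeros((n, n))
    for X, comp in zip(emb.parts, emb.signature):
        DP2 += mf.pairwise_component_distance(X, comp) ** 2
    W = _pair_weight(DP2, DG, form)
    W[~mask] = 0.0
    n_sampled = max(int(mask.sum()) // 2, 1)
    n_total = n * (n - 1) // 2
    scale = n_total / n_sampled  # unbiased estimate of the full pair sum
    sel = np.triu(mask, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = DP2[sel] / DG[sel] ** 2 - 1.0
    loss = scale * float(np.sum(dev**2 if form == "squared" else np.abs(dev)))
    return loss, _component_grads(emb.parts, emb.signature, W * scale)


# ---------------------------------------------------------------------------
# signature enumeration and sweep


def _even_split(total: int, k: int) -> tuple[int, ...]:
    base, extra = divmod(total, k)
    return tuple(base + 1 if i < extra else base for i in range(k))


def signature_grid(
    total_dim: int = 100,
    max_components_per_type: int = 3,
    dim_choices: list[int] | None = None,
    lr_choices: tuple[float, ...] = (0.01, 0.1),
    curvature_choices: tuple[float, ...] = (1.0,),
    epochs: int = 1000,
    seed: int = 0,
) -> list[EmbeddingConfig]:
    """Enumerate sweep configurations under the signature constraints.

    Every emitted signature has 0..max components per space type (at least
    one component overall) and total manifold dimension exactly
    ``total_dim``.  With ``dim_choices=None`` the budget is split as evenly
    as possible across components; otherwise all assignments of the given
    dimensions summing to the budget are enumerated.  The result is
    deduplicated and deterministic.
    """
    kinds = (mf.HYPERBOLIC, mf.SPHERICAL, mf.EUCLIDEAN)
    seen: set[str] = set()
    configs: list[EmbeddingConfig] = []
    rng = range(max_components_per_type + 1)
    for m, s, e in itertools.product(rng, rng, rng):
        k = m + s + e
        if k == 0 or k > total_dim:
            continue
        types = (mf.HYPERBOLIC,) * m + (mf.SPHERICAL,) * s + (mf.EUCLIDEAN,) * e
        if dim_choices is None:
            dim_options = [_even_split(total_dim, k)]
        else:
            dim_options = [
                dims
                for dims in itertools.product(sorted(dim_choices), repeat=k)
                if sum(dims) == total_dim
            ]
        for dims in dim_options:
            for curv in curvature_choices:
                comps = []
                for t, dim in zip(types, dims):
                    comps.append(Component(t, dim, curv if t != mf.EUCLIDEAN else 1.0))
                # canonical order within each type: descending dimension
                comps = [
                    c
                    for kind in kinds
                    for c in sorted(
                        (c for c in comps if c.space_type == kind),
                        key=lambda c: -c.dim,
                    )
                ]
                sig = Signature(tuple(comps))
                if sig.total_dim != total_dim:
                    continue
                for lr in lr_choices:
                    key = f"{sig}|{lr}"
                    if key in seen:
                        continue
                    seen.add(key)
                    configs.append(EmbeddingConfig(sig, lr, epochs, None, seed))
    if not configs:
        logger.warning("signature grid is empty under the given constraints")
    return configs


def spherical_curvature_scale(g: PathwayGraph) -> float:
    """Curvature scale that lets a sphere carry the graph's diameter.

    A sphere of squared radius C has geodesic diameter pi*sqrt(C); distances
    beyond it are unrepresentable, so spherical components embedded at the
    default C=1 cannot express graph distances above pi.  Matching
    ``C = (diam(G)/pi)^2`` makes the sphere's farthest-point distance equal
    the graph diameter.
    """
    d = shortest_path_distances(g)
    diam = float(d.matrix.max())
    return max(1.0, (diam / np.pi) ** 2)


def geometry_recovery_grid(
    g: PathwayGraph,
    total_dim: int = 100,
    lr_choices: tuple[float, ...] = (0.01, 0.1),
    epochs: int = 1000,
    seed: int = 0,
) -> list[EmbeddingConfig]:
    """Sweep grid for geometry-recovery experiments: all one- and
    two-component signatures at the dimension budget, with curved components
    offered both at C=1 and at the graph's scale-matched curvature."""
    curvs = (1.0, spherical_curvature_scale(g))
    return signature_grid(
        total_dim=total_dim,
        max_components_per_type=1,
        lr_choices=lr_choices,
        curvature_choices=tuple(dict.fromkeys(curvs)),
        epochs=epochs,
        seed=seed,
    )


@dataclass
class SweepResult:
    best: EmbeddingConfig | None
    tie: bool
    results: list[tuple[EmbeddingConfig, EmbeddingResult]]

    @property
    def best_result(self) -> EmbeddingResult | None:
        if self.best is None:
            return None
        for cfg, res in self.results:
            if cfg is self.best:
                return res
        return None


def select_best(
    scored: list[tuple[EmbeddingConfig, float]], tie_tol: float = TIE_TOL
) -> tuple[EmbeddingConfig | None, bool]:
    """Minimum-distortion configuration, or a tie flag.

    Distinct signatures whose distortions agree with the minimum within the
    relative tolerance make the selection ambiguous (tie); several learning
    rates reaching the minimum with the *same* signature do not.
    """
    if not scored:
        raise ValueError("nothing to select from")
    best_cfg, best_val = min(scored, key=lambda cv: cv[1])
    for cfg, val in scored:
        if str(cfg.signature) == str(best_cfg.signature):
            continue
        if (val - best_val) / max(best_val, 1e-12) < tie_tol:
            return None, True
    return best_cfg, False


def sweep_and_select(g: PathwayGraph, grid: list[EmbeddingConfig], tie_tol: float = TIE_TOL) -> SweepResult:
    """Train every configuration and select the minimum-distortion signature.

    If several signatures attain the minimum within a relative tie tolerance
    the sweep is flagged as tied (no canonical best space exists) and no
    best configuration is returned.
    """
    if not grid:
        raise ValueError("empty sweep grid")
    results = []
    for cfg in grid:
        res = train_embedding(g, cfg)
        results.append((cfg, res))
    finite = [(c, r) for c, r in results if np.isfinite(r.distortion) and not r.diverged]
    if not finite:
        raise RuntimeError("all sweep runs diverged")
    best_cfg, tie = select_best([(c, r.distortion) for c, r in finite], tie_tol)
    return SweepResult(best_cfg, tie, results)
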