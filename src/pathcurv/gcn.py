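"""Mixed-curvature product graph convolutional network for edge prediction.

One GCN stack runs per signature component.  Each layer maps the component's
points into the tangent space at the origin via the log map, applies a
standard graph-convolution update there (symmetrically normalized
aggregation ``D^{-1/2}(A+I)D^{-1/2}``, a linear transform, an optional
pointwise nonlinearity), and maps the result back onto the manifold via the
exp map.  Edges are scored per component by a Fermi-Dirac decoder on the
component geodesic distance,

    s_c(u, v) = 1 / ( exp( (d_c(u,v)^2 - r_c) / t_c ) + 1 ),

with trainable radius ``r_c`` and temperature ``t_c``; the final edge score
is the arithmetic mean of the component scores.  Training minimizes binary
cross-entropy on observed edges against uniformly sampled non-edges.

All trainable parameters in this architecture (layer weights and biases,
decoder radius and temperature) live in flat Euclidean space — node points
enter as fixed inputs and tangent operations use the origin basepoint — so
the Riemannian Adam optimizer reduces to standard Adam moments for them;
manifold-valued parameter groups (optional embedding fine-tuning) receive
tangent-space moments with exponential-map retraction.

Gradients are computed by reverse-mode accumulation through the exp/log
maps, layer algebra and decoder; the vector-Jacobian products live next to
the maps in :mod:`pathcurv.manifolds` and are finite-difference checked in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import manifolds as mf
from .graphs import PathwayGraph
from .manifolds import Component, Signature

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# embedding slicing and lifting


def slice_embedding(vectors: np.ndarray, signature: Signature) -> list[np.ndarray]:
    """Split flat node vectors into one contiguous block per component.

    Every slice has dimension ``floor(total / n_components)``; trailing
    remainder dimensions are dropped (a 100-dimensional embedding with a
    7-component signature yields 7 slices of dimension 14, dropping 2).
    """
    vectors = np.asarray(vectors, dtype=float)
    total = vectors.shape[1]
    k = len(signature)
    if k > total:
        raise ValueError("more components than embedding dimensions")
    width = total // k
    dropped = total - width * k
    if dropped:
        logger.warning("slicing drops %d trailing dimension(s)", dropped)
    return [vectors[:, i * width : (i + 1) * width] for i in range(k)]


def lift_to_manifold(features: np.ndarray, component: Component) -> np.ndarray:
    """Lift flat features onto the component manifold.

    Features are read as tangent coordinates at the origin (the constrained
    leading coordinate is implicitly zero) and pushed through the exp map;
    euclidean components pass through unchanged.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[-1] != component.dim:
        raise ValueError(
            f"feature dimension {features.shape[-1]} != component dim {component.dim}"
        )
    return mf.exp_origin(features, component)


def normalized_adjacency(g: PathwayGraph) -> np.ndarray:
    """Symmetrically normalized adjacency with self-loops."""
    A = g.adjacency() + np.eye(g.n_nodes)
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    return A * dinv[:, None] * dinv[None, :]


# ---------------------------------------------------------------------------
# model


@dataclass
class LayerSpec:
    in_dim: int
    out_dim: int
    component: Component
    use_bias: bool = True
    activation: str = "none"  # "none" or "relu"

    def __post_init__(self) -> None:
        if self.in_dim < 1 or self.out_dim < 1:
            raise ValueError("layer dimensions must be positive")


@dataclass
class GCNLayer:
    spec: LayerSpec
    W: np.ndarray
    b: np.ndarray


@dataclass
class ComponentGCN:
    """GCN stack plus Fermi-Dirac decoder for one signature component."""

    component: Component
    layers: list[GCNLayer]
    r: np.ndarray  # decoder radius, shape ()
    t: np.ndarray  # decoder temperature, shape ()


@dataclass
class ProductGCNModel:
    signature: Signature
    stacks: list[ComponentGCN]

    def parameters(self) -> list[np.ndarray]:
        out = []
        for stack in self.stacks:
            for layer in stack.layers:
                out.append(layer.W)
                if layer.spec.use_bias:
                    out.append(layer.b)
            out.append(stack.r)
            out.append(stack.t)
        return out

    @classmethod
    def build(
        cls,
        signature: Signature,
        depth: int = 2,
        seed: int = 0,
        decoder_r: float = 2.0,
        decoder_t: float = 1.0,
        activations: dict[str, str] | None = None,
    ) -> "ProductGCNModel":
        """Glorot-initialized model; one ``depth``-layer stack per component.

        Default nonlinearity is ReLU on euclidean tangents and identity on
        curved ones.
        """
        act_of = {
            mf.EUCLIDEAN: "relu",
            mf.SPHERICAL: "none",
            mf.HYPERBOLIC: "none",
        }
        act_of.update(activations or {})
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 17]))
        stacks = []
        for comp in signature:
            layers = []
            for li in range(depth):
                act = act_of[comp.space_type] if li < depth - 1 else "none"
                spec = LayerSpec(comp.dim, comp.dim, comp, True, act)
                limit = np.sqrt(6.0 / (spec.in_dim + spec.out_dim))
                W = rng.uniform(-limit, limit, size=(spec.in_dim, spec.out_dim))
                layers.append(GCNLayer(spec, W, np.zeros(spec.out_dim)))
            stacks.append(
                ComponentGCN(comp, layers, np.array(float(decoder_r)), np.array(float(decoder_t)))
            )
        return cls(signature, stacks)


def _activate(x: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "none":
        return x
    raise ValueError(f"unknown activation {name!r}")


def tangent_gcn_layer(
    points: np.ndarray, adjacency: np.ndarray, layer: GCNLayer
) -> np.ndarray:
    """One forward layer: log map at the origin, GCN update in the tangent
    space, exp map back onto the manifold."""
    comp = layer.spec.component
    T = mf.log_origin(points, comp)
    H = adjacency @ (T @ layer.W)
    if layer.spec.use_bias:
        H = H + layer.b
    H = _activate(H, layer.spec.activation)
    return mf.exp_origin(H, comp)


@dataclass
class _StackCache:
    points: list[np.ndarray] = field(default_factory=list)     # per-layer inputs
    tangents: list[np.ndarray] = field(default_factory=list)
    preact: list[np.ndarray] = field(default_factory=list)
    postact: list[np.ndarray] = field(default_factory=list)


def _stack_forward(stack: ComponentGCN, points: np.ndarray, A: np.ndarray):
    cache = _StackCache()
    P = points
    for layer in stack.layers:
        comp = layer.spec.component
        T = mf.log_origin(P, comp)
        Hpre = A @ (T @ layer.W)
        if layer.spec.use_bias:
            Hpre = Hpre + layer.b
        Hpost = _activate(Hpre, layer.spec.activation)
        cache.points.append(P)
        cache.tangents.append(T)
        cache.preact.append(Hpre)
        cache.postact.append(Hpost)
        P = mf.exp_origin(Hpost, comp)
        if not np.all(np.isfinite(P)):
            raise FloatingPointError("NaN propagated through a GCN layer")
    return P, cache


def _stack_backward(
    stack: ComponentGCN, A: np.ndarray, cache: _StackCache, grad_points: np.ndarray
):
    """Accumulate parameter gradients; returns gradient w.r.t. input points."""
    grads: dict[int, np.ndarray] = {}
    g_P = grad_points
    for li in reversed(range(len(stack.layers))):
        layer = stack.layers[li]
        comp = layer.spec.component
        g_H = mf.exp_origin_vjp(cache.postact[li], comp, g_P)
        if layer.spec.activation == "relu":
            g_H = g_H * (cache.preact[li] > 0)
        AtG = A.T @ g_H
        grads[2 * li] = cache.tangents[li].T @ AtG          # dW
        grads[2 * li + 1] = g_H.sum(axis=0)                 # db
        g_T = AtG @ layer.W.T
        g_P = mf.log_origin_vjp(cache.points[li], comp, g_T)
    return grads, g_P


# ---------------------------------------------------------------------------
# decoder


@dataclass
class EdgeScore:
    pair: tuple[str, str]
    component_scores: np.ndarray
    score: float


def fermi_dirac(dist_sq: np.ndarray, r: float, t: float) -> np.ndarray:
    z = np.clip((dist_sq - r) / t, -30.0, 30.0)
    return 1.0 / (np.exp(z) + 1.0)


def _pair_scores(model: ProductGCNModel, blocks: list[np.ndarray], I: np.ndarray, J: np.ndarray):
    """Component scores for node-index pairs; returns (scores (k,m), dists (k,m))."""
    comp_scores, dists = [], []
    for stack, X in zip(model.stacks, blocks):
        d = mf.component_distance(X[I], X[J], stack.component)
        comp_scores.append(fermi_dirac(d**2, float(stack.r), float(stack.t)))
        dists.append(d)
    return np.stack(comp_scores), np.stack(dists)


def decode_edge(u_points, v_points, model: ProductGCNModel, pair=("u", "v")) -> EdgeScore:
    """Score one node pair from its per-component points.

    The final score is the arithmetic mean of the per-component Fermi-Dirac
    probabilities and decreases monotonically in every component distance.
    """
    comp_scores = []
    for stack, xu, xv in zip(model.stacks, u_points, v_points):
        d = mf.component_distance(np.asarray(xu), np.asarray(xv), stack.component)
        comp_scores.append(float(fermi_dirac(np.asarray(d) ** 2, float(stack.r), float(stack.t))))
    comp_scores = np.array(comp_scores)
    return EdgeScore(tuple(pair), comp_scores, float(comp_scores.mean()))


def score_pairs(model: ProductGCNModel, blocks: list[np.ndarray], pairs_idx: np.ndarray) -> np.ndarray:
    """Mean-over-components scores for an (m, 2) array of node index pairs."""
    if len(pairs_idx) == 0:
        return np.zeros(0)
    I, J = pairs_idx[:, 0], pairs_idx[:, 1]
    comp_scores, _ = _pair_scores(model, blocks, I, J)
    return comp_scores.mean(axis=0)


# ---------------------------------------------------------------------------
# training


@dataclass
class GCNHyperparams:
    learning_rate: float = 0.01
    epochs: int = 100
    negatives_per_positive: int = 1
    seed: int = 0
    depth: int = 2
    finetune_embeddings: bool = False
    eval_every: int = 5
    #: keep the parameter snapshot with the best validation mean(AUROC, AP);
    #: validation metrics guide model training per the evaluation protocol
    early_stopping: bool = True


class Adam:
    """Adam with optional Riemannian parameter groups.

    Euclidean arrays receive the standard update.  Parameters registered as
    manifold points keep their moments in ambient coordinates, convert
    gradients to Riemannian gradients and retract through the exponential
    map after each step (moments are not parallel-transported).
    """

    def __init__(self, params: list[np.ndarray], lr: float, betas=(0.9, 0.999), eps=1e-8,
                 manifold_params: dict[int, Component] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.step_count = 0
        self.manifold_params = manifold_params or {}

    def step(self, grads: list[np.ndarray]) -> None:
        self.step_count += 1
        b1c = 1.0 - self.b1**self.step_count
        b2c = 1.0 - self.b2**self.step_count
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if g is None:
                continue
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("NaN/inf in parameter gradient")
            comp = self.manifold_params.get(i)
            if comp is not None:
                g = mf.riemannian_gradient(p, g, comp)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
            if comp is not None:
                step = mf.project_to_tangent(p, -update, comp)
                p[...] = mf.exp_map(p, step, comp)
            else:
                p -= update


def _bce_and_grad(scores: np.ndarray, labels: np.ndarray):
    s = np.clip(scores, 1e-7, 1.0 - 1e-7)
    loss = -np.mean(labels * np.log(s) + (1 - labels) * np.log(1 - s))
    grad = (s - labels) / (s * (1 - s)) / len(s)
    return float(loss), grad


def _loss_and_grads(model: ProductGCNModel, blocks, A, pairs_idx, labels, finetune=False):
    """Forward + reverse pass; returns (loss, parameter grads aligned with
    model.parameters(), input-block grads or None)."""
    # overflow in a diverging configuration surfaces as a FloatingPointError
    # at the layer or optimizer checks; silence the intermediate warnings
    with np.errstate(over="ignore", invalid="ignore"):
        return _loss_and_grads_inner(model, blocks, A, pairs_idx, labels, finetune)


def _loss_and_grads_inner(model, blocks, A, pairs_idx, labels, finetune=False):
    finals, caches = [], []
    for stack, X in zip(model.stacks, blocks):
        P, cache = _stack_forward(stack, X, A)
        finals.append(P)
        caches.append(cache)
    I, J = pairs_idx[:, 0], pairs_idx[:, 1]
    comp_scores, dists = _pair_scores(model, finals, I, J)
    scores = comp_scores.mean(axis=0)
    loss, g_score = _bce_and_grad(scores, labels)
    k = len(model.stacks)
    param_grads: list[np.ndarray] = []
    input_grads = [] if finetune else None
    for ci, (stack, P, cache) in enumerate(zip(model.stacks, finals, caches)):
        comp = stack.component
        s_c = comp_scores[ci]
        d = dists[ci]
        t = float(stack.t)
        r = float(stack.r)
        g_sc = g_score / k
        ds_ddsq = -s_c * (1 - s_c) / t
        g_dsq = g_sc * ds_ddsq
        g_r = float(np.sum(g_sc * s_c * (1 - s_c) / t))
        g_t = float(np.sum(g_sc * s_c * (1 - s_c) * (d**2 - r) / t**2))
        # d(d^2)/d endpoints, scattered over nodes
        Xi, Xj = P[I], P[J]
        C = comp.curvature_scale
        if comp.space_type == mf.SPHERICAL:
            g_arg = np.clip((Xi * Xj).sum(axis=1) / C, -1.0, 1.0)
            denom = np.sqrt(np.maximum(1.0 - g_arg**2, 1e-12))
            coef = -2.0 * d / (np.sqrt(C) * denom)
            coef[np.abs(g_arg) > 1.0 - 1e-9] = 0.0
            dd_i = coef[:, None] * Xj
            dd_j = coef[:, None] * Xi
        elif comp.space_type == mf.HYPERBOLIC:
            w = np.maximum(-mf.minkowski_inner(Xi, Xj) / C, 1.0)
            denom = np.sqrt(np.maximum(w**2 - 1.0, 1e-12))
            coef = -2.0 * d / (np.sqrt(C) * denom)
            coef[w < 1.0 + 1e-12] = 0.0
            Jj = Xj.copy()
            Jj[:, 0] = -Jj[:, 0]
            Ji = Xi.copy()
            Ji[:, 0] = -Ji[:, 0]
            dd_i = coef[:, None] * Jj
            dd_j = coef[:, None] * Ji
        else:
            dd_i = 2.0 * (Xi - Xj)
            dd_j = -dd_i
        g_P = np.zeros_like(P)
        np.add.at(g_P, I, g_dsq[:, None] * dd_i)
        np.add.at(g_P, J, g_dsq[:, None] * dd_j)
        layer_grads, g_in = _stack_backward(stack, A, cache, g_P)
        for li, layer in enumerate(stack.layers):
            param_grads.append(layer_grads[2 * li])
            if layer.spec.use_bias:
                param_grads.append(layer_grads[2 * li + 1])
        param_grads.append(np.array(g_r))
        param_grads.append(np.array(g_t))
        if finetune:
            input_grads.append(g_in)
    return loss, param_grads, input_grads, scores


@dataclass
class FitTrace:
    loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    val_ap: list[float] = field(default_factory=list)
    best_epoch_index: int | None = None  # index into the validation lists

    @property
    def selected_val_auroc(self) -> float:
        if not self.val_auroc:
            return float("nan")
        i = self.best_epoch_index if self.best_epoch_index is not None else -1
        return self.val_auroc[i]

    @property
    def selected_val_ap(self) -> float:
        if not self.val_ap:
            return float("nan")
        i = self.best_epoch_index if self.best_epoch_index is not None else -1
        return self.val_ap[i]


def riemannian_adam_fit(
    model: ProductGCNModel,
    g_train: PathwayGraph,
    initial_blocks: list[np.ndarray],
    train_edges,
    val_edges,
    hyperparams: GCNHyperparams,
    exclude_edges=frozenset(),
) -> tuple[ProductGCNModel, FitTrace]:
    """Train the product GCN on the edge prediction task.

    Positives are the training edges; one uniform non-edge per positive is
    resampled each epoch.  Validation AUROC/AP against a fixed seeded
    negative sample are recorded every ``eval_every`` epochs.  Layer weights
    and decoder parameters receive standard Adam moments; when
    ``finetune_embeddings`` is set the input node points become manifold
    parameters with tangent moments and exp retraction.
    """
    from .edge_prediction import evaluate_model, sample_negatives

    hp = hyperparams
    idx = g_train.node_index()
    train_idx = np.array([[idx[u], idx[v]] for u, v in sorted(train_edges)], dtype=int)
    val_idx = np.array([[idx[u], idx[v]] for u, v in sorted(val_edges)], dtype=int)
    if len(train_idx) == 0:
        raise ValueError("no training edges")
    A = normalized_adjacency(g_train)
    blocks = [np.array(X, dtype=float, copy=True) for X in initial_blocks]
    exclude = frozenset(train_edges) | frozenset(val_edges) | frozenset(exclude_edges)
    rng_seed = np.random.SeedSequence([int(hp.seed) % (2**31), 23])
    rng = np.random.default_rng(rng_seed)
    if len(val_idx):
        val_negs = sample_negatives(g_train, len(val_idx), exclude, seed=int(rng.integers(2**31)))
        val_neg_idx = np.array([[idx[u], idx[v]] for u, v in sorted(val_negs)], dtype=int)
    params = model.parameters()
    manifold_params: dict[int, Component] = {}
    if hp.finetune_embeddings:
        base = len(params)
        for ci, comp in enumerate(model.signature):
            params.append(blocks[ci])
            manifold_params[base + ci] = comp
    opt = Adam(params, hp.learning_rate, manifold_params=manifold_params)
    trace = FitTrace()
    best = {"crit": -np.inf, "snapshot": None}

    def validate() -> None:
        if not len(val_idx):
            return
        finals = _forward_all(model, blocks, A)
        pos = score_pairs(model, finals, val_idx)
        neg = score_pairs(model, finals, val_neg_idx)
        auroc, ap = evaluate_model(pos, neg)
        trace.val_auroc.append(auroc)
        trace.val_ap.append(ap)
        crit = (auroc + ap) / 2.0
        if hp.early_stopping and crit > best["crit"]:
            best["crit"] = crit
            best["snapshot"] = [np.array(p, copy=True) for p in params]
            trace.best_epoch_index = len(trace.val_auroc) - 1

    if hp.epochs == 0:
        validate()
        return model, trace
    if hp.early_stopping:
        validate()  # the untrained model is a valid early-stopping candidate
    n_pos = len(train_idx)
    for epoch in range(hp.epochs):
        negs = sample_negatives(
            g_train, hp.negatives_per_positive * n_pos, exclude, seed=int(rng.integers(2**31))
        )
        neg_idx = np.array([[idx[u], idx[v]] for u, v in sorted(negs)], dtype=int)
        pairs_idx = np.concatenate([train_idx, neg_idx])
        labels = np.concatenate([np.ones(n_pos), np.zeros(len(neg_idx))])
        loss, pgrads, igrads, _ = _loss_and_grads(
            model, blocks, A, pairs_idx, labels, finetune=hp.finetune_embeddings
        )
        if hp.finetune_embeddings:
            pgrads = pgrads + igrads
        trace.loss.append(loss)
        opt.step(pgrads)
        if (epoch + 1) % hp.eval_every == 0 or epoch == hp.epochs - 1:
            validate()
    if hp.early_stopping and best["snapshot"] is not None:
        for p, saved in zip(params, best["snapshot"]):
            p[...] = saved
    return model, trace


def _forward_all(model: ProductGCNModel, blocks, A) -> list[np.ndarray]:
    return [_stack_forward(stack, X, A)[0] for stack, X in zip(model.stacks, blocks)]


def predict_scores(
    model: ProductGCNModel, g: PathwayGraph, blocks: list[np.ndarray], pairs
) -> np.ndarray:
    """Scores for arbitrary node pairs under the trained model."""
    idx = g.node_index()
    pairs_idx = np.array([[idx[u], idx[v]] for u, v in pairs], dtype=int)
    A = normalized_adjacency(g)
    finals = _forward_all(model, blocks, A)
    return score_pairs(model, finals, pairs_idx)
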