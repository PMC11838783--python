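"""End-to-end edge-prediction evaluation pipeline.

Protocol: 95% of a pathway graph's edges train the model and 5% are held
out as an in-distribution validation set that guides hyperparameter
selection (highest mean of validation AUROC and AP); an optional external
candidate-edge table (scores 0-1000, STRING-style) supplies an
out-of-distribution test set after filtering at a minimum score of 500.
Four models are compared: Euclidean GCNs initialized with node2vec,
Laplacian and distortion-trained Euclidean embeddings, and a Product GCN
whose signature matches the minimum-distortion product-space embedding.
The Product GCN sweep additionally varies the component curvature over
three values, tripling its grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import manifolds as mf
from .baselines import WalkParams, laplacian_embed, node2vec_embed
from .embedding import (
    EmbeddingConfig,
    NodeEmbedding,
    geometry_recovery_grid,
    sweep_and_select,
    train_embedding,
)
from .gcn import GCNHyperparams, ProductGCNModel, predict_scores, riemannian_adam_fit
from .graphs import PathwayGraph
from .manifolds import Component, Signature

logger = logging.getLogger(__name__)

MIN_CANDIDATE_SCORE = 500
VAL_FRACTION = 0.05


@dataclass(frozen=True)
class EdgeSplit:
    train_edges: frozenset[tuple[str, str]]
    val_edges: frozenset[tuple[str, str]]
    seed: int


def split_edges(g: PathwayGraph, val_fraction: float = VAL_FRACTION, seed: int = 0) -> EdgeSplit:
    """Uniform random train/validation edge split.

    The validation set holds ``round(val_fraction * |E|)`` edges (at least
    one); training-graph disconnection is logged but not prevented.
    """
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    if g.n_edges < 2:
        raise ValueError("graph needs at least 2 edges to split")
    edges = sorted(g.edges)
    n_val = max(1, round(val_fraction * len(edges)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 29]))
    val_pos = rng.choice(len(edges), size=n_val, replace=False)
    val = frozenset(edges[i] for i in val_pos)
    train = frozenset(g.edges) - val
    import networkx as nx

    tg = nx.Graph(list(train))
    tg.add_nodes_from(g.nodes)
    if not nx.is_connected(tg):
        logger.info("edge split leaves the training graph disconnected")
    return EdgeSplit(train, val, seed)


def sample_negatives(g: PathwayGraph, count: int, exclude=frozenset(), seed: int = 0) -> frozenset:
    """Uniformly sample unordered non-adjacent node pairs.

    Pairs in ``exclude`` (canonically ordered) are never returned; requesting
    more than the number of available non-edges raises ``ValueError``.
    """
    exclude = {tuple(sorted(e)) for e in exclude}
    nodes = g.nodes
    non_edges = [
        (u, v)
        for u, v in itertools.combinations(nodes, 2)
        if not g.has_edge(u, v) and (u, v) not in exclude
    ]
    if count > len(non_edges):
        raise ValueError(f"requested {count} negatives but only {len(non_edges)} non-edges exist")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 31]))
    chosen = rng.choice(len(non_edges), size=count, replace=False)
    return frozenset(non_edges[i] for i in chosen)


def filter_candidate_edges(
    table: pd.DataFrame, g: PathwayGraph, min_score: int = MIN_CANDIDATE_SCORE
) -> frozenset[tuple[str, str]]:
    """External test edges: candidate rows scoring at least ``min_score``
    whose endpoints are pathway nodes and which are not already graph edges.

    Idempotent and row-order independent; an empty result is allowed.
    """
    nodes = set(g.nodes)
    kept = set()
    for row in table.itertuples(index=False):
        a, b, score = str(row.node_a), str(row.node_b), int(row.score)
        if score < min_score or a == b:
            continue
        if a not in nodes or b not in nodes:
            continue
        pair = (a, b) if a < b else (b, a)
        if pair in g.edges:
            continue
        kept.add(pair)
    if not kept:
        logger.info("candidate filter produced an empty test set")
    return frozenset(kept)


def evaluate_model(pos_scores, neg_scores) -> tuple[float, float]:
    """AUROC (rank-based, tie-corrected) and average precision."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative score")
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.concatenate([pos, neg])
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkConfig:
    val_fraction: float = VAL_FRACTION
    min_score: int = MIN_CANDIDATE_SCORE
    seed: int = 0
    total_dim: int = 100
    embedding_epochs: int = 1000
    embedding_lr: float = 0.01
    gcn_epochs: int = 100
    lr_choices: tuple[float, ...] = (0.005, 0.01, 0.05)
    depth_choices: tuple[int, ...] = (2,)
    curvature_choices: tuple[float, ...] = (0.5, 1.0, 2.0)
    product_signature: Signature | None = None  # None: select by sweep
    sweep_epochs: int = 600
    node2vec_params: WalkParams = field(default_factory=WalkParams)
    methods: tuple[str, ...] = ("node2vec", "laplacian", "euclidean", "product")


@dataclass
class MethodReport:
    method: str
    val_auroc: float
    val_ap: float
    test_auroc: float | None
    test_ap: float | None
    hyperparams: dict


@dataclass
class EvaluationReport:
    methods: list[MethodReport]
    split: EdgeSplit
    product_signature: Signature | None
    product_tie: bool = False

    def method(self, name: str) -> MethodReport:
        for m in self.methods:
            if m.method == name:
                return m
        raise KeyError(name)


def _baseline_grid(config: BenchmarkConfig):
    return [
        {"learning_rate": lr, "depth": depth}
        for lr in config.lr_choices
        for depth in config.depth_choices
    ]


def _product_grid(config: BenchmarkConfig):
    return [
        {**hp, "curvature": c} for hp in _baseline_grid(config) for c in config.curvature_choices
    ]


def _rescale_curvature(blocks, signature: Signature, curvature: float):
    """Move pretrained component points onto manifolds of another curvature
    scale (radial rescale on spheres, recomputed time coordinate on
    hyperboloids)."""
    comps = [
        Component(c.space_type, c.dim, curvature if c.is_curved else 1.0) for c in signature
    ]
    sig = Signature(tuple(comps))
    out = [mf.project_to_manifold(X, c) for X, c in zip(blocks, sig)]
    return out, sig


def _fit_and_select(g, train_graph, blocks_of, signature_of, split, grid, config, test_edges):
    """Sweep one method's grid, select by mean(val AUROC, val AP)."""
    best = None
    for hp in grid:
        sig = signature_of(hp)
        blocks = blocks_of(hp)
        model = ProductGCNModel.build(sig, depth=hp["depth"], seed=config.seed)
        fit_hp = GCNHyperparams(
            learning_rate=hp["learning_rate"],
            epochs=config.gcn_epochs,
            seed=config.seed,
            depth=hp["depth"],
        )
        try:
            model, trace = riemannian_adam_fit(
                model, train_graph, blocks, split.train_edges, split.val_edges, fit_hp
            )
        except FloatingPointError:
            logger.warning("configuration %s diverged; skipping", hp)
            continue
        val_auroc = trace.selected_val_auroc
        val_ap = trace.selected_val_ap
        crit = (val_auroc + val_ap) / 2.0
        if best is None or crit > best[0]:
            best = (crit, hp, model, blocks, val_auroc, val_ap)
    if best is None:
        raise RuntimeError("every hyperparameter configuration diverged")
    _, hp, model, blocks, val_auroc, val_ap = best
    test_auroc = test_ap = None
    if test_edges:
        neg = sample_negatives(
            g,
            len(test_edges),
            exclude=frozenset(g.edges) | frozenset(test_edges),
            seed=config.seed + 1,
        )
        pos_scores = predict_scores(model, train_graph, blocks, sorted(test_edges))
        neg_scores = predict_scores(model, train_graph, blocks, sorted(neg))
        test_auroc, test_ap = evaluate_model(pos_scores, neg_scores)
    return MethodReport("", val_auroc, val_ap, test_auroc, test_ap, dict(hp)), model


def run_benchmark(
    g: PathwayGraph, candidates: pd.DataFrame | None, config: BenchmarkConfig | None = None
) -> EvaluationReport:
    """Run the four-model edge-prediction comparison on one pathway graph.

    Validation metrics guide hyperparameter selection; external test metrics
    (when a candidate table is given) never feed back into selection.
    """
    config = config or BenchmarkConfig()
    split = split_edges(g, config.val_fraction, config.seed)
    train_graph = PathwayGraph(g.nodes, frozenset(split.train_edges))
    test_edges = (
        filter_candidate_edges(candidates, g, config.min_score)
        if candidates is not None and len(candidates)
        else frozenset()
    )
    reports: list[MethodReport] = []
    product_sig = config.product_signature
    tie = False

    def flat_blocks(vectors):
        return lambda hp: [np.asarray(vectors, dtype=float)]

    if "node2vec" in config.methods:
        emb = node2vec_embed(
            train_graph, dim=config.total_dim, walk_params=config.node2vec_params, seed=config.seed
        )
        sig = Signature((Component(mf.EUCLIDEAN, config.total_dim),))
        rep, _ = _fit_and_select(
            g, train_graph, flat_blocks(emb.vectors), lambda hp: sig, split,
            _baseline_grid(config), config, test_edges,
        )
        rep.method = "node2vec"
        reports.append(rep)

    if "laplacian" in config.methods:
        from .graphs import largest_component

        lap_graph = train_graph if _connected(train_graph) else largest_component(train_graph)
        emb = laplacian_embed(lap_graph)
        vectors = _align_flat(emb.nodes, emb.vectors, g)
        sig = Signature((Component(mf.EUCLIDEAN, emb.dim),))
        rep, _ = _fit_and_select(
            g, train_graph, flat_blocks(vectors), lambda hp: sig, split,
            _baseline_grid(config), config, test_edges,
        )
        rep.method = "laplacian"
        reports.append(rep)

    if "euclidean" in config.methods:
        sig = Signature((Component(mf.EUCLIDEAN, config.total_dim),))
        res = train_embedding(
            train_graph,
            EmbeddingConfig(sig, config.embedding_lr, config.embedding_epochs, seed=config.seed),
        )
        vectors = _align_vectors(res.embedding, g)
        rep, _ = _fit_and_select(
            g, train_graph, flat_blocks(vectors), lambda hp: sig, split,
            _baseline_grid(config), config, test_edges,
        )
        rep.method = "euclidean"
        reports.append(rep)

    if "product" in config.methods:
        emb_graph = train_graph
        if product_sig is None:
            grid = geometry_recovery_grid(
                emb_graph, total_dim=config.total_dim, epochs=config.sweep_epochs, seed=config.seed
            )
            sweep = sweep_and_select(emb_graph, grid)
            tie = sweep.tie
            if sweep.best is None:
                # tied sweep: no canonical space; fall back to the minimum-
                # distortion configuration for reporting purposes
                best_cfg = min(
                    (cr for cr in sweep.results if not cr[1].diverged),
                    key=lambda cr: cr[1].distortion,
                )[0]
            else:
                best_cfg = sweep.best
            product_sig = best_cfg.signature
            emb_cfg = replace(best_cfg, epochs=config.embedding_epochs)
        else:
            emb_cfg = EmbeddingConfig(
                product_sig, config.embedding_lr, config.embedding_epochs, seed=config.seed
            )
        res = train_embedding(emb_graph, emb_cfg)
        base_blocks = _align_blocks(res.embedding, g)

        def product_blocks(hp):
            blocks, _ = _rescale_curvature(base_blocks, product_sig, hp["curvature"])
            return blocks

        def product_sig_of(hp):
            _, sig = _rescale_curvature(base_blocks, product_sig, hp["curvature"])
            return sig

        rep, _ = _fit_and_select(
            g, train_graph, product_blocks, product_sig_of, split,
            _product_grid(config), config, test_edges,
        )
        rep.method = "product"
        reports.append(rep)

    return EvaluationReport(reports, split, product_sig, tie)


def _connected(g: PathwayGraph) -> bool:
    from .graphs import is_connected

    return is_connected(g)


def _align_vectors(emb: NodeEmbedding, g: PathwayGraph) -> np.ndarray:
    """Embedding rows aligned to g's node order; nodes missing from the
    embedding (disconnected during pretraining) get zero vectors."""
    return _align_blocks(emb, g)[0] if len(emb.signature) == 1 else np.concatenate(
        _align_blocks(emb, g), axis=1
    )


def _align_flat(nodes, vectors: np.ndarray, g: PathwayGraph) -> np.ndarray:
    pos = {u: i for i, u in enumerate(nodes)}
    out = np.zeros((g.n_nodes, vectors.shape[1]))
    for j, u in enumerate(g.nodes):
        if u in pos:
            out[j] = vectors[pos[u]]
    return out


def _align_blocks(emb: NodeEmbedding, g: PathwayGraph) -> list[np.ndarray]:
    pos = {u: i for i, u in enumerate(emb.nodes)}
    blocks = []
    for X, comp in zip(emb.parts, emb.signature):
        out = np.tile(mf.origin(comp), (g.n_nodes, 1)) if comp.is_curved else np.zeros(
            (g.n_nodes, comp.dim)
        )
        for j, u in enumerate(g.nodes):
            if u in pos:
                out[j] = X[pos[u]]
        blocks.append(out)
    return blocks
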