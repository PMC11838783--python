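"""Euclidean baseline embeddings and the post-hoc scaling optimization.

Two classical baselines are provided for comparison against product-manifold
embeddings: spectral embeddings from graph-Laplacian eigenvectors and
node2vec (skip-gram with negative sampling trained on biased random walks).
Neither optimizes graph-distance distortion directly, so their coordinates
carry an arbitrary global scale; a closed-form least-squares scaling

    min_{c > 0} sum_{i<j} ( c * d(x_i, x_j) / d_G(n_i, n_j) - 1 )^2

is applied before distortion is compared.  The minimizer is
``c* = sum r_ij / sum r_ij^2`` with ``r_ij = d(x_i, x_j) / d_G(n_i, n_j)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .graphs import GraphDistances, PathwayGraph, UNREACHABLE, is_connected, shortest_path_distances

logger = logging.getLogger(__name__)


@dataclass
class EuclideanEmbedding:
    """Flat real vectors, one row per node in node order."""

    nodes: tuple[str, ...]
    vectors: np.ndarray

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self.nodes.index(node)]

    def pairwise_distance(self) -> np.ndarray:
        return squareform(pdist(self.vectors))

    def scaled(self, c: float) -> "EuclideanEmbedding":
        return EuclideanEmbedding(self.nodes, c * self.vectors)


# ---------------------------------------------------------------------------
# graph Laplacian


def laplacian_embed(g: PathwayGraph) -> EuclideanEmbedding:
    """Rows of the eigenvector matrix of the combinatorial Laplacian L = D - A.

    Eigenvalues ascend, so the first coordinate is the constant null vector
    of a connected graph; the embedding dimension equals the node count.
    Eigenvector signs are fixed so each vector's largest-magnitude entry is
    positive, making the embedding deterministic.
    """
    if not is_connected(g):
        raise ValueError("Laplacian embedding requires a connected graph")
    A = g.adjacency()
    L = np.diag(A.sum(axis=1)) - A
    eigvals, eigvecs = np.linalg.eigh(L)
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return EuclideanEmbedding(g.nodes, eigvecs)


def laplacian_eigenvalues(g: PathwayGraph) -> np.ndarray:
    A = g.adjacency()
    return np.linalg.eigvalsh(np.diag(A.sum(axis=1)) - A)


# ---------------------------------------------------------------------------
# node2vec


@dataclass(frozen=True)
class WalkParams:
    """Biased second-order random-walk parameters (node2vec p/q semantics)."""

    return_bias: float = 1.0   # p: controls immediate backtracking
    inout_bias: float = 1.0    # q: interpolates BFS-like vs DFS-like walks
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 10


def generate_walks(g: PathwayGraph, params: WalkParams, seed: int) -> list[list[int]]:
    """Seeded biased random-walk corpus over node indices."""
    idx = g.node_index()
    neighbors = [[] for _ in range(g.n_nodes)]
    for u, v in sorted(g.edges):
        neighbors[idx[u]].append(idx[v])
        neighbors[idx[v]].append(idx[u])
    neighbors = [sorted(ns) for ns in neighbors]
    neighbor_sets = [set(ns) for ns in neighbors]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 11]))
    p, q = params.return_bias, params.inout_bias
    unbiased = p == 1.0 and q == 1.0
    walks = []
    for _ in range(params.walks_per_node):
        for start in range(g.n_nodes):
            if not neighbors[start]:
                continue
            walk = [start]
            prev = None
            while len(walk) < params.walk_length:
                cur = walk[-1]
                ns = neighbors[cur]
                if not ns:
                    break
                if unbiased or prev is None:
                    nxt = ns[rng.integers(len(ns))]
                else:
                    w = np.array(
                        [1.0 / p if n == prev else (1.0 if n in neighbor_sets[prev] else 1.0 / q) for n in ns]
                    )
                    nxt = ns[rng.choice(len(ns), p=w / w.sum())]
                prev = cur
                walk.append(nxt)
            walks.append(walk)
    return walks


def _skipgram_pairs(walks: list[list[int]], window: int) -> np.ndarray:
    centers, contexts = [], []
    for walk in walks:
        L = len(walk)
        for i, c in enumerate(walk):
            for j in range(max(0, i - window), min(L, i + window + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(walk[j])
    return np.stack([np.array(centers), np.array(contexts)], axis=1)


def node2vec_embed(
    g: PathwayGraph,
    dim: int = 100,
    walk_params: WalkParams | None = None,
    seed: int = 0,
    epochs: int = 2,
    negatives: int = 5,
    lr: float = 0.025,
    batch_size: int | None = None,
) -> EuclideanEmbedding:
    """Skip-gram-with-negative-sampling embedding of a random-walk corpus.

    Word2vec-style training on the walk corpus: each (center, context)
    window pair is a positive example; ``negatives`` contexts drawn from the
    unigram^(3/4) distribution are negatives.  Minibatched SGD with a
    linearly decaying learning rate; single-threaded and deterministic under
    the seed.
    """
    params = walk_params or WalkParams()
    walks = generate_walks(g, params, seed)
    if not walks:
        raise ValueError("graph has no edges to walk on")
    pairs = _skipgram_pairs(walks, params.window)
    n = g.n_nodes
    if batch_size is None:
        # cap duplicate-row accumulation within a batch: with b >> n the
        # scattered updates to one row compound and the iteration diverges
        batch_size = int(max(64, min(1024, 4 * n)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 13]))
    W = (rng.random((n, dim)) - 0.5) / dim     # input vectors
    Wc = np.zeros((n, dim))                    # context vectors
    counts = np.bincount(pairs[:, 1], minlength=n).astype(float)
    noise = counts**0.75
    noise /= noise.sum()
    n_steps = max(1, epochs * ((len(pairs) + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for lo in range(0, len(pairs), batch_size):
            batch = pairs[order[lo : lo + batch_size]]
            cur_lr = lr * max(1.0 - step / n_steps, 1e-4)
            step += 1
            c, o = batch[:, 0], batch[:, 1]
            neg = rng.choice(n, size=(len(batch), negatives), p=noise)
            vc = W[c]                                   # (b, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (b, 1+k)
            vt = Wc[targets]                            # (b, 1+k, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            label = np.zeros_like(score)
            label[:, 0] = 1.0
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            err = (label - sig) * cur_lr                # (b, 1+k)
            grad_vc = np.einsum("bk,bkd->bd", err, vt)
            grad_vt = err[..., None] * vc[:, None, :]
            np.add.at(W, c, grad_vc)
            np.add.at(Wc, targets.ravel(), grad_vt.reshape(-1, dim))
    return EuclideanEmbedding(g.nodes, W)


# ---------------------------------------------------------------------------
# scaling optimization and distortion


def _distance_ratios(e: EuclideanEmbedding, d: GraphDistances) -> np.ndarray:
    if e.nodes != d.nodes:
        raise ValueError("embedding and distance matrix cover different nodes")
    if np.any(d.matrix == UNREACHABLE):
        raise ValueError("unreachable pair: restrict to a connected component first")
    DE = e.pairwise_distance()
    iu = np.triu_indices(len(e.nodes), k=1)
    return DE[iu] / d.matrix[iu].astype(float)


def optimal_scaling(e: EuclideanEmbedding, d: GraphDistances) -> float:
    """Closed-form least-squares minimizer of the scaling objective."""
    r = _distance_ratios(e, d)
    denom = float(np.sum(r * r))
    if denom == 0.0:
        raise ValueError("degenerate embedding: all pairwise distances are zero")
    return float(np.sum(r)) / denom


def euclidean_distortion(e: EuclideanEmbedding, d: GraphDistances) -> float:
    """Average relative distance deviation of a Euclidean embedding."""
    r = _distance_ratios(e, d)
    return float(np.mean(np.abs(r - 1.0)))


def scaled_distortion(e: EuclideanEmbedding, d: GraphDistances) -> float:
    """Distortion after rescaling all vectors by the optimal factor c*."""
    c = optimal_scaling(e, d)
    return euclidean_distortion(e.scaled(c), d)
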