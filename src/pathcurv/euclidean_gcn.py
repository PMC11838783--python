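"""Plain Euclidean GCN with a Fermi-Dirac distance decoder.

A self-contained flat-space implementation of the edge-prediction model:
dense symmetric-normalized graph convolutions, ReLU between layers, a
Fermi-Dirac decoder on squared Euclidean distances and Adam on binary
cross-entropy.  It deliberately shares no forward/backward code with the
product GCN; with an all-euclidean signature the product model must
reproduce it step for step, which the test suite checks as the flat-space
reduction of the manifold machinery.

Seeding conventions (Glorot draws, negative-sample seed stream) match the
product trainer so runs are comparable draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import PathwayGraph


@dataclass
class PlainGCN:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    r: float
    t: float


def build_plain_gcn(dim: int, depth: int = 2, seed: int = 0, r: float = 2.0, t: float = 1.0) -> PlainGCN:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 17]))
    Ws, bs = [], []
    for _ in range(depth):
        limit = np.sqrt(6.0 / (dim + dim))
        Ws.append(rng.uniform(-limit, limit, size=(dim, dim)))
        bs.append(np.zeros(dim))
    return PlainGCN(Ws, bs, r, t)


def _norm_adjacency(g: PathwayGraph) -> np.ndarray:
    A = g.adjacency() + np.eye(g.n_nodes)
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    return A * dinv[:, None] * dinv[None, :]


def _forward(model: PlainGCN, X: np.ndarray, A: np.ndarray):
    acts = [X]
    pre = []
    H = X
    depth = len(model.weights)
    for li, (W, b) in enumerate(zip(model.weights, model.biases)):
        Z = A @ (H @ W) + b
        pre.append(Z)
        H = np.maximum(Z, 0.0) if li < depth - 1 else Z
        acts.append(H)
    return H, acts, pre


def _scores(model: PlainGCN, H: np.ndarray, I: np.ndarray, J: np.ndarray):
    diff = H[I] - H[J]
    dsq = (diff * diff).sum(axis=1)
    z = np.clip((dsq - model.r) / model.t, -30.0, 30.0)
    return 1.0 / (np.exp(z) + 1.0), dsq


def fit_plain_gcn(
    model: PlainGCN,
    g_train: PathwayGraph,
    X: np.ndarray,
    train_edges,
    val_edges,
    lr: float = 0.01,
    epochs: int = 100,
    seed: int = 0,
    eval_every: int = 10,
):
    """Adam training of the flat GCN on edge prediction; mirrors the product
    trainer's protocol (one resampled uniform negative per positive,
    validation metrics on a fixed seeded negative sample)."""
    from .edge_prediction import evaluate_model, sample_negatives

    idx = g_train.node_index()
    train_idx = np.array([[idx[u], idx[v]] for u, v in sorted(train_edges)], dtype=int)
    val_idx = np.array([[idx[u], idx[v]] for u, v in sorted(val_edges)], dtype=int)
    A = _norm_adjacency(g_train)
    exclude = frozenset(train_edges) | frozenset(val_edges)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 23]))
    val_neg_idx = None
    if len(val_idx):
        vn = sample_negatives(g_train, len(val_idx), exclude, seed=int(rng.integers(2**31)))
        val_neg_idx = np.array([[idx[u], idx[v]] for u, v in sorted(vn)], dtype=int)

    params = []
    for W, b in zip(model.weights, model.biases):
        params.append(W)
        params.append(b)
    r_arr, t_arr = np.array(model.r), np.array(model.t)
    params += [r_arr, t_arr]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    losses, val_auroc, val_ap = [], [], []
    n_pos = len(train_idx)
    depth = len(model.weights)
    for epoch in range(epochs):
        model.r, model.t = float(r_arr), float(t_arr)
        negs = sample_negatives(g_train, n_pos, exclude, seed=int(rng.integers(2**31)))
        neg_idx = np.array([[idx[u], idx[v]] for u, v in sorted(negs)], dtype=int)
        pairs = np.concatenate([train_idx, neg_idx])
        labels = np.concatenate([np.ones(n_pos), np.zeros(len(neg_idx))])
        I, J = pairs[:, 0], pairs[:, 1]
        H, acts, pre = _forward(model, X, A)
        s, dsq = _scores(model, H, I, J)
        sc = np.clip(s, 1e-7, 1 - 1e-7)
        losses.append(float(-np.mean(labels * np.log(sc) + (1 - labels) * np.log(1 - sc))))
        g_s = (sc - labels) / (sc * (1 - sc)) / len(sc)
        g_dsq = g_s * (-s * (1 - s) / model.t)
        g_r = float(np.sum(g_s * s * (1 - s) / model.t))
        g_t = float(np.sum(g_s * s * (1 - s) * (dsq - model.r) / model.t**2))
        g_H = np.zeros_like(H)
        np.add.at(g_H, I, (2.0 * g_dsq)[:, None] * (H[I] - H[J]))
        np.add.at(g_H, J, (-2.0 * g_dsq)[:, None] * (H[I] - H[J]))
        grads = [None] * len(params)
        g_out = g_H
        for li in reversed(range(depth)):
            if li < depth - 1:
                g_out = g_out * (pre[li] > 0)
            AtG = A.T @ g_out
            grads[2 * li] = acts[li].T @ AtG
            grads[2 * li + 1] = g_out.sum(axis=0)
            g_out = AtG @ model.weights[li].T
        grads[-2] = np.array(g_r)
        grads[-1] = np.array(g_t)
        step = epoch + 1
        for i, (p, gr) in enumerate(zip(params, grads)):
            m[i] = b1 * m[i] + (1 - b1) * gr
            v[i] = b2 * v[i] + (1 - b2) * gr * gr
            p -= lr * (m[i] / (1 - b1**step)) / (np.sqrt(v[i] / (1 - b2**step)) + eps)
        if ((epoch + 1) % eval_every == 0 or epoch == epochs - 1) and val_neg_idx is not None:
            model.r, model.t = float(r_arr), float(t_arr)
            Hf, _, _ = _forward(model, X, A)
            sp, _ = _scores(model, Hf, val_idx[:, 0], val_idx[:, 1])
            sn, _ = _scores(model, Hf, val_neg_idx[:, 0], val_neg_idx[:, 1])
            a, ap = evaluate_model(sp, sn)
            val_auroc.append(a)
            val_ap.append(ap)
    model.r, model.t = float(r_arr), float(t_arr)
    return model, {"loss": losses, "val_auroc": val_auroc, "val_ap": val_ap}
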