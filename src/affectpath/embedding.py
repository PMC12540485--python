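"""LINE-style graph embedding of the emotional interaction graph.

Vertices get low-dimensional vectors preserving first-order proximity
(directly linked vertices are close) and second-order proximity
(vertices with similar out-neighbourhoods are close, even when not
linked).  The second-order objective is the out-degree-weighted KL
divergence between each vertex's empirical transition distribution
w_ij / lambda_i and the model softmax p(j|i) = exp(u_i . c_j) / Z_i,
where c_j is vertex j's context vector.

Training follows the edge-sampling scheme: positive edges are drawn with
probability proportional to their weight, each paired with ``n_negative``
vertices from a noise distribution proportional to lambda^(3/4), and the
logistic approximation of the softmax is optimised by SGD with a
linearly decaying learning rate.  An exact (full-softmax) loss and its
analytic gradient are also provided for small graphs; the test suite
verifies them against finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import EmbeddingTable, EmotionGraph, GraphVertex, TrajectoryMatrix, UserTrajectory


@dataclass
class LineConfig:
    dim: int = 64
    order: str = "both"  # "first", "second" or "both" (split dim in half)
    n_samples: int = 100_000
    n_negative: int = 5
    lr: float = 0.025
    lr_min: float = 1e-4
    batch: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("first", "second", "both"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.order == "both" and self.dim % 2:
            raise ValueError("dim must be even when order='both'")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")


def _graph_arrays(graph: EmotionGraph) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge arrays (src, dst, weight) in a stable vertex/edge order."""
    order = sorted(range(graph.n_vertices),
                   key=lambda i: (graph.vertices[i].area_id, graph.vertices[i].quadrant.value))
    pos = {old: new for new, old in enumerate(order)}
    edges = sorted(
        ((pos[graph.index_of(s)], pos[graph.index_of(d)], w) for (s, d), w in graph.edges.items())
    )
    src = np.array([e[0] for e in edges], dtype=int)
    dst = np.array([e[1] for e in edges], dtype=int)
    w = np.array([e[2] for e in edges], dtype=float)
    return src, dst, w


def _vertex_order(graph: EmotionGraph) -> List[GraphVertex]:
    return sorted(graph.vertices, key=lambda v: (v.area_id, v.quadrant.value))


def _out_degree(n: int, src: np.ndarray, w: np.ndarray) -> np.ndarray:
    lam = np.zeros(n)
    np.add.at(lam, src, w)
    return lam


def second_order_loss_exact(src, dst, w, U, C) -> float:
    """-sum_e w_e log softmax_j(U_src . C_j), the exact sampled objective."""
    scores = U @ C.T
    scores -= scores.max(axis=1, keepdims=True)
    logz = np.log(np.exp(scores).sum(axis=1)) + 0.0
    logp = scores - logz[:, None]
    return float(-(w * logp[src, dst]).sum())


def second_order_grad_exact(src, dst, w, U, C) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`second_order_loss_exact` w.r.t. U and C."""
    n = U.shape[0]
    scores = U @ C.T
    scores -= scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=1, keepdims=True)  # p[i, k] = p(k|i)
    lam = _out_degree(n, src, w)
    wc = np.zeros_like(U)  # sum of w_e * C_dst per source
    np.add.at(wc, src, w[:, None] * C[dst])
    dU = -wc + lam[:, None] * (p @ C)
    dC = np.zeros_like(C)
    np.add.at(dC, dst, -w[:, None] * U[src])
    dC += (lam[:, None] * p).T @ U
    return dU, dC


def _sgd_embed(
    src: np.ndarray,
    dst: np.ndarray,
    w: np.ndarray,
    n_vertices: int,
    dim: int,
    cfg: LineConfig,
    rng: np.random.Generator,
    first_order: bool,
) -> np.ndarray:
    """Edge-sampled negative-sampling SGD for one proximity order."""
    U = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_vertices, dim))
    if first_order:
        C = U  # first order is symmetric: one table plays both roles
    else:
        C = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_vertices, dim))

    edge_cdf = np.cumsum(w)
    edge_cdf /= edge_cdf[-1]
    lam = _out_degree(n_vertices, src, w)
    noise = lam ** 0.75
    if noise.sum() == 0:
        raise ValueError("graph has no outgoing weight")
    noise_cdf = np.cumsum(noise)
    noise_cdf /= noise_cdf[-1]

    # batched scatter updates are only a faithful stand-in for sequential
    # edge sampling when index collisions are rare; cap the batch by the
    # edge count so tiny graphs fall back to (near-)sequential updates
    B = max(1, min(cfg.batch, len(w)))
    n_steps = max(1, cfg.n_samples // B)
    K = cfg.n_negative

    def sigm(s):
        return 1.0 / (1.0 + np.exp(-np.clip(s, -35.0, 35.0)))

    for step in range(n_steps):
        lr = max(cfg.lr_min, cfg.lr * (1.0 - step / n_steps))
        e = np.searchsorted(edge_cdf, rng.random(B))
        i, j = src[e], dst[e]
        neg = np.searchsorted(noise_cdf, rng.random((B, K)))

        ui = U[i]  # (B, d)
        # positive pairs: push sigma(u_i . c_j) toward 1
        s_pos = sigm(np.einsum("bd,bd->b", ui, C[j]))
        g_pos = (s_pos - 1.0)[:, None]  # dL/dscore
        # negative pairs: push sigma(u_i . c_k) toward 0
        cn = C[neg]  # (B, K, d)
        s_neg = sigm(np.einsum("bd,bkd->bk", ui, cn))

        grad_ui = g_pos * C[j] + np.einsum("bk,bkd->bd", s_neg, cn)
        grad_cj = g_pos * ui
        grad_cn = s_neg[..., None] * ui[:, None, :]

        np.add.at(U, i, -lr * grad_ui)
        np.add.at(C, j, -lr * grad_cj)
        np.add.at(C, neg.ravel(), -lr * grad_cn.reshape(-1, grad_cn.shape[-1]))
    return U


def line_embed(graph: EmotionGraph, config: LineConfig) -> EmbeddingTable:
    """Embed every vertex of the graph; deterministic under a fixed seed.

    order='both' trains the first- and second-order objectives
    independently on half the dimensions each and concatenates.  Vertices
    with zero total degree keep their initialization and are reported via
    a warning.
    """
    if graph.n_vertices < 2 or graph.n_edges < 1:
        raise ValueError("graph needs >= 2 vertices and >= 1 edge")
    src, dst, w = _graph_arrays(graph)
    n = graph.n_vertices
    rng = np.random.default_rng(config.seed)

    if config.order == "both":
        half = config.dim // 2
        u1 = _sgd_embed(src, dst, w, n, half, config, rng, first_order=True)
        u2 = _sgd_embed(src, dst, w, n, half, config, rng, first_order=False)
        U = np.concatenate([u1, u2], axis=1)
    else:
        U = _sgd_embed(src, dst, w, n, config.dim, config, rng,
                       first_order=(config.order == "first"))

    touched = np.zeros(n, dtype=bool)
    touched[src] = True
    touched[dst] = True
    verts = _vertex_order(graph)
    if not touched.all():
        isolated = [verts[k] for k in np.flatnonzero(~touched)]
        warnings.warn(f"{len(isolated)} zero-degree vertices kept their initialization: {isolated}")
    return EmbeddingTable(dim=config.dim, vectors={v: U[k] for k, v in enumerate(verts)})


# ---------------------------------------------------------------------------
# trajectory matrices


def trajectory_matrix(traj: UserTrajectory, table: EmbeddingTable) -> TrajectoryMatrix:
    """Stack the embeddings of steps 1..m-1; the m-th step is the target."""
    if len(traj) < 2:
        raise ValueError(f"trajectory of {traj.user_id} has fewer than 2 steps")
    rows = []
    for v, _ in traj.steps[:-1]:
        if v not in table:
            raise KeyError(f"vertex {v} missing from embedding table")
        rows.append(table[v])
    target = traj.steps[-1][0]
    if target not in table:
        raise KeyError(f"vertex {target} missing from embedding table")
    return TrajectoryMatrix(user_id=traj.user_id, rows=np.array(rows), target=target)


def expand_trajectory(
    traj: UserTrajectory,
    table: EmbeddingTable,
    max_history: Optional[int] = None,
) -> List[TrajectoryMatrix]:
    """All prefix matrices of a trajectory (history -> next step).

    A length-m trajectory yields m-1 samples: for each cut point the
    history is the (optionally truncated to ``max_history`` most recent)
    embedded steps before it and the target is the step at the cut.
    """
    if len(traj) < 2:
        return []
    emb = np.array([table[v] for v, _ in traj.steps])
    out = []
    for m in range(2, len(traj) + 1):
        lo = 0 if max_history is None else max(0, (m - 1) - max_history)
        out.append(TrajectoryMatrix(user_id=traj.user_id,
                                    rows=emb[lo:m - 1],
                                    target=traj.steps[m - 1][0]))
    return out
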