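"""LINE embedding: objective gradients, determinism, community structure,
and trajectory-matrix assembly."""

import numpy as np
import pytest

from affectpath.embedding import (
    LineConfig,
    expand_trajectory,
    line_embed,
    second_order_grad_exact,
    second_order_loss_exact,
    trajectory_matrix,
)
from affectpath.types import (
    EmbeddingTable,
    EmotionGraph,
    GraphVertex,
    Quadrant,
    UserTrajectory,
)


def _block_graph(seed=0, n=100, p_in=0.3, p_out=0.01):
    rng = np.random.default_rng(seed)
    g = EmotionGraph()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            p = p_in if (i < n // 2) == (j < n // 2) else p_out
            if rng.random() < p:
                g.add_edge(GraphVertex(i, Quadrant.I), GraphVertex(j, Quadrant.I), 1.0)
    return g


def cosine_block_gap(table, n=100):
    U = np.array([table[GraphVertex(i, Quadrant.I)] for i in range(n)])
    U = U / np.linalg.norm(U, axis=1, keepdims=True)
    S = U @ U.T
    same = np.zeros((n, n), bool)
    same[: n // 2, : n // 2] = True
    same[n // 2:, n // 2:] = True
    np.fill_diagonal(same, False)
    other = ~same
    np.fill_diagonal(other, False)
    return S[same].mean() - S[other].mean()


class TestSecondOrderObjective:
    def test_analytic_gradient_matches_finite_differences(self):
        src = np.array([0, 1, 2, 0])
        dst = np.array([1, 2, 0, 2])
        w = np.array([1.0, 2.0, 0.5, 1.5])
        rng = np.random.default_rng(7)
        U = rng.normal(size=(3, 4)) * 0.3
        C = rng.normal(size=(3, 4)) * 0.3
        dU, dC = second_order_grad_exact(src, dst, w, U, C)
        eps = 1e-6
        for A, dA, fix in ((U, dU, "U"), (C, dC, "C")):
            num = np.zeros_like(A)
            for i in range(A.shape[0]):
                for j in range(A.shape[1]):
                    up, dn = A.copy(), A.copy()
                    up[i, j] += eps
                    dn[i, j] -= eps
                    if fix == "U":
                        num[i, j] = (second_order_loss_exact(src, dst, w, up, C)
                                     - second_order_loss_exact(src, dst, w, dn, C)) / (2 * eps)
                    else:
                        num[i, j] = (second_order_loss_exact(src, dst, w, U, up)
                                     - second_order_loss_exact(src, dst, w, U, dn)) / (2 * eps)
            np.testing.assert_allclose(dA, num, atol=1e-5)


class TestLineEmbed:
    def test_seeded_determinism_bitwise(self, tiny_graph):
        g, a, b = tiny_graph
        cfg = LineConfig(dim=8, n_samples=2000, seed=42)
        t1 = line_embed(g, cfg)
        t2 = line_embed(g, cfg)
        assert np.array_equal(t1[a], t2[a]) and np.array_equal(t1[b], t2[b])

    def test_first_order_pulls_linked_pair_together(self):
        g = EmotionGraph()
        a, b = GraphVertex(0, Quadrant.I), GraphVertex(1, Quadrant.II)
        g.add_edge(a, b, 1.0)
        table = line_embed(g, LineConfig(dim=8, order="first", n_samples=20_000, seed=1))
        cos = float(table[a] @ table[b]
                    / (np.linalg.norm(table[a]) * np.linalg.norm(table[b])))
        assert cos > 0

    def test_block_graph_within_vs_between_cosine(self):
        g = _block_graph(seed=0)
        table = line_embed(g, LineConfig(dim=16, order="both", n_samples=100_000, seed=1))
        assert cosine_block_gap(table) >= 0.2

    def test_both_order_dim_is_sum_of_halves(self, tiny_graph):
        g, a, _ = tiny_graph
        table = line_embed(g, LineConfig(dim=10, order="both", n_samples=1000, seed=0))
        assert table.dim == 10 and table[a].shape == (10,)
        with pytest.raises(ValueError):
            LineConfig(dim=9, order="both")

    def test_norms_stay_finite(self, tiny_graph):
        g, a, b = tiny_graph
        table = line_embed(g, LineConfig(dim=8, n_samples=50_000, seed=3))
        assert np.isfinite(table[a]).all() and np.isfinite(table[b]).all()

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            line_embed(EmotionGraph(), LineConfig())


class TestTrajectoryMatrix:
    def _table(self, rng, n=4, d=6):
        vs = [GraphVertex(i, Quadrant.I) for i in range(n)]
        return EmbeddingTable(dim=d, vectors={v: rng.normal(size=d) for v in vs})

    def _traj(self, areas):
        return UserTrajectory("u", [(GraphVertex(a, Quadrant.I), 10.0 * (k + 1))
                                    for k, a in enumerate(areas)])

    def test_minimal_two_step(self, rng):
        table = self._table(rng)
        fm = trajectory_matrix(self._traj([0, 1]), table)
        assert fm.rows.shape == (1, 6)
        assert fm.target == GraphVertex(1, Quadrant.I)

    def test_rows_are_exact_lookups(self, rng):
        table = self._table(rng)
        traj = self._traj([0, 1, 2, 3, 0, 1])
        fm = trajectory_matrix(traj, table)
        assert fm.rows.shape == (5, 6)
        for k, (v, _) in enumerate(traj.steps[:-1]):
            np.testing.assert_array_equal(fm.rows[k], table[v])

    def test_unknown_vertex_errors(self, rng):
        table = self._table(rng, n=2)
        with pytest.raises(KeyError):
            trajectory_matrix(self._traj([0, 3]), table)

    def test_too_short_errors(self, rng):
        with pytest.raises(ValueError):
            trajectory_matrix(self._traj([0]), self._table(rng))

    def test_prefix_expansion_counts_and_targets(self, rng):
        table = self._table(rng)
        traj = self._traj([0, 1, 2, 3])
        samples = expand_trajectory(traj, table)
        assert len(samples) == 3
        assert [s.rows.shape[0] for s in samples] == [1, 2, 3]
        assert [s.target.area_id for s in samples] == [1, 2, 3]
        capped = expand_trajectory(traj, table, max_history=2)
        assert [s.rows.shape[0] for s in capped] == [1, 2, 2]
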