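"""Percolation sparsification and directed weighted graph metrics, checked
against independently coded brute-force oracles."""

import itertools

import numpy as np
import pytest

from eegdecide.network import (clustering_directed, cpl, global_efficiency,
                               graph_metrics, local_efficiency_directed,
                               percolation_threshold, shortest_paths,
                               summarize, weights_to_lengths)

# --------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)


def floyd_warshall(D0):
    n = D0.shape[0]
    D = D0.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def cc_bruteforce(W):
    n = W.shape[0]
    A = (W > 0).astype(float)
    out = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += ((W[i, j] ** (1 / 3) + W[j, i] ** (1 / 3))
                      * (W[i, h] ** (1 / 3) + W[h, i] ** (1 / 3))
                      * (W[j, h] ** (1 / 3) + W[h, j] ** (1 / 3)))
        t /= 2.0
        k = A[i].sum() + A[:, i].sum()
        denom = k * (k - 1) - 2 * sum(A[i, j] * A[j, i] for j in range(n))
        out[i] = t / denom if denom > 0 else 0.0
    return out


def le_bruteforce(W):
    n = W.shape[0]
    A = (W > 0).astype(float)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n)
                if j != i and (A[i, j] > 0 or A[j, i] > 0)]
        k = A[i].sum() + A[:, i].sum()
        denom = k * (k - 1) - 2 * sum(A[i, j] * A[j, i] for j in range(n))
        if len(nbrs) < 2 or denom <= 0:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            L = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1), np.inf)
        np.fill_diagonal(L, 0.0)
        D = floyd_warshall(L)
        acc = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if j == h:
                    continue
                inv = (1.0 / D[a, b] if np.isfinite(D[a, b]) and D[a, b] > 0
                       else 0.0)
                acc += (A[i, j] + A[j, i]) * (A[i, h] + A[h, i]) * inv
        out[i] = acc / denom  # the 1/2 pairs with the double (j,h)+(h,j) sum
    return out


def random_digraph(rng, n, density=0.4):
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(W, 0.0)
    return W


# --------------------------------------------------------------------------
# hand-enumerable instances


def test_three_cycle_cpl_and_ge():
    """a->b->c->a with unit lengths: CPL = 9/6 = 1.5, GE = 4.5/6 = 0.75."""
    W = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    D = shortest_paths(weights_to_lengths(W))
    assert cpl(D) == pytest.approx(1.5, abs=1e-12)
    assert global_efficiency(D) == pytest.approx(0.75, abs=1e-12)


def test_complete_unit_digraph():
    W = np.ones((4, 4)) - np.eye(4)
    D = shortest_paths(weights_to_lengths(W))
    assert cpl(D) == pytest.approx(1.0, abs=1e-12)
    assert global_efficiency(D) == pytest.approx(1.0, abs=1e-12)


def test_bidirectional_triangle_cc_is_one():
    W = np.ones((3, 3)) - np.eye(3)
    np.testing.assert_allclose(clustering_directed(W), 1.0, atol=1e-12)


def test_bidirectional_triangle_le():
    """Each neighbor subgraph is a 2-node bidirectional pair with direct
    length 1; matches the brute-force enumeration."""
    W = np.ones((3, 3)) - np.eye(3)
    le = local_efficiency_directed(W)
    np.testing.assert_allclose(le, le_bruteforce(W), atol=1e-12)
    assert (le > 0).all()


def test_isolated_and_low_degree_nodes_zero():
    W = np.zeros((4, 4))
    W[0, 1] = 1.0  # node 2, 3 isolated; 0 and 1 have a single neighbor
    assert (clustering_directed(W) == 0).all()
    assert (local_efficiency_directed(W) == 0).all()


def test_star_graph_percolation():
    """Undirected star with weights 0.9/0.8/0.7: removing any edge
    disconnects, so tau* is the weakest weight."""
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 0.9
    W[0, 2] = W[2, 0] = 0.8
    W[0, 3] = W[3, 0] = 0.7
    tau, Ws = percolation_threshold(W)
    assert tau == pytest.approx(0.7)
    np.testing.assert_array_equal(Ws, W)


def test_two_triangle_bridge_percolation():
    """Two unit triangles joined by a 0.5 bridge: tau* = 0.5 and the
    size-6 component survives with the bridge retained."""
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        W[a, b] = W[b, a] = 1.0
    W[2, 3] = W[3, 2] = 0.5
    tau, Ws = percolation_threshold(W)
    assert tau == pytest.approx(0.5)
    assert Ws[2, 3] == 0.5


def test_complete_equal_weights_unchanged():
    W = 0.4 * (np.ones((5, 5)) - np.eye(5))
    tau, Ws = percolation_threshold(W)
    assert tau == pytest.approx(0.4)
    np.testing.assert_array_equal(Ws, W)


def test_chain_distances():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 2] = 1.0
    D = shortest_paths(weights_to_lengths(W))
    assert D[0, 2] == pytest.approx(2.0)
    assert np.isinf(D[2, 0])


def test_two_hop_beats_long_direct_edge():
    W = np.zeros((3, 3))
    W[0, 2] = 0.2   # direct length 5
    W[0, 1] = W[1, 2] = 1.0
    D = shortest_paths(weights_to_lengths(W))
    assert D[0, 2] == pytest.approx(2.0)


def test_weights_to_lengths_rules():
    W = np.array([[0.0, 0.5], [0.0, 0.0]])
    D0 = weights_to_lengths(W)
    assert D0[0, 1] == pytest.approx(2.0)
    assert np.isinf(D0[1, 0])


def test_shortcut_never_increases_cpl(rng):
    W = random_digraph(rng, 8, 0.5)
    D = shortest_paths(weights_to_lengths(W))
    base = cpl(D)
    zeros = np.argwhere(W == 0)
    zeros = zeros[zeros[:, 0] != zeros[:, 1]]
    i, j = zeros[0]
    W2 = W.copy()
    W2[i, j] = 10.0  # very strong shortcut, length 0.1
    assert cpl(shortest_paths(weights_to_lengths(W2))) <= base + 1e-12


# --------------------------------------------------------------------------
# oracle equivalence and invariances


def test_metrics_match_bruteforce_oracles(rng):
    """CPL, GE, CC, LE agree with naive implementations on random
    directed weighted graphs (8 nodes)."""
    for _ in range(30):
        W = random_digraph(rng, rng.integers(4, 9))
        D = shortest_paths(weights_to_lengths(W))
        Do = floyd_warshall(weights_to_lengths(W))
        np.testing.assert_allclose(D, Do, atol=1e-12)
        off = ~np.eye(W.shape[0], dtype=bool)
        vals = Do[off]
        if np.isfinite(vals).any():
            assert cpl(D) == pytest.approx(
                vals[np.isfinite(vals)].mean(), abs=1e-12)
        inv = np.where(np.isfinite(vals), 1.0 / np.where(vals > 0, vals, 1),
                       0.0)
        assert global_efficiency(D) == pytest.approx(inv.mean(), abs=1e-12)
        np.testing.assert_allclose(clustering_directed(W), cc_bruteforce(W),
                                   atol=1e-12)
        np.testing.assert_allclose(local_efficiency_directed(W),
                                   le_bruteforce(W), atol=1e-12)


def test_binary_graph_triangle_count(rng):
    """On binary graphs the Fagiolo numerator reduces to counting directed
    triangles through each node."""
    for _ in range(20):
        A = (rng.random((6, 6)) < 0.5).astype(float)
        np.fill_diagonal(A, 0.0)
        cc = clustering_directed(A)
        for i in range(6):
            t = 0.0
            for j, h in itertools.product(range(6), repeat=2):
                t += ((A[i, j] + A[j, i]) * (A[i, h] + A[h, i])
                      * (A[j, h] + A[h, j]))
            t /= 2.0
            k = A[i].sum() + A[:, i].sum()
            denom = k * (k - 1) - 2 * (A[i] * A[:, i]).sum()
            expected = t / denom if denom > 0 else 0.0
            assert cc[i] == pytest.approx(expected, abs=1e-12)


def test_metrics_invariant_to_node_relabeling(rng):
    W = random_digraph(rng, 8, 0.5)
    perm = rng.permutation(8)
    Wp = W[np.ix_(perm, perm)]
    D, Dp = (shortest_paths(weights_to_lengths(x)) for x in (W, Wp))
    assert cpl(D) == pytest.approx(cpl(Dp), abs=1e-12)
    assert global_efficiency(D) == pytest.approx(global_efficiency(Dp),
                                                 abs=1e-12)
    np.testing.assert_allclose(clustering_directed(W)[perm],
                               clustering_directed(Wp), atol=1e-12)


def test_percolation_never_shrinks_giant_component(rng):
    """The sparsified graph keeps the giant weak component at its
    tau -> 0+ size (exhaustive threshold-scan oracle)."""
    from scipy.sparse import csr_array
    from scipy.sparse.csgraph import connected_components

    def giant(W, tau):
        keep = W >= tau
        if not keep.any():
            return 1
        _, memb = connected_components(csr_array(keep), connection="weak")
        return np.bincount(memb).max()

    for _ in range(20):
        W = random_digraph(rng, 10, 0.3)
        if not (W > 0).any():
            continue
        tau, Ws = percolation_threshold(W)
        cands = np.unique(W[W > 0])
        size0 = giant(W, cands[0])
        assert giant(W, tau) == size0
        # oracle: tau* is the largest candidate preserving size0
        tau_oracle = max(c for c in cands if giant(W, c) == size0)
        assert tau == pytest.approx(tau_oracle)
        np.testing.assert_array_equal(Ws, np.where(W >= tau, W, 0.0))


def test_empty_graph_threshold_zero():
    tau, Ws = percolation_threshold(np.zeros((4, 4)))
    assert tau == 0.0 and Ws.sum() == 0.0


def test_fully_disconnected_cpl_raises():
    D = shortest_paths(weights_to_lengths(np.zeros((3, 3))))
    with pytest.raises(ValueError):
        cpl(D)
    assert global_efficiency(D) == 0.0


def test_summarize_table_shapes(rng):
    graphs = {(s, b, band): random_digraph(rng, 5)
              for s in (1, 2) for b in (1, 2) for band in ("delta", "theta")}
    whole, nodal = summarize(graphs, labels=list("abcde"))
    assert len(whole) == 8
    assert len(nodal) == 8 * 5
    row = whole.iloc[0]
    sub = nodal[(nodal["subject"] == row["subject"])
                & (nodal["block"] == row["block"])
                & (nodal["band"] == row["band"])]
    assert row["cc_mean"] == pytest.approx(sub["cc"].mean(), abs=1e-12)


def test_graph_metrics_deterministic(rng):
    W = random_digraph(rng, 8)
    m1, m2 = graph_metrics(W), graph_metrics(W)
    assert m1.cpl == m2.cpl and m1.ge == m2.ge
    np.testing.assert_array_equal(m1.cc, m2.cc)
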