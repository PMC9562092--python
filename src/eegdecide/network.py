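"""Percolation-sparsified directed weighted graph metrics.

The adjacency W holds nonnegative directed weights (here: positive PSI
values).  Sparsification keeps the largest threshold at which the giant
weakly-connected component is still as large as with all positive edges —
the percolation threshold — so weak edges are pruned without fragmenting
the network.

Metric conventions (Brain Connectivity Toolbox style):

* Edge length d_ij = 1/w_ij; shortest paths are directed Dijkstra.
* CPL = mean shortest path over ordered pairs, finite entries only
  (directed PSI graphs are rarely strongly connected).
* GE  = mean inverse shortest path, with 1/inf = 0.
* CC  = Fagiolo directed weighted clustering with cube-root weights.
* LE  = directed local efficiency on each node's neighbor-induced
  subgraph, same denominator as CC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, dijkstra


@dataclass
class GraphMetrics:
    cpl: float
    ge: float
    cc: np.ndarray          # per node
    le: np.ndarray          # per node
    cc_mean: float
    le_mean: float
    n_finite_pairs: int
    threshold: float = 0.0


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def _giant_size(W: np.ndarray, tau: float) -> int:
    keep = W >= tau
    if not keep.any():
        return 1 if W.shape[0] else 0
    n, memb = connected_components(csr_array(keep), directed=True,
                                   connection="weak")
    return int(np.bincount(memb).max())


def percolation_threshold(W: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest threshold that preserves the giant component.

    Candidate thresholds are the sorted unique positive weights; the giant
    (weakly connected) component size is non-increasing in the threshold,
    so the largest candidate preserving the tau -> 0+ size is found by
    bisection.  Returns ``(tau_star, W_sparsified)`` with edges >= tau_star
    kept.
    """
    W = _check_weights(W)
    cands = np.unique(W[W > 0])
    if cands.size == 0:
        return 0.0, W
    size0 = _giant_size(W, cands[0])
    lo, hi = 0, cands.size - 1  # invariant: size(cands[lo]) == size0
    if _giant_size(W, cands[hi]) == size0:
        lo = hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _giant_size(W, cands[mid]) == size0:
            lo = mid
        else:
            hi = mid
    tau = float(cands[lo])
    out = np.where(W >= tau, W, 0.0)
    return tau, out


def weights_to_lengths(W: np.ndarray) -> np.ndarray:
    """Edge lengths d_ij = 1/w_ij (inf where no edge)."""
    W = _check_weights(W)
    with np.errstate(divide="ignore"):
        D0 = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(D0, 0.0)
    return D0


def shortest_paths(D0: np.ndarray) -> np.ndarray:
    """Directed all-pairs shortest path lengths (Dijkstra per source)."""
    D0 = np.asarray(D0, dtype=float)
    n = D0.shape[0]
    finite = np.isfinite(D0) & (D0 > 0)
    graph = csr_array((D0[finite], np.nonzero(finite)), shape=(n, n))
    D = dijkstra(graph, directed=True)
    np.fill_diagonal(D, 0.0)
    return D


def cpl(D: np.ndarray) -> float:
    """Characteristic path length: mean shortest path over ordered pairs
    i != j, finite entries only."""
    off = ~np.eye(D.shape[0], dtype=bool)
    vals = D[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite node pairs; graph fully disconnected")
    return float(vals[finite].mean())


def global_efficiency(D: np.ndarray) -> float:
    """Mean inverse shortest path over ordered pairs (1/inf = 0)."""
    n = D.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def _degrees_and_denominator(W: np.ndarray):
    A = (W > 0).astype(float)
    k_tot = A.sum(axis=0) + A.sum(axis=1)          # in + out degree
    recip = np.einsum("ij,ji->i", A, A)            # reciprocal edges at i
    denom = k_tot * (k_tot - 1) - 2 * recip
    return A, denom


def clustering_directed(W: np.ndarray) -> np.ndarray:
    """Fagiolo directed weighted clustering coefficient per node.

    t_i = 1/2 [ (W^{1/3} + (W^T)^{1/3})^3 ]_ii and
    CC_i = t_i / [ (k_in + k_out)(k_in + k_out - 1) - 2 sum_j a_ij a_ji ],
    zero where the denominator is not positive.
    """
    W = _check_weights(W)
    A, denom = _degrees_and_denominator(W)
    S = np.cbrt(W) + np.cbrt(W.T)
    t = np.einsum("ii->i", S @ S @ S) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0), 0.0)
    return cc


def local_efficiency_directed(W: np.ndarray) -> np.ndarray:
    """Directed local efficiency per node.

    For each node i, shortest paths are computed on the subgraph induced
    by i's neighbors (i removed; lengths 1/w), and
    LE_i = 1/2 sum_{j != h in nbrs} (a_ij + a_ji)(a_ih + a_hi)
           [ d_jh(N_i)^-1 + d_hj(N_i)^-1 ] / denom_i
    with the same denominator as the clustering coefficient.
    """
    W = _check_weights(W)
    n = W.shape[0]
    A, denom = _degrees_and_denominator(W)
    le = np.zeros(n)
    for i in range(n):
        nbrs = np.where((A[i] > 0) | (A[:, i] > 0))[0]
        nbrs = nbrs[nbrs != i]
        if nbrs.size < 2 or denom[i] <= 0:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = shortest_paths(weights_to_lengths(sub))
        with np.errstate(divide="ignore"):
            inv = 1.0 / D
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        conn = A[i, nbrs] + A[nbrs, i]             # a_ij + a_ji
        pair = np.outer(conn, conn) * (inv + inv.T)
        np.fill_diagonal(pair, 0.0)
        le[i] = pair.sum() / 2.0 / denom[i]
    return le


def graph_metrics(W: np.ndarray, *, sparsify: bool = True) -> GraphMetrics:
    """All four metrics for one adjacency; percolation-sparsified first
    unless *sparsify* is False."""
    W = _check_weights(W)
    tau = 0.0
    if sparsify:
        tau, W = percolation_threshold(W)
    D = shortest_paths(weights_to_lengths(W))
    off = ~np.eye(W.shape[0], dtype=bool)
    finite = np.isfinite(D[off])
    cc = clustering_directed(W)
    le = local_efficiency_directed(W)
    return GraphMetrics(
        cpl=cpl(D) if finite.any() else np.nan,
        ge=global_efficiency(D),
        cc=cc, le=le,
        cc_mean=float(cc.mean()), le_mean=float(le.mean()),
        n_finite_pairs=int(finite.sum()), threshold=tau)


def summarize(graphs: dict, labels: list[str] | None = None,
              sparsify: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric tables for a set of graphs keyed by (subject, block, band).

    Returns ``(whole, nodal)``: one row per graph with CPL/GE and the
    whole-brain CC/LE means, and one row per graph x node with the local
    measures.
    """
    whole_rows, nodal_rows = [], []
    for (subject, block, band), W in graphs.items():
        m = graph_metrics(W, sparsify=sparsify)
        whole_rows.append((subject, block, band, m.cpl, m.ge,
                           m.cc_mean, m.le_mean, m.threshold,
                           m.n_finite_pairs))
        node_names = labels if labels is not None else [
            str(i) for i in range(len(m.cc))]
        for i, name in enumerate(node_names):
            nodal_rows.append((subject, block, band, name,
                               m.cc[i], m.le[i]))
    whole = pd.DataFrame(whole_rows, columns=[
        "subject", "block", "band", "cpl", "ge", "cc_mean", "le_mean",
        "threshold", "n_finite_pairs"])
    nodal = pd.DataFrame(nodal_rows, columns=[
        "subject", "block", "band", "electrode", "cc", "le"])
    return whole, nodal
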