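"""Flattened tree representation and numba pruning kernels.

The MCMC and stepping-stone samplers call the pruning likelihood millions of
times, so the post-order recursion is compiled with numba over a flat array
encoding of the tree.  Everything here is internal plumbing; the public
surface lives in :mod:`cellphylo.markov`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .trees import Chronogram

__all__ = ["FlatTree", "flatten_tree", "prune_loglik_many", "node_marginals_kernel"]


class FlatTree:
    """Array encoding of a rooted tree for the kernels.

    Attributes
    ----------
    n_nodes : int
    tip_nodes : (n_tips,) node index of each pattern column
    order : (n_internal,) internal nodes in postorder
    child_idx, child_ptr : CSR children lists aligned with ``order``
    edge_length : (n_nodes,) branch length above each node (root: 0)
    root : int
    parent : (n_nodes,)
    """

    __slots__ = (
        "n_nodes", "tip_nodes", "order", "child_idx", "child_ptr",
        "edge_length", "root", "parent", "tree",
    )

    def __init__(self, tree: Chronogram, tip_order):
        self.tree = tree
        self.n_nodes = tree.n_nodes
        self.root = tree.root
        self.parent = tree.parent
        self.edge_length = np.ascontiguousarray(tree.edge_length, dtype=np.float64)
        self.tip_nodes = np.array([tree.tip_node(t) for t in tip_order], dtype=np.int64)
        internals = [v for v in tree.postorder() if not tree.is_tip(int(v))]
        self.order = np.array(internals, dtype=np.int64)
        idx, ptr = [], [0]
        for v in internals:
            kids = tree.children(int(v))
            idx.extend(kids)
            ptr.append(len(idx))
        self.child_idx = np.array(idx, dtype=np.int64)
        self.child_ptr = np.array(ptr, dtype=np.int64)


def flatten_tree(tree: Chronogram, tip_order) -> FlatTree:
    return FlatTree(tree, tip_order)


@njit(cache=True)
def prune_loglik_many(patterns, tip_nodes, order, child_idx, child_ptr,
                      P, root, root_freqs, cnode, cstate, out):
    """Felsenstein pruning log-likelihood for each pattern row.

    ``P`` is (n_nodes, k, k): transition matrix over the branch above each
    node.  ``cnode`` >= 0 restricts that internal node to state ``cstate``
    (node fixing for hypothesis tests).  Per-node rescaling guards against
    underflow.  Writes into ``out`` (n_pat,).
    """
    n_pat = patterns.shape[0]
    n_tips = tip_nodes.shape[0]
    n_nodes = P.shape[0]
    k = P.shape[1]
    partial = np.empty((n_nodes, k))
    for p in range(n_pat):
        logscale = 0.0
        for j in range(n_tips):
            v = tip_nodes[j]
            s = patterns[p, j]
            for a in range(k):
                partial[v, a] = 0.0
            partial[v, s] = 1.0
        ok = True
        for oi in range(order.shape[0]):
            v = order[oi]
            for a in range(k):
                partial[v, a] = 1.0
            for ci in range(child_ptr[oi], child_ptr[oi + 1]):
                c = child_idx[ci]
                for a in range(k):
                    acc = 0.0
                    for b in range(k):
                        acc += P[c, a, b] * partial[c, b]
                    partial[v, a] *= acc
            if v == cnode:
                for a in range(k):
                    if a != cstate:
                        partial[v, a] = 0.0
            mx = partial[v, 0]
            for a in range(1, k):
                if partial[v, a] > mx:
                    mx = partial[v, a]
            if mx <= 0.0:
                out[p] = -np.inf
                ok = False
                break
            for a in range(k):
                partial[v, a] /= mx
            logscale += np.log(mx)
        if not ok:
            continue
        tot = 0.0
        for a in range(k):
            tot += root_freqs[a] * partial[root, a]
        if tot <= 0.0:
            out[p] = -np.inf
        else:
            out[p] = np.log(tot) + logscale


@njit(cache=True)
def node_marginals_kernel(pattern, tip_nodes, order, child_idx, child_ptr,
                          P, root, root_freqs, cnode, cstate, out):
    """Marginal state distribution at every node for one pattern.

    Down pass = pruning partials (rescaled); up pass distributes the
    root-conditional outside probabilities.  ``out`` is (n_nodes, k); rows
    for tips are their (one-hot) observed states.
    """
    n_tips = tip_nodes.shape[0]
    n_nodes = P.shape[0]
    k = P.shape[1]
    down = np.zeros((n_nodes, k))
    up = np.zeros((n_nodes, k))
    for j in range(n_tips):
        v = tip_nodes[j]
        down[v, pattern[j]] = 1.0
    for oi in range(order.shape[0]):
        v = order[oi]
        for a in range(k):
            down[v, a] = 1.0
        for ci in range(child_ptr[oi], child_ptr[oi + 1]):
            c = child_idx[ci]
            for a in range(k):
                acc = 0.0
                for b in range(k):
                    acc += P[c, a, b] * down[c, b]
                down[v, a] *= acc
        if v == cnode:
            for a in range(k):
                if a != cstate:
                    down[v, a] = 0.0
        mx = 0.0
        for a in range(k):
            if down[v, a] > mx:
                mx = down[v, a]
        if mx > 0.0:
            for a in range(k):
                down[v, a] /= mx
    # up pass: iterate internal nodes root-first
    for a in range(k):
        up[root, a] = root_freqs[a]
    if cnode == root:
        for a in range(k):
            if a != cstate:
                up[root, a] = 0.0
    maxc = 1
    for oi in range(order.shape[0]):
        nc = child_ptr[oi + 1] - child_ptr[oi]
        if nc > maxc:
            maxc = nc
    lik = np.empty((maxc, k))
    for oi in range(order.shape[0] - 1, -1, -1):
        v = order[oi]
        lo = child_ptr[oi]
        hi = child_ptr[oi + 1]
        nc = hi - lo
        for i in range(nc):
            c = child_idx[lo + i]
            for a in range(k):
                acc = 0.0
                for b in range(k):
                    acc += P[c, a, b] * down[c, b]
                lik[i, a] = acc
        for i in range(nc):
            c = child_idx[lo + i]
            # w[a] = up[v,a] * prod_{j != i} lik[j,a]
            for a in range(k):
                w = up[v, a]
                for j in range(nc):
                    if j != i:
                        w *= lik[j, a]
                acc = 0.0
                # up[c, b] = sum_a w[a] P[c, a, b] ... accumulate below
                up[c, a] = w  # stash w temporarily in up[c] row? no: need matrix product
            # matrix product: U_c[b] = sum_a w_a P[c,a,b]
            tmp = np.zeros(k)
            for a in range(k):
                wa = up[c, a]
                for b in range(k):
                    tmp[b] += wa * P[c, a, b]
            mx = 0.0
            for b in range(k):
                up[c, b] = tmp[b]
                if tmp[b] > mx:
                    mx = tmp[b]
            if mx > 0.0:
                for b in range(k):
                    up[c, b] /= mx
            if c == cnode:
                for b in range(k):
                    if b != cstate:
                        up[c, b] = 0.0
    # combine
    for v in range(n_nodes):
        tot = 0.0
        for a in range(k):
            out[v, a] = up[v, a] * down[v, a]
            tot += out[v, a]
        if tot > 0.0:
            for a in range(k):
                out[v, a] /= tot
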