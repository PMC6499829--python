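"""Continuous-time Markov (Mk) models for discrete characters on trees.

A character with ``k`` states evolves along each branch as a continuous-time
Markov chain with instantaneous rate matrix ``Q``; the probability of change
is independent on each branch and depends only on the state at the branch's
start.  Three rate-constraint patterns are supported:

* ``SINGLE`` — all off-diagonal rates equal (one free rate; for binary
  characters this constrains q01 = q10),
* ``TWO_RATE`` — binary characters with q01 and q10 free,
* ``ARD`` — all k(k-1) rates different.

The likelihood is computed by Felsenstein's pruning algorithm with per-node
rescaling; a brute-force enumeration oracle over internal-node states is
provided for testing; exact marginal state distributions at internal nodes
are computed by the standard up-down pass.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._kernels import FlatTree, node_marginals_kernel, prune_loglik_many
from .trees import Chronogram, TreeError

__all__ = [
    "RateConstraint",
    "MkModelSpec",
    "build_rate_matrix",
    "transition_probabilities",
    "transition_matrices",
    "pruning_loglik",
    "brute_force_loglik",
    "node_marginal",
]


class RateConstraint(str, enum.Enum):
    SINGLE = "single"
    TWO_RATE = "two_rate"
    ARD = "ard"


@dataclass(frozen=True)
class MkModelSpec:
    """Number of states, rate-constraint pattern, and root distribution.

    ``root_freqs`` defaults to uniform 1/k (the conventional choice for
    multistate reconstructions; the symmetric models are then reversible
    with a uniform stationary distribution).  The equilibrium distribution
    of a fitted ``Q`` may be supplied instead.
    """

    k: int
    constraint: RateConstraint = RateConstraint.SINGLE
    root_freqs: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.constraint == RateConstraint.TWO_RATE and self.k != 2:
            raise ValueError("TWO_RATE is defined for binary characters only")
        if self.root_freqs is not None:
            f = np.asarray(self.root_freqs, dtype=float)
            if f.shape != (self.k,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
                raise ValueError("root_freqs must be a length-k probability vector")

    @property
    def n_free_rates(self) -> int:
        if self.constraint == RateConstraint.SINGLE:
            return 1
        if self.constraint == RateConstraint.TWO_RATE:
            return 2
        return self.k * (self.k - 1)

    @property
    def rate_names(self) -> list[str]:
        if self.constraint == RateConstraint.SINGLE:
            return ["q"]
        if self.constraint == RateConstraint.TWO_RATE:
            return ["q01", "q10"]
        return [
            f"q{i}{j}" for i in range(self.k) for j in range(self.k) if i != j
        ]

    def root_distribution(self) -> np.ndarray:
        if self.root_freqs is None:
            return np.full(self.k, 1.0 / self.k)
        return np.asarray(self.root_freqs, dtype=float)


def build_rate_matrix(spec: MkModelSpec, rates) -> np.ndarray:
    """k x k rate matrix Q from the free-rate vector.

    Off-diagonal entries are filled per the constraint pattern (ARD order:
    row-major over (i, j), i != j); the diagonal makes rows sum to zero.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if rates.shape != (spec.n_free_rates,):
        raise ValueError(
            f"expected {spec.n_free_rates} rates for {spec.constraint.value}, "
            f"got {rates.shape[0]}"
        )
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be non-negative and finite")
    k = spec.k
    Q = np.zeros((k, k))
    if spec.constraint == RateConstraint.SINGLE:
        Q[:] = rates[0]
        np.fill_diagonal(Q, 0.0)
    elif spec.constraint == RateConstraint.TWO_RATE:
        Q[0, 1] = rates[0]
        Q[1, 0] = rates[1]
    else:
        it = iter(rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = next(it)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1.

    Uses the closed form for symmetric-exchange (equal off-diagonal) and
    general binary matrices, scaling-and-squaring otherwise.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    off = Q[~np.eye(k, dtype=bool)]
    if np.allclose(off, off[0] if off.size else 0.0, rtol=0, atol=0):
        # equal-rates: P = 1/k + (I - 1/k) exp(-k q t)
        q = float(off[0]) if off.size else 0.0
        e = np.exp(-k * q * t)
        return np.full((k, k), (1 - e) / k) + np.eye(k) * e
    if k == 2:
        a, b = Q[0, 1], Q[1, 0]
        s = a + b
        e = np.exp(-s * t)
        return np.array(
            [[(b + a * e) / s, (a - a * e) / s], [(b - b * e) / s, (a + b * e) / s]]
        )
    P = scipy.linalg.expm(Q * t)
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_matrices(spec: MkModelSpec, rates, t: np.ndarray) -> np.ndarray:
    """Vectorized P(t) over an array of branch lengths -> (n, k, k).

    Closed forms for SINGLE (any k) and binary TWO_RATE; eigendecomposition
    of Q (shared across branch lengths) for general ARD, with an ``expm``
    fallback when the eigenvector basis is ill-conditioned.
    """
    t = np.asarray(t, dtype=float)
    n = t.shape[0]
    k = spec.k
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if spec.constraint == RateConstraint.SINGLE:
        q = rates[0]
        e = np.exp(-k * q * t)  # (n,)
        P = np.empty((n, k, k))
        P[:] = ((1 - e) / k)[:, None, None]
        idx = np.arange(k)
        P[:, idx, idx] += e[:, None]
        return P
    if spec.constraint == RateConstraint.TWO_RATE:
        a, b = rates
        s = a + b
        P = np.empty((n, 2, 2))
        if s == 0.0:
            P[:] = np.eye(2)
            return P
        e = np.exp(-s * t)
        P[:, 0, 0] = (b + a * e) / s
        P[:, 0, 1] = (a - a * e) / s
        P[:, 1, 0] = (b - b * e) / s
        P[:, 1, 1] = (a + b * e) / s
        return P
    Q = build_rate_matrix(spec, rates)
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            E = np.exp(np.multiply.outer(t, lam))  # (n, k)
            P = np.real(np.einsum("ab,nb,bc->nac", V, E, Vinv))
            np.clip(P, 0.0, 1.0, out=P)
            P /= P.sum(axis=2, keepdims=True)
            return P
    except np.linalg.LinAlgError:
        pass
    P = np.empty((n, k, k))
    for i in range(n):
        P[i] = transition_probabilities(Q, float(t[i]))
    return P


def _check_pattern(tree: Chronogram, pattern) -> tuple[list[str], np.ndarray]:
    """Pattern as dict {tip: state} or (taxa, states) aligned object."""
    if hasattr(pattern, "taxa") and hasattr(pattern, "states"):
        taxa, states = list(pattern.taxa), np.asarray(pattern.states)
    elif isinstance(pattern, dict):
        taxa = list(pattern)
        states = np.array([pattern[t] for t in taxa], dtype=np.int64)
    else:
        raise TypeError("pattern must be a GenePattern or {taxon: state} dict")
    if set(taxa) != tree.tip_set:
        missing = tree.tip_set - set(taxa)
        extra = set(taxa) - tree.tip_set
        raise TreeError(
            f"pattern does not match tree tips (unscored: {sorted(missing)}, "
            f"unknown: {sorted(extra)}); prune the tree to the scored taxa"
        )
    return taxa, states.astype(np.int64)


def _p_matrices(tree: Chronogram, Q: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(tree.edge_length)):
        raise TreeError("non-finite branch length")
    k = Q.shape[0]
    P = np.empty((tree.n_nodes, k, k))
    for v in range(tree.n_nodes):
        P[v] = transition_probabilities(Q, float(tree.edge_length[v]))
    return P


def pruning_loglik(tree: Chronogram, pattern, Q: np.ndarray, root_freqs=None) -> float:
    """Felsenstein pruning log-likelihood of tip states under Q.

    ``pattern`` must score every tip of ``tree`` (prune first for missing
    data).  ``root_freqs`` defaults to uniform.
    """
    taxa, states = _check_pattern(tree, pattern)
    k = Q.shape[0]
    freqs = np.full(k, 1.0 / k) if root_freqs is None else np.asarray(root_freqs, float)
    flat = FlatTree(tree, taxa)
    P = _p_matrices(tree, Q)
    out = np.empty(1)
    prune_loglik_many(
        states[None, :], flat.tip_nodes, flat.order, flat.child_idx,
        flat.child_ptr, P, flat.root, freqs, -1, -1, out,
    )
    return float(out[0])


def brute_force_loglik(tree: Chronogram, pattern, Q: np.ndarray, root_freqs=None) -> float:
    """Likelihood by explicit summation over all internal-node assignments.

    Test oracle; restricted to <= 8 internal nodes.
    """
    taxa, states = _check_pattern(tree, pattern)
    k = Q.shape[0]
    freqs = np.full(k, 1.0 / k) if root_freqs is None else np.asarray(root_freqs, float)
    internals = tree.internal_nodes()
    if len(internals) > 8:
        raise ValueError("brute force restricted to <= 8 internal nodes")
    P = _p_matrices(tree, Q)
    state_of = dict(zip((tree.tip_node(t) for t in taxa), states))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        node_state = dict(zip(internals, assign))
        node_state.update(state_of)
        term = freqs[node_state[tree.root]]
        for v in range(tree.n_nodes):
            p = int(tree.parent[v])
            if p >= 0:
                term *= P[v, node_state[p], node_state[v]]
        total += term
    return float(np.log(total))


def node_marginal(tree: Chronogram, pattern, Q: np.ndarray, root_freqs=None,
                  node: int | None = None) -> np.ndarray:
    """Marginal posterior state distribution at fixed rates.

    With ``node`` given (must be internal) returns its k-vector; otherwise
    returns the (n_nodes, k) matrix for all nodes.
    """
    taxa, states = _check_pattern(tree, pattern)
    k = Q.shape[0]
    freqs = np.full(k, 1.0 / k) if root_freqs is None else np.asarray(root_freqs, float)
    flat = FlatTree(tree, taxa)
    P = _p_matrices(tree, Q)
    out = np.zeros((tree.n_nodes, k))
    node_marginals_kernel(
        states, flat.tip_nodes, flat.order, flat.child_idx, flat.child_ptr,
        P, flat.root, freqs, -1, -1, out,
    )
    if node is None:
        return out
    if tree.is_tip(node):
        raise TreeError("node_marginal is defined for internal nodes")
    return out[node]
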