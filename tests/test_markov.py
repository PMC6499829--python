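import itertools

import numpy as np
import pytest
import scipy.linalg

from cellphylo.markov import (
    MkModelSpec,
    RateConstraint,
    build_rate_matrix,
    brute_force_loglik,
    node_marginal,
    pruning_loglik,
    transition_matrices,
    transition_probabilities,
)
from cellphylo.trees import TreeError, parse_newick

from conftest import random_tree_newick


class TestRateMatrix:
    def test_single_binary(self):
        Q = build_rate_matrix(MkModelSpec(2), [1.0])
        np.testing.assert_allclose(Q, [[-1, 1], [1, -1]])

    def test_two_rate(self):
        Q = build_rate_matrix(MkModelSpec(2, RateConstraint.TWO_RATE), [1.0, 2.0])
        np.testing.assert_allclose(Q, [[-1, 1], [2, -2]])

    def test_ard_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        spec = MkModelSpec(4, RateConstraint.ARD)
        Q = build_rate_matrix(spec, rng.uniform(0, 2, 12))
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            build_rate_matrix(MkModelSpec(2), [-0.1])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            build_rate_matrix(MkModelSpec(2), [0.1, 0.2])


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = build_rate_matrix(MkModelSpec(3), [0.7])
        np.testing.assert_allclose(transition_probabilities(Q, 0.0), np.eye(3))

    def test_binary_symmetric_closed_form(self):
        Q = build_rate_matrix(MkModelSpec(2), [0.5])
        P = transition_probabilities(Q, 1.0)
        assert P[0, 0] == pytest.approx(0.6839397, abs=1e-7)
        np.testing.assert_allclose(P, scipy.linalg.expm(Q), atol=1e-12)

    def test_stationary_limit(self):
        Q = build_rate_matrix(MkModelSpec(2), [1.0])
        np.testing.assert_allclose(
            transition_probabilities(Q, 100.0), 0.5 * np.ones((2, 2)), atol=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(build_rate_matrix(MkModelSpec(2), [1.0]), -0.1)

    @pytest.mark.parametrize(
        "spec,rates",
        [
            (MkModelSpec(2), [0.3]),
            (MkModelSpec(2, RateConstraint.TWO_RATE), [0.3, 1.1]),
            (MkModelSpec(4), [0.4]),
            (MkModelSpec(4, RateConstraint.ARD), list(np.linspace(0.1, 1.2, 12))),
        ],
    )
    def test_rows_stochastic_and_match_expm(self, spec, rates):
        Q = build_rate_matrix(spec, rates)
        ts = np.array([0.0, 0.05, 0.3, 2.0])
        P = transition_matrices(spec, rates, ts)
        np.testing.assert_allclose(P.sum(axis=2), 1.0, atol=1e-12)
        for i, t in enumerate(ts):
            np.testing.assert_allclose(P[i], scipy.linalg.expm(Q * t), atol=1e-9)

    @pytest.mark.parametrize(
        "spec,rates",
        [
            (MkModelSpec(2), [0.6]),
            (MkModelSpec(2, RateConstraint.TWO_RATE), [0.6, 0.2]),
            (MkModelSpec(4, RateConstraint.ARD), list(np.linspace(0.2, 0.9, 12))),
        ],
    )
    def test_chapman_kolmogorov(self, spec, rates):
        t1, t2 = 0.37, 0.81
        P1, P2, P12 = transition_matrices(spec, rates, np.array([t1, t2, t1 + t2]))
        np.testing.assert_allclose(P1 @ P2, P12, atol=1e-10)


class TestPruningLikelihood:
    def test_no_change_limit(self, tree5):
        Q = build_rate_matrix(MkModelSpec(2), [1e-12])
        pat = {t: 0 for t in tree5.tip_labels}
        assert pruning_loglik(tree5, pat, Q) == pytest.approx(np.log(0.5), abs=1e-6)

    def test_two_tip_definition(self):
        t = parse_newick("(A:0.4,B:0.9);")
        Q = build_rate_matrix(MkModelSpec(2), [0.7])
        pat = {"A": 0, "B": 1}
        P1 = transition_probabilities(Q, 0.4)
        P2 = transition_probabilities(Q, 0.9)
        expected = np.log(sum(0.5 * P1[r, 0] * P2[r, 1] for r in range(2)))
        assert pruning_loglik(t, pat, Q) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        tree = parse_newick(random_tree_newick(rng, n))
        if rng.random() < 0.5:
            spec, k = MkModelSpec(2), 2
        else:
            spec, k = MkModelSpec(4, RateConstraint.ARD), 4
        rates = rng.uniform(0.05, 1.5, spec.n_free_rates)
        Q = build_rate_matrix(spec, rates)
        pat = {t: int(rng.integers(k)) for t in tree.tip_labels}
        assert pruning_loglik(tree, pat, Q) == pytest.approx(
            brute_force_loglik(tree, pat, Q), abs=1e-10
        )

    def test_child_order_invariance(self):
        Q = build_rate_matrix(MkModelSpec(2), [0.4])
        t1 = parse_newick("((A:0.3,B:0.5):0.2,C:0.9);")
        t2 = parse_newick("(C:0.9,(B:0.5,A:0.3):0.2);")
        pat = {"A": 0, "B": 1, "C": 1}
        assert pruning_loglik(t1, pat, Q) == pytest.approx(
            pruning_loglik(t2, pat, Q), abs=1e-10
        )

    def test_reroot_invariance_symmetric_model(self):
        # moving the root along a branch leaves the likelihood unchanged
        # for the reversible symmetric model with uniform root frequencies
        Q = build_rate_matrix(MkModelSpec(2), [0.4])
        pat = {"A": 0, "B": 1, "C": 1}
        t1 = parse_newick("((A:0.3,B:0.5):0.2,C:0.9);")
        t2 = parse_newick("((A:0.3,B:0.5):0.6,C:0.5);")
        assert pruning_loglik(t1, pat, Q) == pytest.approx(
            pruning_loglik(t2, pat, Q), abs=1e-10
        )

    def test_unscored_tip_rejected(self, tree3):
        Q = build_rate_matrix(MkModelSpec(2), [0.4])
        with pytest.raises(TreeError, match="unscored"):
            pruning_loglik(tree3, {"A": 0, "B": 1}, Q)

    def test_no_underflow_at_tiny_rates_12_taxa(self, tree_sample_small):
        tree = tree_sample_small[0].scale_branches(0.1)
        Q = build_rate_matrix(MkModelSpec(2), [1e-8])
        pat = {t: 1 for t in tree.tip_labels}
        ll = pruning_loglik(tree, pat, Q)
        assert np.isfinite(ll)
        assert ll == pytest.approx(np.log(0.5), abs=1e-5)


class TestNodeMarginal:
    def test_no_change_limit_point_mass(self, tree5):
        Q = build_rate_matrix(MkModelSpec(2), [1e-12])
        pat = {t: 0 for t in tree5.tip_labels}
        m = node_marginal(tree5, pat, Q)
        for v in tree5.internal_nodes():
            np.testing.assert_allclose(m[v], [1.0, 0.0], atol=1e-6)

    def test_symmetric_cherry_equivocal(self):
        t = parse_newick("(A:0.5,B:0.5);")
        Q = build_rate_matrix(MkModelSpec(2), [0.3])
        m = node_marginal(t, {"A": 0, "B": 1}, Q, node=t.root)
        np.testing.assert_allclose(m, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_posterior(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tree = parse_newick(random_tree_newick(rng, 5))
        k = 2 if seed % 2 == 0 else 4
        spec = MkModelSpec(k) if k == 2 else MkModelSpec(4, RateConstraint.ARD)
        rates = rng.uniform(0.1, 1.0, spec.n_free_rates)
        Q = build_rate_matrix(spec, rates)
        pat = {t: int(rng.integers(k)) for t in tree.tip_labels}
        marg = node_marginal(tree, pat, Q)
        expected = _enumeration_marginals(tree, pat, Q)
        for v in tree.internal_nodes():
            np.testing.assert_allclose(marg[v], expected[v], atol=1e-10)
            assert marg[v].sum() == pytest.approx(1.0, abs=1e-12)

    def test_washout_limit_uniform(self):
        t = parse_newick("(A:50,B:50);")
        Q = build_rate_matrix(MkModelSpec(4), [1.0])
        m = node_marginal(t, {"A": 0, "B": 3}, Q, node=t.root)
        np.testing.assert_allclose(m, 0.25 * np.ones(4), atol=1e-6)

    def test_tip_rejected(self, tree3):
        Q = build_rate_matrix(MkModelSpec(2), [0.4])
        pat = {"A": 0, "B": 1, "C": 1}
        with pytest.raises(TreeError, match="internal"):
            node_marginal(tree3, pat, Q, node=tree3.tip_node("A"))


def _enumeration_marginals(tree, pat, Q):
    k = Q.shape[0]
    P = {v: transition_probabilities(Q, float(tree.edge_length[v]))
         for v in range(tree.n_nodes)}
    internals = tree.internal_nodes()
    state_of = {tree.tip_node(t): s for t, s in pat.items()}
    post = {v: np.zeros(k) for v in internals}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        ns = dict(zip(internals, assign))
        ns.update(state_of)
        term = 1.0 / k
        for v in range(tree.n_nodes):
            p = int(tree.parent[v])
            if p >= 0:
                term *= P[v][ns[p], ns[v]]
        total += term
        for v in internals:
            post[v][ns[v]] += term
    return {v: post[v] / total for v in internals}
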