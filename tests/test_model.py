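import numpy as np
import pytest
from scipy import stats
from scipy.integrate import trapezoid

from cellphylo.markov import MkModelSpec, build_rate_matrix, pruning_loglik
from cellphylo.model import (
    AncestralStateModel,
    McmcSettings,
    NodePosterior,
    PosteriorChain,
    RatePrior,
    run_asr_mcmc,
    summarize,
)
from cellphylo.trees import TreeError, TreeSample, parse_newick

FAST = McmcSettings(generations=40_000, thinning=20, burn_in=8_000)


class TestMcmc:
    def test_symmetric_cherry_is_equivocal(self):
        tree = parse_newick("(A:0.5,B:0.5);")
        chain = run_asr_mcmc(tree, {"A": 0, "B": 1}, settings=FAST, seed=1)
        root = summarize(chain, chain.target_labels[0])
        np.testing.assert_allclose(root.mean_pp, [0.5, 0.5], atol=0.02)

    def test_posterior_matches_quadrature_on_fixed_tree(self, tree5):
        # numerically integrate prior x likelihood over q on the scaled tree
        pat = {"A": 0, "B": 1, "C": 0, "D": 0, "E": 1}
        prior = RatePrior(0.0, 2.0)
        settings = McmcSettings(generations=120_000, thinning=20, burn_in=20_000)
        chain = run_asr_mcmc(tree5, pat, prior=prior, settings=settings, seed=2)
        scaled = tree5.scale_branches(0.1)
        qs = np.linspace(1e-9, 2.0, 4001)
        spec = MkModelSpec(2)
        ll = np.array(
            [pruning_loglik(scaled, pat, build_rate_matrix(spec, [q])) for q in qs]
        )
        w = np.exp(ll - ll.max())
        post_mean = trapezoid(qs * w, qs) / trapezoid(w, qs)
        q_samples = chain.rates[:, 0]
        from cellphylo.diagnostics import ess

        se = q_samples.std(ddof=1) / np.sqrt(ess(q_samples).ess)
        assert q_samples.mean() == pytest.approx(post_mean, abs=3 * se + 1e-3)
        # central interval agrees too
        lo, hi = np.quantile(q_samples, [0.025, 0.975])
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        qlo, qhi = np.interp([0.025, 0.975], cdf, qs)
        assert lo == pytest.approx(qlo, abs=0.1)
        assert hi == pytest.approx(qhi, abs=0.1)

    def test_repeated_tree_sample_equals_single_tree(self, tree5):
        pat = {"A": 0, "B": 1, "C": 0, "D": 0, "E": 1}
        rep = TreeSample([tree5] * 20)
        c1 = run_asr_mcmc(tree5, pat, settings=FAST, seed=3)
        c2 = run_asr_mcmc(rep, pat, settings=FAST, seed=4)
        p = stats.ks_2samp(c1.rates[:, 0], c2.rates[:, 0]).pvalue
        assert p > 0.01

    def test_bit_identical_under_seed(self, tree_sample_small, fixture):
        pat = fixture.matrix.restrict("erg")
        sub = TreeSample(tree_sample_small.trees[:20])
        small = McmcSettings(generations=10_000, thinning=20, burn_in=2_000)
        c1 = run_asr_mcmc(sub, pat, settings=small, seed=99)
        c2 = run_asr_mcmc(sub, pat, settings=small, seed=99)
        np.testing.assert_array_equal(c1.rates, c2.rates)
        np.testing.assert_array_equal(c1.tree_index, c2.tree_index)
        np.testing.assert_array_equal(c1.node_pp, c2.node_pp)

    def test_chain_shape_and_normalization(self, tree_sample_small, fixture):
        pat = fixture.matrix.restrict("vegfr")
        sub = TreeSample(tree_sample_small.trees[:10])
        small = McmcSettings(generations=10_000, thinning=25, burn_in=2_000)
        chain = run_asr_mcmc(sub, pat, settings=small, seed=0)
        assert len(chain) == (10_000 - 2_000) // 25
        np.testing.assert_allclose(chain.node_pp.sum(axis=2), 1.0, atol=1e-9)
        assert chain.seed == 0

    def test_pooled_patterns_sum_likelihood(self, tree5):
        pats = [
            {"A": 0, "B": 1, "C": 0, "D": 0, "E": 1},
            {"A": 1, "B": 1, "C": 0, "D": 1, "E": 0},
        ]
        model = AncestralStateModel(tree5, pats)
        single = [AncestralStateModel(tree5, p) for p in pats]
        rates = np.array([0.7])
        expected = sum(m._loglik(0, rates) for m in single)
        assert model._loglik(0, rates) == pytest.approx(expected, abs=1e-10)

    def test_unscored_taxon_rejected(self, tree5):
        with pytest.raises(TreeError):
            AncestralStateModel(tree5, {"A": 0, "B": 1, "Z": 0, "C": 1, "D": 0})

    def test_tip_target_rejected(self, tree5):
        pat = {"A": 0, "B": 1, "C": 0, "D": 0, "E": 1}
        with pytest.raises(TreeError, match="tip"):
            AncestralStateModel(tree5, pat, target_nodes={"bad": {"A"}})


class TestSummarize:
    def _chain(self, pp):
        pp = np.asarray(pp, dtype=float)[:, None, :]
        n = pp.shape[0]
        return PosteriorChain(
            rates=np.full((n, 1), 0.5),
            loglik=np.zeros(n),
            tree_index=np.zeros(n, dtype=np.int64),
            node_pp=pp,
            target_labels=("node",),
            state_labels=("s0", "s1"),
            rate_names=("q",),
            settings=McmcSettings(generations=100, thinning=1, burn_in=0),
            prior=RatePrior(),
            seed=0,
            acceptance_rate=0.3,
            final_window=np.array([0.5]),
        )

    def test_constant_chain_has_zero_se(self):
        chain = self._chain([[0.7, 0.3]] * 20)
        node = summarize(chain, "node")
        np.testing.assert_allclose(node.mean_pp, [0.7, 0.3])
        np.testing.assert_allclose(node.mc_se, 0.0)

    def test_two_opposite_samples_average(self):
        chain = self._chain([[1.0, 0.0], [0.0, 1.0]] * 10)
        node = summarize(chain, "node")
        np.testing.assert_allclose(node.mean_pp, [0.5, 0.5])

    def test_unknown_node_rejected(self):
        chain = self._chain([[0.7, 0.3]] * 20)
        with pytest.raises(KeyError):
            summarize(chain, "missing-node")

    def test_map_state(self):
        node = NodePosterior("n", ("a", "b"), np.array([0.2, 0.8]), np.zeros(2))
        assert node.map_state == 1


class TestResults:
    def test_summary_text_and_tables(self, tree_sample_small, fixture):
        pat = fixture.matrix.restrict("erg")
        sub = TreeSample(tree_sample_small.trees[:10])
        model = AncestralStateModel(sub, pat)
        res = model.fit(McmcSettings(generations=10_000, thinning=25, burn_in=2_000),
                        seed=8)
        text = res.summary()
        assert "Posterior transition rates" in text
        assert "U(0.0, 2.0)" in text
        df = res.node_posteriors()
        assert set(df.columns) == {"node", "state", "mean_pp", "mc_se"}
        sums = df.groupby("node")["mean_pp"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        assert res.ess_loglik().ess > 10
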