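"""Bayesian ancestral state reconstruction over a sample of chronograms.

:class:`AncestralStateModel` bundles the data (a tree sample and one gene's
tip-state pattern) with an Mk model specification and a uniform prior on
the free transition rates.  ``fit()`` runs a Metropolis–Hastings sampler:

* at every generation a tree is drawn uniformly at random from the tree
  sample, so rate estimates and node probabilities integrate over
  divergence-time uncertainty;
* one free rate is updated per generation by a uniform sliding-window
  proposal reflected at the prior bounds; the window is tuned during
  burn-in toward an acceptance rate of 0.2–0.4, then frozen;
* retained samples record the exact marginal state distribution at each
  target node under the current (tree, rates) — a Rao–Blackwellized
  estimate whose mean is identical to sampling node states but with lower
  variance.

The result object carries the thinned chain, mean posterior probabilities
(PPs) per node with Monte-Carlo standard errors, and CODA-style diagnostics
(trace, autocorrelation, effective sample size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._kernels import FlatTree, node_marginals_kernel, prune_loglik_many
from .characters import GenePattern
from .diagnostics import EssResult, autocorrelation, ess
from .markov import MkModelSpec, transition_matrices
from .trees import Chronogram, TreeError, TreeSample

__all__ = [
    "RatePrior",
    "McmcSettings",
    "DESK_SETTINGS",
    "FULL_SETTINGS",
    "PosteriorChain",
    "NodePosterior",
    "AncestralStateModel",
    "AncestralStateResults",
    "run_asr_mcmc",
    "summarize",
]


@dataclass(frozen=True)
class RatePrior:
    """Independent uniform prior on each free transition rate."""

    lower: float = 0.0
    upper: float = 2.0
    kind: str = "uniform"

    def __post_init__(self):
        if self.kind != "uniform":
            raise ValueError("only uniform rate priors are supported")
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")


@dataclass(frozen=True)
class McmcSettings:
    """Chain length, thinning, burn-in, proposal tuning, branch scaling."""

    generations: int = 10_000_000
    thinning: int = 1_000
    burn_in: int = 2_000_000
    window: float = 0.5  # initial sliding-window half-width
    adapt: bool = True
    scale_target_mean: float = 0.1

    def __post_init__(self):
        if not 0 <= self.burn_in < self.generations:
            raise ValueError("require 0 <= burn_in < generations")
        if self.thinning < 1 or self.thinning > self.generations - self.burn_in:
            raise ValueError("thinning must divide the sampling range sensibly")

    @property
    def n_samples(self) -> int:
        return (self.generations - self.burn_in) // self.thinning


#: Full-scale settings matching the published analyses.
FULL_SETTINGS = McmcSettings()
#: Reduced settings for interactive work and the test suite.
DESK_SETTINGS = McmcSettings(generations=500_000, thinning=100, burn_in=100_000)


@dataclass
class NodePosterior:
    """Mean posterior state probabilities at one named node."""

    label: str
    state_labels: tuple[str, ...]
    mean_pp: np.ndarray
    mc_se: np.ndarray

    def __post_init__(self):
        s = float(np.sum(self.mean_pp))
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"mean PPs must sum to 1, got {s}")

    @property
    def map_state(self) -> int:
        return int(np.argmax(self.mean_pp))


@dataclass
class PosteriorChain:
    """Thinned MCMC output: rates, log-likelihoods, tree draws, node marginals."""

    rates: np.ndarray            # (S, m)
    loglik: np.ndarray           # (S,)
    tree_index: np.ndarray       # (S,)
    node_pp: np.ndarray          # (S, T, k)
    target_labels: tuple[str, ...]
    state_labels: tuple[str, ...]
    rate_names: tuple[str, ...]
    settings: McmcSettings
    prior: RatePrior
    seed: int | None
    acceptance_rate: float
    final_window: np.ndarray

    def __len__(self) -> int:
        return self.rates.shape[0]

    def target_index(self, label: str) -> int:
        try:
            return self.target_labels.index(label)
        except ValueError:
            raise KeyError(f"node {label!r} not among chain targets "
                           f"{list(self.target_labels)}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=list(self.rate_names))
        df.insert(0, "lnL", self.loglik)
        df["tree_index"] = self.tree_index
        return df


def summarize(chain: PosteriorChain, node: str) -> NodePosterior:
    """Mean PPs and ESS-adjusted Monte-Carlo standard errors at one node."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    ti = chain.target_index(node)
    pp = chain.node_pp[:, ti, :]  # (S, k)
    mean = pp.mean(axis=0)
    mean = mean / mean.sum()
    se = np.empty_like(mean)
    for s in range(pp.shape[1]):
        series = pp[:, s]
        if np.ptp(series) == 0.0:
            se[s] = 0.0
        else:
            se[s] = series.std(ddof=1) / np.sqrt(max(ess(series).ess, 1.0))
    return NodePosterior(node, chain.state_labels, mean, se)


def _as_pattern(pattern, k_hint=None) -> GenePattern:
    if isinstance(pattern, GenePattern):
        return pattern
    if isinstance(pattern, dict):
        from .characters import StateSpace

        taxa = tuple(pattern)
        states = np.array([pattern[t] for t in taxa], dtype=np.int64)
        k = max(int(states.max()) + 1 if states.size else 2, 2, k_hint or 0)
        return GenePattern(
            "character", taxa, states,
            StateSpace("character", tuple(f"s{i}" for i in range(k))),
        )
    raise TypeError("pattern must be a GenePattern or {taxon: state} mapping")


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


class AncestralStateModel:
    """Mk-model ancestral state reconstruction over a chronogram sample.

    Parameters
    ----------
    trees : TreeSample or Chronogram
        Time-calibrated trees.  Each is pruned to the pattern's taxa and
        branch-scaled to ``scale_target_mean`` (mean branch length 0.1 by
        default) before analysis.
    pattern : GenePattern or {taxon: state} mapping
        Tip states for one character; every taxon must be on every tree.
    spec : MkModelSpec, optional
        Defaults to a single-rate model with the pattern's state count.
    prior : RatePrior
        Uniform prior applied independently to each free rate.
    target_nodes : mapping {label: taxon set}, optional
        Internal nodes to track.  Defaults to every internal node of the
        (pruned) first tree, labelled by its tip set.
    """

    def __init__(self, trees, pattern, spec: MkModelSpec | None = None,
                 prior: RatePrior = RatePrior(),
                 target_nodes: Mapping[str, Iterable[str]] | None = None,
                 scale_target_mean: float = 0.1):
        if isinstance(trees, Chronogram):
            trees = TreeSample([trees])
        extra_patterns = None
        if isinstance(pattern, (list, tuple)):
            # pooled characters: likelihood sums over independent patterns
            # sharing one taxon set (node marginals refer to the first)
            pattern, *extra_patterns = [
                _as_pattern(p, k_hint=spec.k if spec else None) for p in pattern
            ]
            for p in extra_patterns:
                if p.taxa != pattern.taxa or p.k != pattern.k:
                    raise ValueError("pooled patterns must share taxa and k")
        else:
            pattern = _as_pattern(pattern, k_hint=spec.k if spec else None)
        self.pattern = pattern
        self.spec = spec if spec is not None else MkModelSpec(pattern.k)
        if self.spec.k != pattern.k:
            raise ValueError(
                f"model has k={self.spec.k} but pattern has k={pattern.k}"
            )
        self.prior = prior
        self.scale_target_mean = scale_target_mean

        taxa = set(pattern.taxa)
        if not taxa <= trees.tip_set:
            raise TreeError(
                f"pattern taxa missing from trees: {sorted(taxa - trees.tip_set)}"
            )
        prepped = []
        for t in trees:
            if t.tip_set != taxa:
                t = t.prune_to_taxa(taxa)
            prepped.append(t.scale_branches(scale_target_mean))
        self.trees = TreeSample(prepped, provenance=trees.provenance)

        first = self.trees[0]
        if target_nodes is None:
            target_nodes = {}
            for v in first.internal_nodes():
                tips = sorted(first.clade_tips(v))
                target_nodes["+".join(tips)] = tips
        self.target_labels = tuple(target_nodes)
        self.target_taxa = {lab: frozenset(ts) for lab, ts in target_nodes.items()}
        # resolve targets on every tree (errors at startup, not mid-chain)
        self._flat: list[FlatTree] = []
        self._targets: np.ndarray = np.empty((len(self.trees), len(self.target_labels)),
                                             dtype=np.int64)
        tip_order = list(pattern.taxa)
        for i, t in enumerate(self.trees):
            self._flat.append(FlatTree(t, tip_order))
            for j, lab in enumerate(self.target_labels):
                node = t.mrca(self.target_taxa[lab])
                if t.is_tip(node):
                    raise TreeError(f"target node {lab!r} resolves to a tip")
                self._targets[i, j] = node
        if extra_patterns:
            self._states = np.ascontiguousarray(
                np.vstack([pattern.states] + [p.states for p in extra_patterns])
            )
        else:
            self._states = np.ascontiguousarray(pattern.states[None, :])
        self._loglik_buf = np.empty(self._states.shape[0])
        self._root_freqs = self.spec.root_distribution()

    # -- likelihood ------------------------------------------------------

    def _loglik(self, tree_i: int, rates: np.ndarray, out=None) -> float:
        flat = self._flat[tree_i]
        P = transition_matrices(self.spec, rates, flat.edge_length)
        buf = out if out is not None else self._loglik_buf
        prune_loglik_many(
            self._states, flat.tip_nodes, flat.order, flat.child_idx,
            flat.child_ptr, P, flat.root, self._root_freqs, -1, -1, buf,
        )
        return float(buf[0]) if buf.shape[0] == 1 else float(buf.sum())

    # -- fitting ---------------------------------------------------------

    def fit(self, settings: McmcSettings = DESK_SETTINGS,
            seed: int | None = None) -> "AncestralStateResults":
        chain = self._run_chain(settings, seed)
        return AncestralStateResults(self, chain)

    def _run_chain(self, settings: McmcSettings, seed) -> PosteriorChain:
        rng = np.random.default_rng(seed)
        m = self.spec.n_free_rates
        lo, hi = self.prior.lower, self.prior.upper
        n_trees = len(self.trees)
        T = len(self.target_labels)
        k = self.spec.k
        S = settings.n_samples

        rates = rng.uniform(lo, hi, m)
        window = np.full(m, min(settings.window, hi - lo))
        tree_i = int(rng.integers(n_trees))
        ll = self._loglik(tree_i, rates)

        out_rates = np.empty((S, m))
        out_ll = np.empty(S)
        out_tree = np.empty(S, dtype=np.int64)
        out_pp = np.empty((S, T, k))
        marg = np.zeros((self._flat[0].n_nodes, k))

        accept_post = 0
        n_post = 0
        acc_win = 0
        prop_win = 0
        s_idx = 0
        BLOCK = 8192
        gen = 0
        while gen < settings.generations:
            nb = min(BLOCK, settings.generations - gen)
            tree_draws = rng.integers(0, n_trees, nb)
            rate_picks = rng.integers(0, m, nb) if m > 1 else np.zeros(nb, dtype=np.int64)
            steps = rng.uniform(-1.0, 1.0, nb)
            us = rng.random(nb)
            for b in range(nb):
                gen += 1
                tree_i = int(tree_draws[b])
                ll = self._loglik(tree_i, rates)
                j = int(rate_picks[b])
                old = rates[j]
                rates[j] = _reflect(old + steps[b] * window[j], lo, hi)
                ll2 = self._loglik(tree_i, rates)
                if ll2 >= ll or us[b] < np.exp(ll2 - ll):
                    ll = ll2
                    acc_win += 1
                    if gen > settings.burn_in:
                        accept_post += 1
                else:
                    rates[j] = old
                prop_win += 1
                if gen > settings.burn_in:
                    n_post += 1
                # window adaptation during burn-in
                if settings.adapt and gen <= settings.burn_in and prop_win >= 200:
                    r = acc_win / prop_win
                    if r > 0.4:
                        window *= 1.3
                    elif r < 0.2:
                        window /= 1.3
                    np.clip(window, 1e-6 * (hi - lo), hi - lo, out=window)
                    acc_win = 0
                    prop_win = 0
                if gen > settings.burn_in and (gen - settings.burn_in) % settings.thinning == 0:
                    if s_idx < S:
                        flat = self._flat[tree_i]
                        P = transition_matrices(self.spec, rates, flat.edge_length)
                        node_marginals_kernel(
                            self._states[0], flat.tip_nodes, flat.order,
                            flat.child_idx, flat.child_ptr, P, flat.root,
                            self._root_freqs, -1, -1, marg,
                        )
                        out_rates[s_idx] = rates
                        out_ll[s_idx] = ll
                        out_tree[s_idx] = tree_i
                        for ti in range(T):
                            out_pp[s_idx, ti] = marg[self._targets[tree_i, ti]]
                        s_idx += 1
        return PosteriorChain(
            rates=out_rates[:s_idx],
            loglik=out_ll[:s_idx],
            tree_index=out_tree[:s_idx],
            node_pp=out_pp[:s_idx],
            target_labels=self.target_labels,
            state_labels=self.pattern.space.labels,
            rate_names=tuple(self.spec.rate_names),
            settings=settings,
            prior=self.prior,
            seed=seed,
            acceptance_rate=accept_post / max(n_post, 1),
            final_window=window.copy(),
        )


class AncestralStateResults:
    """Posterior summaries, diagnostics and reporting for a fitted model."""

    def __init__(self, model: AncestralStateModel, chain: PosteriorChain):
        self.model = model
        self.chain = chain

    # -- posterior summaries ----------------------------------------------

    @property
    def rate_posterior_mean(self) -> np.ndarray:
        return self.chain.rates.mean(axis=0)

    def rate_interval(self, level: float = 0.95) -> np.ndarray:
        """Central credible interval per free rate -> (m, 2)."""
        a = (1 - level) / 2
        return np.quantile(self.chain.rates, [a, 1 - a], axis=0).T

    def node_posterior(self, label: str) -> NodePosterior:
        return summarize(self.chain, label)

    def node_posteriors(self) -> pd.DataFrame:
        """Long-format table: node, state, mean PP, MC standard error."""
        rows = []
        for lab in self.chain.target_labels:
            np_ = summarize(self.chain, lab)
            for s, slab in enumerate(np_.state_labels):
                rows.append((lab, slab, np_.mean_pp[s], np_.mc_se[s]))
        return pd.DataFrame(rows, columns=["node", "state", "mean_pp", "mc_se"])

    # -- diagnostics ------------------------------------------------------

    def ess_loglik(self) -> EssResult:
        return ess(self.chain.loglik)

    def ess_rates(self) -> list[EssResult]:
        return [ess(self.chain.rates[:, j]) for j in range(self.chain.rates.shape[1])]

    def rate_autocorrelation(self, max_lag: int = 50) -> np.ndarray:
        max_lag = min(max_lag, len(self.chain) // 2 - 1)
        return autocorrelation(self.chain.rates[:, 0], max_lag)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        c = self.chain
        lines = [
            "Ancestral state reconstruction (Mk model, MCMC over tree sample)",
            "=" * 66,
            f"states: {c.state_labels}   constraint: {self.model.spec.constraint.value}",
            f"prior: U({c.prior.lower}, {c.prior.upper}) per free rate",
            f"generations: {c.settings.generations:,}  burn-in: {c.settings.burn_in:,}"
            f"  thinning: {c.settings.thinning:,}  samples: {len(c)}",
            f"trees: {len(self.model.trees)} ({self.model.trees.provenance}),"
            f" branch lengths scaled to mean {self.model.scale_target_mean}",
            f"seed: {c.seed}  acceptance: {c.acceptance_rate:.3f}",
            "",
            "Posterior transition rates:",
        ]
        ci = self.rate_interval()
        for j, name in enumerate(c.rate_names):
            e = ess(c.rates[:, j])
            lines.append(
                f"  {name}: mean {c.rates[:, j].mean():.4f}"
                f"  95% CI [{ci[j, 0]:.4f}, {ci[j, 1]:.4f}]  ESS {e.ess:.0f}"
            )
        lines += ["", "Mean posterior probabilities at target nodes:"]
        for lab in c.target_labels:
            npn = summarize(c, lab)
            states = "  ".join(
                f"{sl}={p:.3f}(±{se:.3f})"
                for sl, p, se in zip(npn.state_labels, npn.mean_pp, npn.mc_se)
            )
            lines.append(f"  {lab}: {states}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<AncestralStateResults {len(self.chain)} samples>"

    # -- plotting (optional; requires matplotlib) -------------------------

    def plot_trace(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, name in enumerate(self.chain.rate_names):
            ax.plot(self.chain.rates[:, j], lw=0.5, label=name)
        ax.set_xlabel("retained sample")
        ax.set_ylabel("rate")
        ax.legend()
        return ax

    def plot_node_posteriors(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        df = self.node_posteriors().pivot(index="node", columns="state",
                                          values="mean_pp")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1))
        df.plot.barh(stacked=True, ax=ax)
        ax.set_xlabel("mean posterior probability")
        return ax


def run_asr_mcmc(trees, pattern, spec: MkModelSpec | None = None,
                 prior: RatePrior = RatePrior(),
                 settings: McmcSettings = DESK_SETTINGS,
                 target_nodes: Mapping[str, Iterable[str]] | None = None,
                 seed: int | None = None) -> PosteriorChain:
    """Functional wrapper: build the model, run the chain, return it."""
    model = AncestralStateModel(
        trees, pattern, spec=spec, prior=prior, target_nodes=target_nodes,
        scale_target_mean=settings.scale_target_mean,
    )
    return model._run_chain(settings, seed)
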