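"""Stepping-stone marginal likelihoods, Bayes factors, node-fixed tests.

The marginal likelihood of an Mk model (optionally with an internal node
fixed to one state — "fossilizing", used for hypothesis tests at named
ancestors) is estimated by stepping-stone sampling: MCMC runs along a path
of power posteriors ``prior x likelihood^beta`` with powers spaced as
quantiles of a Beta(0.4, 1) distribution between 0 (the prior) and 1 (the
posterior); the marginal likelihood is the product of the per-stone ratio
estimates.  Hypotheses and models are compared with ``2 ln BF =
2 (lnML0 - lnML1)``, read against the Kass–Raftery scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from ._kernels import prune_loglik_many
from .diagnostics import ess
from .markov import MkModelSpec, transition_matrices
from .model import AncestralStateModel, McmcSettings, RatePrior, _reflect
from .trees import TreeError

__all__ = [
    "SteppingStoneSettings",
    "DESK_SS_SETTINGS",
    "FULL_SS_SETTINGS",
    "SteppingStoneResult",
    "BayesFactorResult",
    "stepping_stone_logml",
    "bayes_factor",
    "compare_rate_models",
]


@dataclass(frozen=True)
class SteppingStoneSettings:
    """Number of stones, iterations per stone, and power spacing.

    Powers are ``(j/stones)**(1/shape)`` for ``j = 0..stones`` (Beta(shape, 1)
    quantiles), concentrating stones near the prior where the integrand
    changes fastest.  The first ``burn_fraction`` of each stone's
    iterations is discarded.
    """

    stones: int = 1_000
    iterations: int = 100_000
    shape: float = 0.4
    burn_fraction: float = 0.2
    window: float = 0.5

    def __post_init__(self):
        if self.stones < 2:
            raise ValueError("need at least 2 stones")
        if not 0 <= self.burn_fraction < 1:
            raise ValueError("burn_fraction in [0, 1)")

    def powers(self) -> np.ndarray:
        j = np.arange(self.stones + 1)
        return (j / self.stones) ** (1.0 / self.shape)


#: Full-scale settings matching the published hypothesis tests.
FULL_SS_SETTINGS = SteppingStoneSettings()
#: Reduced settings for interactive work and the test suite.
DESK_SS_SETTINGS = SteppingStoneSettings(stones=100, iterations=10_000)


@dataclass
class SteppingStoneResult:
    logml: float
    mc_se: float
    stones: pd.DataFrame  # per-stone: beta, log_ratio, variance

    def __float__(self) -> float:
        return self.logml


_KASS_RAFTERY = ((2.0, "negligible"), (6.0, "positive"), (10.0, "strong"))


@dataclass(frozen=True)
class BayesFactorResult:
    """2 ln BF = 2 (lnML0 - lnML1) with its Kass–Raftery category."""

    lnml0: float
    lnml1: float
    statistic: float
    category: str

    @property
    def favored(self) -> int:
        """0 or 1: the hypothesis with the larger marginal likelihood."""
        return 0 if self.statistic >= 0 else 1


def bayes_factor(lnml0: float, lnml1: float) -> BayesFactorResult:
    if not (math.isfinite(lnml0) and math.isfinite(lnml1)):
        raise ValueError("marginal likelihoods must be finite")
    stat = 2.0 * (lnml0 - lnml1)
    mag = abs(stat)
    category = "very strong"
    for bound, name in _KASS_RAFTERY:
        if mag < bound:
            category = name
            break
    return BayesFactorResult(lnml0, lnml1, stat, category)


def _resolve_constraint(model: AncestralStateModel, node_constraint):
    """(taxa, state) -> per-tree constrained node ids + state."""
    if node_constraint is None:
        return None, -1
    taxa, state = node_constraint
    state = int(state)
    if not 0 <= state < model.spec.k:
        raise ValueError(f"constrained state {state} out of range [0, {model.spec.k})")
    taxa = frozenset(taxa)
    nodes = np.empty(len(model.trees), dtype=np.int64)
    for i, t in enumerate(model.trees):
        v = t.mrca(taxa)
        if t.is_tip(v):
            raise TreeError("constrained node resolves to a tip")
        nodes[i] = v
    return nodes, state


def stepping_stone_logml(trees, pattern, spec: MkModelSpec | None = None,
                         prior: RatePrior = RatePrior(),
                         ss: SteppingStoneSettings = DESK_SS_SETTINGS,
                         node_constraint=None,
                         seed: int | None = None,
                         scale_target_mean: float = 0.1) -> SteppingStoneResult:
    """ln marginal likelihood by stepping-stone sampling.

    ``node_constraint`` is an optional ``(taxon_set, state)`` pair fixing
    the MRCA of ``taxon_set`` to ``state`` (partial-likelihood masking).
    Within each power posterior, trees are updated by a uniform
    independence proposal accepted with the power-likelihood ratio, and
    rates by the reflected sliding-window move.
    """
    model = AncestralStateModel(trees, pattern, spec=spec, prior=prior,
                                scale_target_mean=scale_target_mean)
    cnodes, cstate = _resolve_constraint(model, node_constraint)
    rng = np.random.default_rng(seed)

    m = model.spec.n_free_rates
    lo, hi = prior.lower, prior.upper
    n_trees = len(model.trees)
    betas = ss.powers()
    n_burn = int(ss.burn_fraction * ss.iterations)
    n_keep = ss.iterations - n_burn

    out = np.empty(model._states.shape[0])

    def loglik(tree_i: int, rates: np.ndarray) -> float:
        flat = model._flat[tree_i]
        P = transition_matrices(model.spec, rates, flat.edge_length)
        cn = int(cnodes[tree_i]) if cnodes is not None else -1
        prune_loglik_many(
            model._states, flat.tip_nodes, flat.order, flat.child_idx,
            flat.child_ptr, P, flat.root, model._root_freqs, cn, cstate, out,
        )
        return float(out.sum())

    rates = rng.uniform(lo, hi, m)
    tree_i = int(rng.integers(n_trees))
    ll = loglik(tree_i, rates)
    window = np.full(m, min(ss.window, hi - lo))

    rows = []
    total = 0.0
    total_var = 0.0
    keep = np.empty(n_keep)
    for si in range(ss.stones):
        beta = betas[si]
        dbeta = betas[si + 1] - beta
        acc = 0
        prop = 0
        tree_draws = rng.integers(0, n_trees, ss.iterations)
        rate_picks = rng.integers(0, m, ss.iterations) if m > 1 else np.zeros(ss.iterations, dtype=np.int64)
        steps = rng.uniform(-1.0, 1.0, ss.iterations)
        u_tree = rng.random(ss.iterations)
        u_rate = rng.random(ss.iterations)
        for it in range(ss.iterations):
            # tree: uniform independence proposal, MH-corrected at power beta
            tj = int(tree_draws[it])
            if tj != tree_i:
                ll_new = loglik(tj, rates)
                if beta * (ll_new - ll) >= 0 or u_tree[it] < np.exp(beta * (ll_new - ll)):
                    tree_i, ll = tj, ll_new
            # rate: reflected sliding window
            j = int(rate_picks[it])
            old = rates[j]
            rates[j] = _reflect(old + steps[it] * window[j], lo, hi)
            ll_new = loglik(tree_i, rates)
            if beta * (ll_new - ll) >= 0 or u_rate[it] < np.exp(beta * (ll_new - ll)):
                ll = ll_new
                acc += 1
            else:
                rates[j] = old
            prop += 1
            if it < n_burn:
                if prop >= 200:
                    r = acc / prop
                    if r > 0.4:
                        window *= 1.3
                    elif r < 0.2:
                        window /= 1.3
                    np.clip(window, 1e-6 * (hi - lo), hi - lo, out=window)
                    acc = 0
                    prop = 0
            else:
                keep[it - n_burn] = ll
        # ln r_i = ln E_{beta_i}[ L^{dbeta} ]  (log-sum-exp)
        w = dbeta * keep
        a = w.max()
        z = np.exp(w - a)
        r_hat = z.mean()
        log_r = a + np.log(r_hat)
        if np.ptp(z) == 0.0:
            var = 0.0
        else:
            n_eff = max(ess(z).ess, 1.0)
            var = float(z.var(ddof=1) / (n_eff * r_hat**2))
        total += log_r
        total_var += var
        rows.append((beta, log_r, var))
    stones_df = pd.DataFrame(rows, columns=["beta", "log_ratio", "variance"])
    return SteppingStoneResult(logml=total, mc_se=float(np.sqrt(total_var)),
                               stones=stones_df)


def compare_rate_models(trees, pattern, specs, prior: RatePrior = RatePrior(),
                        ss: SteppingStoneSettings = DESK_SS_SETTINGS,
                        seed: int | None = None):
    """2 ln BF between two rate-constraint models on the same data.

    ``specs`` is a pair (model0, model1) sharing ``k``.  Returns
    ``(BayesFactorResult, result0, result1)``.
    """
    spec0, spec1 = specs
    if spec0.k != spec1.k:
        raise ValueError("models must share the state count k")
    rng = np.random.default_rng(seed)
    r0 = stepping_stone_logml(trees, pattern, spec0, prior, ss,
                              seed=int(rng.integers(2**31)))
    r1 = stepping_stone_logml(trees, pattern, spec1, prior, ss,
                              seed=int(rng.integers(2**31)))
    return bayes_factor(r0.logml, r1.logml), r0, r1
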