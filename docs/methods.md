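# Methods

## Model

A discrete spatial-expression character with `k` states evolves along each
branch of a rooted time tree as a continuous-time Markov chain (Mk model):
off-diagonal entries of the rate matrix `Q` are instantaneous transition
rates, rows sum to zero, and the transition kernel over a branch of length
`t` is `P(t) = exp(Qt)`. Change on a branch depends only on the state at
its start; branches are independent given node states. Three constraint
patterns are supported: single-rate (all off-diagonal rates equal — for a
binary character `q01 = q10`), two-rate (binary, both rates free), and
all-rates-different (`k(k−1)` free rates, row-major order).

The tip-pattern likelihood is computed by Felsenstein's post-order pruning
with per-node rescaling (each node's partial vector divided by its maximum,
log factors accumulated), which keeps 12-taxon likelihoods finite down to
rates of 1e−12. Root state frequencies default to uniform `1/k`, keeping
the symmetric models reversible with a uniform stationary distribution; the
equilibrium distribution of a fitted `Q` may be supplied instead. Closed
forms are used for `P(t)` where they exist (equal-rates for any `k`;
general binary), eigendecomposition shared across branch lengths for
general `Q`, and scaling-and-squaring as the fallback.

Marginal ancestral-state distributions at internal nodes combine the
pruning ("down") partials with an outside ("up") pass and are exact at
fixed rates. A brute-force enumeration over all internal-node state
assignments (≤ 8 internal nodes) serves as the standing test oracle for
both the likelihood and the marginals.

## Bayesian reconstruction over a tree sample

Because divergence times are uncertain, the analysis integrates over a
sample of chronograms rather than conditioning on one tree. Before
analysis every tree is pruned to the taxa scored for the focal gene and its
branch lengths rescaled so their mean is 0.1 (the conventional operating
scale for these reconstructions; rates are therefore in units of expected
changes per 0.1-mean-branch tree).

The sampler is Metropolis–Hastings over the free rates with an independent
uniform prior per rate, `U(0, 2)` by default:

* every generation one chronogram is redrawn uniformly from the tree
  sample (unconditionally — the tree is integrated over its sample
  distribution, not reweighted by the likelihood);
* one randomly chosen rate is updated by a uniform sliding-window proposal
  reflected at the prior bounds; the window is tuned every 200 proposals
  during burn-in toward an acceptance rate of 0.2–0.4, then frozen;
* retained (thinned, post-burn-in) samples record the exact per-node
  marginal state distribution under the current tree and rates
  (Rao–Blackwellized); their arithmetic mean is the reported mean posterior
  probability (PP), with a Monte-Carlo standard error computed from the
  series' effective sample size. Sampling node states instead would have
  the same expectation with more variance.

Full-scale settings are 10,000,000 generations, thinning 1,000, burn-in
2,000,000 (`FULL_SETTINGS`); the desk scale used throughout the test
suite and the acceptance script is 500,000 / 100 / 100,000
(`DESK_SETTINGS`), which leaves rate-ESS values in the thousands for these
data sizes.

Convergence diagnostics follow the usual trace/density/autocorrelation
workflow: autocorrelation is the biased autocovariance estimator
normalized by lag 0, and ESS uses Geyer's initial-positive-sequence
truncation. The estimator is deliberately left uncapped: a negatively
autocorrelated chain can report ESS > n. Constant series are flagged
degenerate and reported as ESS = n.

## Marginal likelihoods and hypothesis tests

Model and hypothesis comparison uses stepping-stone sampling: MCMC runs at
powers `β` spaced as quantiles of Beta(0.4, 1) between 0 (prior) and 1
(posterior), each stone warm-started from the previous, the first 20% of
each stone's iterations discarded, and the log marginal likelihood
assembled from per-stone log-mean-exponential ratio estimates. The
reported Monte-Carlo SE sums per-stone delta-method variances with
ESS-adjusted sample sizes. Full scale is 1,000 stones × 100,000
iterations; desk scale 100 × 10,000.

Inside a power posterior the tree cannot simply be redrawn uniformly (that
would leave the tree marginal untempered), so the tree move becomes a
uniform independence proposal accepted with the power-likelihood ratio.
At `β = 0` and for single-tree samples the two schemes coincide, which is
the regime the quadrature oracle checks.

Ancestral-state hypotheses fix an internal node (the MRCA of a named
clade, e.g. the asterozoan ancestor) to one state by zeroing all other
entries of that node's partial vector — "fossilizing". The marginal
likelihoods of the fixed-state models are compared with
`2 ln BF = 2(lnML0 − lnML1)`, interpreted on the Kass–Raftery scale
(0–2 negligible, 2–6 positive, 6–10 strong, >10 very strong). Fixing a
node partitions the unconstrained marginal likelihood across states, an
identity the test suite checks by quadrature.

## Chronogram sampler (and what it does not emulate)

A sequence-informed relaxed-clock analysis would normally supply the
divergence-time posterior. Here it is replaced by a calibration-constrained
sampler on the fixed 12-genus topology: in a root-to-tip pass each
calibrated node's age is drawn uniformly inside its fossil window (clipped
to its parent's age and its descendants' minima), and each uncalibrated
node's age uniformly between the oldest descendant constraint and the
parent's age. Tips are extant (age 0); trees are ultrametric by
construction, and a node whose window does not interact with its
neighbours' keeps an exactly uniform marginal. The seven calibration
windows (Ma): euechinoid–cidaroid [269, 346.7]; irregular–camarodont
[190.8, 235]; holothuroid–echinoid [464, 470];
neognathostomate–atelostomate [174, 201]; asterozoan–echinozoan (the root)
[481, 521]; asteroid–ophiuroid [477, 521]; holothuriid–neoholothuriid
[241, 260]; reference root age 500 Ma.

What this stand-in does *not* reproduce: sequence data concentrate
posterior node ages and, in particular, make young crown groups (e.g. the
camarodont radiation) much shallower than the uniform fill-in does. Since
branch lengths are rescaled to mean 0.1, only these *relative* ages
matter — but they shape how much evidence flows between adjacent nodes.
On uniform-age trees an internal node one short stem away from the root
(the asterozoan MRCA here) inherits the root's confidence at any
transition rate, so reconstructions at such nodes are systematically more
confident than they would be on a sequence-informed tree sample. Deep-node
PPs for strongly asymmetric patterns (one discordant taxon) are robust to
this; near-equivocal interior-node PPs are not, and the package reports
them as computed. Supplying an externally produced tree sample (one
Newick per line, or a NEXUS TREES block) bypasses the stand-in entirely.

## Study fixture

The built-in 12-genus system places one asteroid (*Patiria*), two
ophiuroids (*Amphipholis* and a placeholder second genus), two holothuroids
(*Holothuria*, *Apostichopus*), one cidaroid, four camarodont placeholders
and two irregular echinoids (*Scaphechinus*, *Echinocardium*) in the
standard clade structure. Gene coverage follows the published record:
12 taxa for *alx1*/*ets1*, 11 for *tbrain* (no ophiuroid *Amphipholis*
data), 7 for *vegfr*, 6 for *erg*.

States pinned by published expression descriptions are encoded directly
(the asteroid's mesodermal *alx1* and absent *vegfr*; camarodont
SM-specific *tbrain*; mesodermal *tbrain* in cidaroids and holothuroids;
endomesodermal *tbrain* in the asteroid). Taxa without a published
description carry the modal state of their clade and are listed in the
fixture's `assumed` metadata. Two non-obvious choices: *erg* is scored in
parallel with *ets1* (the asteroid differing from a shared SM+NSM state),
and since *tbrain* is a four-state character over 11 scored taxa, the
otherwise-unused fourth state is placed on one irregular echinoid — the
assignment consistent with reconstruction confidence dropping at the
echinoid ancestor while staying high at the camarodont ancestor. A
curated matrix file can override all of this
(`build_study_fixture(overrides=...)`).

## Synthetic data

Characters are simulated root-to-tip: the root state is drawn from the
root distribution (or fixed), each child from the `P(branch)` row of its
parent's state — exact endpoint sampling; no waiting-time simulation is
needed because only node states are used. True internal states are kept,
which is what makes the PP-calibration experiment possible: characters are
simulated with rates drawn from the analysis prior, reconstructed
per-character, and the fraction of correct most-probable states inside
each PP bin compared with the bin center. The generator matches the
inference model by construction, so passing calibration demonstrates
internal coherence of the sampler and marginals — not robustness to model
misspecification in real expression data.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script: 10,000
sampled chronograms per gene reconstruction (500 for the stepping-stone
hypothesis tests), 500k-generation chains, 100 × 10,000 stepping stones,
100 replicates × 200 characters for rate recovery, 1,000 characters for
PP calibration. Ultrametricity tolerance 1e−6; transition-matrix row sums
hold to 1e−12; pruning-vs-enumeration agreement to 1e−10; scaling is exact
to 1e−12. Ties in `argmax` over PPs resolve to the lowest state index.
Degenerate inputs (all-zero branch lengths, < 2 scored taxa, constrained
node resolving to a tip, infeasible calibration nesting) raise typed
errors at construction time rather than mid-chain.

## Known limitations

* The chronogram stand-in (above) — the dominant source of disagreement
  with reconstructions computed on sequence-informed tree samples.
* Uniform rate priors only; the prior-sensitivity sweep
  (`U(0,0.2) … U(0,200)`) is the supported way to probe prior influence.
* No correlated-character or hidden-rate models; no tree-topology
  inference; missing data handled by taxon pruning, not ambiguity coding.
* Stepping-stone estimates at desk scale carry Monte-Carlo SEs of ~0.01 ln
  units on the fixture-sized problems; Bayes-factor *categories* near
  thresholds should be read with that in mind.
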