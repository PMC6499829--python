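"""Per-gene analysis orchestration, sensitivity suite, hypothesis tests.

This is the reproducible entry point tying the pieces together: restrict
the character matrix to a gene's scored taxa, obtain a chronogram sample
(either supplied as a file of trees or drawn from the fossil-calibration
sampler), prune and branch-scale the trees, run the MCMC, and emit tidy
TSV reports with full provenance (seed, settings, matrix hash).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .characters import CharacterMatrix, GenePattern
from .chronogram import CalibrationTable, sample_tree_set
from .markov import MkModelSpec, RateConstraint
from .model import (
    AncestralStateModel,
    AncestralStateResults,
    DESK_SETTINGS,
    McmcSettings,
    RatePrior,
)
from .model_select import (
    DESK_SS_SETTINGS,
    SteppingStoneSettings,
    bayes_factor,
    stepping_stone_logml,
)
from .simulate import CLADES, ONE_PER_CLASS
from .trees import Chronogram, TreeSample

__all__ = [
    "AnalysisConfig",
    "SensitivityPlan",
    "GeneAnalysisReport",
    "run_gene_analysis",
    "run_sensitivity_suite",
    "run_node_hypothesis_tests",
]

#: ESS below which the report flags (but does not fail) a chain.
ESS_WARN_THRESHOLD = 100.0


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one gene's reconstruction."""

    gene: str
    matrix: CharacterMatrix
    topology: Chronogram | None = None
    calibrations: CalibrationTable | None = None
    tree_sample: TreeSample | None = None
    spec: MkModelSpec | None = None
    prior: RatePrior = field(default_factory=RatePrior)
    settings: McmcSettings = field(default_factory=lambda: DESK_SETTINGS)
    tree_sample_size: int = 10_000
    clades: Mapping[str, frozenset[str]] = field(default_factory=lambda: dict(CLADES))
    taxa: frozenset[str] | None = None  # optional taxon subset (pruned analyses)
    outdir: Path | None = None
    seed: int = 0

    def __post_init__(self):
        has_cal = self.calibrations is not None and self.topology is not None
        has_trees = self.tree_sample is not None
        if has_cal == has_trees:
            raise ValueError(
                "supply exactly one of (topology + calibrations) or tree_sample"
            )

    @classmethod
    def from_fixture(cls, fixture, gene: str, **kw) -> "AnalysisConfig":
        kw.setdefault("clades", fixture.clades)
        if "tree_sample" not in kw:
            kw.setdefault("topology", fixture.topology)
            kw.setdefault("calibrations", fixture.calibrations)
        else:
            kw.pop("topology", None)
            kw.pop("calibrations", None)
        return cls(gene=gene, matrix=fixture.matrix, **kw)


@dataclass
class SensitivityPlan:
    """Grid of priors, rate models and taxon subsets to sweep."""

    priors: tuple[RatePrior, ...] = (
        RatePrior(0.0, 0.2),
        RatePrior(0.0, 2.0),
        RatePrior(0.0, 20.0),
        RatePrior(0.0, 200.0),
    )
    constraints: tuple[RateConstraint, ...] = (RateConstraint.SINGLE,)
    taxon_subsets: Mapping[str, frozenset[str] | None] = field(
        default_factory=lambda: {"full": None, "one-per-class": ONE_PER_CLASS}
    )

    def __post_init__(self):
        if not self.priors or not self.constraints or not self.taxon_subsets:
            raise ValueError("priors, constraints and taxon subsets must be non-empty")


@dataclass
class GeneAnalysisReport:
    gene: str
    results: AncestralStateResults
    node_table: pd.DataFrame
    diagnostics: dict
    provenance: dict


def _matrix_hash(matrix: CharacterMatrix) -> str:
    buf = io.StringIO()
    matrix.to_frame().to_csv(buf, sep="\t")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


def _derive_seed(seed: int, salt: str) -> int:
    h = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _gene_inputs(config: AnalysisConfig):
    """(pattern, trees, targets) for a gene analysis."""
    pattern = config.matrix.restrict(config.gene, config.taxa)
    if config.tree_sample is not None:
        trees = config.tree_sample
    else:
        trees = sample_tree_set(
            config.topology, config.calibrations, config.tree_sample_size,
            seed=_derive_seed(config.seed, "trees"),
        )
    scored = set(pattern.taxa)
    targets: dict[str, frozenset[str]] = {}
    # name every internal node of the pruned tree by the smallest named
    # clade that maps onto it; anonymous clades get a tip-set label
    pruned0 = trees[0].prune_to_taxa(scored)
    named_first = sorted(config.clades.items(), key=lambda kv: len(kv[1]))
    for v in pruned0.internal_nodes():
        tips = pruned0.clade_tips(v)
        label = None
        for name, clade in named_first:
            sub = frozenset(clade & scored)
            if len(sub) >= 1 and pruned0.mrca(sub) == v:
                label = f"{name} MRCA"
                break
        if label is None:
            label = "+".join(sorted(tips))
        if label not in targets:
            targets[label] = tips
    return pattern, trees, targets


def resolve_node(config: AnalysisConfig, node) -> frozenset[str]:
    """A node argument: clade name, 'X MRCA' label, or explicit taxon set."""
    if isinstance(node, str):
        name = node.removesuffix(" MRCA")
        if name in config.clades:
            return frozenset(config.clades[name])
        raise KeyError(f"unknown clade label {node!r}")
    return frozenset(node)


def run_gene_analysis(config: AnalysisConfig) -> GeneAnalysisReport:
    """Full reconstruction for one gene; writes TSVs when ``outdir`` is set."""
    pattern, trees, targets = _gene_inputs(config)
    spec = config.spec if config.spec is not None else MkModelSpec(pattern.k)
    model = AncestralStateModel(
        trees, pattern, spec=spec, prior=config.prior, target_nodes=targets,
        scale_target_mean=config.settings.scale_target_mean,
    )
    res = model.fit(config.settings, seed=_derive_seed(config.seed, f"asr:{config.gene}"))
    node_table = res.node_posteriors()
    ess_ll = res.ess_loglik()
    diagnostics = {
        "ess_loglik": ess_ll.ess,
        "ess_rates": [e.ess for e in res.ess_rates()],
        "low_ess_warning": bool(ess_ll.ess < ESS_WARN_THRESHOLD),
        "acceptance_rate": res.chain.acceptance_rate,
    }
    provenance = {
        "gene": config.gene,
        "seed": config.seed,
        "matrix_sha256": _matrix_hash(config.matrix),
        "n_trees": len(trees),
        "tree_provenance": trees.provenance,
        "taxa": list(pattern.taxa),
        "prior": f"U({config.prior.lower},{config.prior.upper})",
        "constraint": spec.constraint.value,
        "generations": config.settings.generations,
        "burn_in": config.settings.burn_in,
        "thinning": config.settings.thinning,
    }
    report = GeneAnalysisReport(config.gene, res, node_table, diagnostics, provenance)
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        node_table.to_csv(out / f"{config.gene}_node_pp.tsv", sep="\t", index=False)
        res.chain.to_frame().to_csv(out / f"{config.gene}_chain.tsv", sep="\t", index=False)
        pd.Series({**provenance, **{k: str(v) for k, v in diagnostics.items()}}).to_csv(
            out / f"{config.gene}_provenance.tsv", sep="\t", header=False
        )
    return report


def run_sensitivity_suite(config: AnalysisConfig, plan: SensitivityPlan) -> pd.DataFrame:
    """Cross-tabulated node PPs per (prior, model, taxon subset).

    Returns a long table with one row per node x condition, carrying the
    most-probable state, its PP, and a flag for nodes whose most-probable
    state differs from the baseline (first) condition.
    """
    rows = []
    baseline_map: dict[str, str] = {}
    first = True
    for subset_name, subset in plan.taxon_subsets.items():
        for constraint in plan.constraints:
            for prior in plan.priors:
                cfg = replace(config, prior=prior, taxa=subset)
                pattern_k = cfg.matrix.restrict(cfg.gene, subset).k
                cfg.spec = MkModelSpec(pattern_k, constraint)
                rep = run_gene_analysis(cfg)
                for node, grp in rep.node_table.groupby("node", sort=False):
                    i = grp["mean_pp"].idxmax()
                    map_state = grp.loc[i, "state"]
                    if first:
                        baseline_map[node] = map_state
                    rows.append(
                        {
                            "gene": config.gene,
                            "taxa": subset_name,
                            "model": constraint.value,
                            "prior": f"U({prior.lower},{prior.upper})",
                            "node": node,
                            "map_state": map_state,
                            "map_pp": grp.loc[i, "mean_pp"],
                            "map_changed": baseline_map.get(node) not in (None, map_state),
                        }
                    )
                first = False
    df = pd.DataFrame(rows)
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{config.gene}_sensitivity.tsv", sep="\t", index=False)
    return df


def run_node_hypothesis_tests(config: AnalysisConfig, node, states: Iterable[int] | None = None,
                              ss: SteppingStoneSettings = DESK_SS_SETTINGS) -> pd.DataFrame:
    """Node-fixed stepping-stone tests: lnML per fixed state + pairwise 2lnBF.

    ``node`` is a clade label (e.g. ``"Asterozoa"``) or a taxon set whose
    MRCA is constrained; ``states`` defaults to all k states.
    """
    pattern, trees, _ = _gene_inputs(config)
    spec = config.spec if config.spec is not None else MkModelSpec(pattern.k)
    taxa = resolve_node(config, node)
    taxa = frozenset(taxa & set(pattern.taxa))
    if len(taxa) < 2:
        raise ValueError(f"constrained clade has <2 scored taxa for {config.gene}")
    if states is None:
        states = range(spec.k)
    results = {}
    for s in states:
        results[int(s)] = stepping_stone_logml(
            trees, pattern, spec, config.prior, ss,
            node_constraint=(taxa, int(s)),
            seed=_derive_seed(config.seed, f"ss:{config.gene}:{int(s)}"),
        )
    rows = []
    state_labels = pattern.space.labels
    items = sorted(results)
    for i, s0 in enumerate(items):
        for s1 in items[i + 1:]:
            bf = bayes_factor(results[s0].logml, results[s1].logml)
            rows.append(
                {
                    "gene": config.gene,
                    "node": node if isinstance(node, str) else "+".join(sorted(taxa)),
                    "state0": state_labels[s0],
                    "state1": state_labels[s1],
                    "lnML0": bf.lnml0,
                    "lnML1": bf.lnml1,
                    "se0": results[s0].mc_se,
                    "se1": results[s1].mc_se,
                    "two_ln_bf": bf.statistic,
                    "category": bf.category,
                    "favored": state_labels[s0] if bf.favored == 0 else state_labels[s1],
                }
            )
    df = pd.DataFrame(rows)
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{config.gene}_bf_tests.tsv", sep="\t", index=False)
    return df
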