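"""Calibration-constrained chronogram sampling and the clock-prior helper.

Stands in for a full Bayesian divergence-time posterior: given a fixed
rooted topology and a table of fossil calibrations (hard min/max node ages
in Ma), it draws ultrametric trees whose calibrated node ages fall inside
their windows — uniformly within a window when nesting permits — and fills
uncalibrated node ages uniformly between the constraints above and below.
The ancestral-state machinery rescales branch lengths to a fixed mean, so
only relative node ages matter downstream; a file of externally produced
trees can be supplied anywhere a :class:`~cellphylo.trees.TreeSample` is
accepted.

Also provides :func:`gamma_clock_prior`, the moment-matched gamma prior for
a relaxed-clock mean rate given a strict-clock point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .trees import Chronogram, TreeError, TreeSample

__all__ = [
    "Calibration",
    "CalibrationTable",
    "CalibrationError",
    "default_calibrations",
    "gamma_clock_prior",
    "sample_chronogram",
    "sample_tree_set",
]


class CalibrationError(ValueError):
    """Inconsistent or unresolvable calibrations."""


@dataclass(frozen=True)
class Calibration:
    """Hard min/max age (Ma) on the MRCA of a defining taxon pair."""

    clade: str
    taxon_a: str
    taxon_b: str
    min_age: float
    max_age: float

    def __post_init__(self):
        if not (0 < self.min_age < self.max_age):
            raise CalibrationError(
                f"{self.clade}: require 0 < min < max, got [{self.min_age}, {self.max_age}]"
            )


def default_calibrations() -> "CalibrationTable":
    """The seven echinoderm fossil calibrations (ages in Ma).

    Taxon pairs are phrased on the 12-genus study topology (see
    :func:`cellphylo.simulate.build_study_fixture`); the root (asterozoan–
    echinozoan split) carries both its own window and the 500 Ma reference
    age used for the strict-clock rate.
    """
    return CalibrationTable(
        [
            Calibration("Euechinoid-Cidaroid", "Cidaroid_A", "Camarodont_A", 269.0, 346.7),
            Calibration("Irregularia-Camarodonta", "Camarodont_A", "Scaphechinus", 190.8, 235.0),
            Calibration("Holothuroid-Echinoid", "Holothuria", "Cidaroid_A", 464.0, 470.0),
            Calibration("Neognathostomata-Atelostomata", "Scaphechinus", "Echinocardium", 174.0, 201.0),
            Calibration("Asterozoan-Echinozoan", "Patiria", "Cidaroid_A", 481.0, 521.0),
            Calibration("Asteroid-Ophiuroid", "Patiria", "Amphipholis", 477.0, 521.0),
            Calibration("Holothuriida-Neoholothuriida", "Holothuria", "Apostichopus", 241.0, 260.0),
        ],
        root_reference_age=500.0,
    )


class CalibrationTable:
    """A set of node-age calibrations plus a reference root age."""

    def __init__(self, calibrations: Iterable[Calibration], root_reference_age: float = 500.0):
        self.calibrations = list(calibrations)
        self.root_reference_age = float(root_reference_age)
        labels = [c.clade for c in self.calibrations]
        if len(set(labels)) != len(labels):
            raise CalibrationError("duplicate clade labels")

    def __iter__(self):
        return iter(self.calibrations)

    def __len__(self):
        return len(self.calibrations)

    # -- resolution against a topology ------------------------------------

    def resolve(self, topology: Chronogram) -> dict[int, Calibration]:
        """Map calibrations to node ids on ``topology``; validate uniqueness
        and static nesting consistency (a descendant's min may not exceed an
        ancestor's max)."""
        node_cal: dict[int, Calibration] = {}
        for cal in self.calibrations:
            node = topology.mrca({cal.taxon_a, cal.taxon_b})
            if node in node_cal:
                raise CalibrationError(
                    f"{cal.clade} and {node_cal[node].clade} resolve to the same node"
                )
            node_cal[node] = cal
        # static consistency: for each calibrated node, every calibrated
        # ancestor must have max >= this node's min
        for node, cal in node_cal.items():
            v = int(topology.parent[node])
            while v >= 0:
                anc = node_cal.get(v)
                if anc is not None and anc.max_age < cal.min_age:
                    raise CalibrationError(
                        f"nested calibrations clash: {cal.clade} min {cal.min_age} "
                        f"exceeds ancestor {anc.clade} max {anc.max_age}"
                    )
                v = int(topology.parent[v])
        return node_cal

    # -- IO ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [
                (c.clade, c.taxon_a, c.taxon_b, c.min_age, c.max_age)
                for c in self.calibrations
            ],
            columns=["clade", "taxonA", "taxonB", "min", "max"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, root_reference_age: float = 500.0) -> "CalibrationTable":
        df = pd.read_csv(path, sep="\t")
        cals = [
            Calibration(str(r.clade), str(r.taxonA), str(r.taxonB), float(r["min"]), float(r["max"]))
            for _, r in df.iterrows()
        ]
        return cls(cals, root_reference_age=root_reference_age)


def gamma_clock_prior(mean_rate: float, scale: float) -> tuple[float, float]:
    """Moment-matched gamma prior (alpha, beta) for a clock rate.

    ``alpha = (mean_rate/scale)**2`` and ``beta = mean_rate/scale**2``, so the
    implied gamma mean ``alpha/beta`` equals ``mean_rate``.  With the strict
    clock estimate 0.016 substitutions per unit time used for both arguments
    this gives (1, 62.5).
    """
    if mean_rate <= 0 or scale <= 0:
        raise ValueError("mean_rate and scale must be positive")
    return (mean_rate / scale) ** 2, mean_rate / scale**2


def _effective_minima(topology: Chronogram, node_cal) -> np.ndarray:
    """Per-node lower bound on age: max over own and descendant calibration minima."""
    eff = np.zeros(topology.n_nodes)
    for v in topology.postorder():
        v = int(v)
        lo = 0.0
        cal = node_cal.get(v)
        if cal is not None:
            lo = cal.min_age
        for c in topology.children(v):
            lo = max(lo, eff[c])
        eff[v] = lo
    return eff


def _sample_ages(topology: Chronogram, table: CalibrationTable, rng) -> np.ndarray:
    node_cal = table.resolve(topology)
    eff_min = _effective_minima(topology, node_cal)
    ages = np.zeros(topology.n_nodes)
    for v in topology.postorder()[::-1]:  # root first
        v = int(v)
        if topology.is_tip(v):
            ages[v] = 0.0  # all study taxa are extant
            continue
        cal = node_cal.get(v)
        if v == topology.root:
            hi = cal.max_age if cal is not None else max(
                table.root_reference_age, 1.05 * eff_min[v]
            )
        else:
            hi = ages[int(topology.parent[v])]
        lo = eff_min[v]
        if cal is not None:
            lo = max(lo, cal.min_age)
            hi = min(hi, cal.max_age)
        if hi < lo:
            raise CalibrationError(
                f"infeasible age window at node {v}: [{lo}, {hi}]"
            )
        ages[v] = rng.uniform(lo, hi)
    return ages


def sample_chronogram(topology: Chronogram, calibrations: CalibrationTable,
                      seed_or_rng) -> Chronogram:
    """Draw one calibration-consistent ultrametric chronogram.

    Node ages are assigned root-to-tip: calibrated nodes uniformly within
    their window (clipped to the parent's age and to descendant minima);
    uncalibrated nodes uniformly between the oldest descendant constraint
    and the parent's age.  Tips sit at age 0.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    ages = _sample_ages(topology, calibrations, rng)
    elen = np.zeros(topology.n_nodes)
    for v in range(topology.n_nodes):
        p = int(topology.parent[v])
        if p >= 0:
            elen[v] = ages[p] - ages[v]
    return Chronogram(topology.parent, elen, topology.labels)


def sample_tree_set(topology: Chronogram, calibrations: CalibrationTable,
                    n: int, seed) -> TreeSample:
    """``n`` independent chronogram draws (deterministic per seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    trees = [sample_chronogram(topology, calibrations, rng) for _ in range(n)]
    return TreeSample(trees, provenance="sampled")


def age_summary(sample: TreeSample, clades: dict[str, set[str]]) -> pd.DataFrame:
    """Mean and 2.5/97.5 percentile node ages (Ma) for named clades."""
    rows = []
    for label, taxa in clades.items():
        ages = np.array([t.node_ages()[t.mrca(taxa)] for t in sample])
        rows.append(
            (label, ages.mean(), np.percentile(ages, 2.5), np.percentile(ages, 97.5))
        )
    return pd.DataFrame(rows, columns=["clade", "mean_age", "q2.5", "q97.5"])
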