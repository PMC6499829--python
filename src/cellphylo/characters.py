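"""Discrete spatial-expression character matrices.

Characters record where in the early embryo a regulatory gene is expressed
(e.g. restricted to the skeletogenic mesenchyme, SM, versus broadly in
mesoderm).  Each gene has its own :class:`StateSpace` — the skeletogenic
regulators *alx1*, *erg*, *ets1* and *vegfr* are binary, while *tbrain* is a
four-state character.  Taxa without published expression data for a gene are
``MISSING`` and are handled by pruning them from the tree, not by ambiguity
coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "StateSpace",
    "CharacterMatrix",
    "GenePattern",
    "SchemaError",
    "default_state_spaces",
    "read_matrix",
    "restrict",
]

#: Token used for unscored cells in tabular files.
MISSING = "?"


class SchemaError(ValueError):
    """Unknown state label, duplicate taxon, or malformed matrix."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered state labels for one gene's character."""

    gene: str
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) < 2:
            raise SchemaError(f"{self.gene}: a character needs at least 2 states")
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError(f"{self.gene}: duplicate state labels")

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SchemaError(
                f"{self.gene}: unknown state label {label!r} "
                f"(known: {list(self.labels)})"
            ) from None


def default_state_spaces() -> dict[str, StateSpace]:
    """Per-gene state spaces for the five skeletogenic regulatory genes.

    Index 0 is, per gene, the broad/ancestral-mesoderm-like state; index 1
    the skeletogenic state.  *tbrain* is four-state.  The mapping is
    configuration — analyses only see indices.
    """
    return {
        "alx1": StateSpace("alx1", ("mesoderm", "SM-specific")),
        "ets1": StateSpace("ets1", ("mesoderm", "SM+NSM")),
        "erg": StateSpace("erg", ("mesoderm", "SM+NSM")),
        "vegfr": StateSpace("vegfr", ("absent-in-SM", "present-in-SM")),
        "tbrain": StateSpace(
            "tbrain", ("SM-specific", "mesoderm", "endomesoderm", "other")
        ),
    }


@dataclass(frozen=True)
class GenePattern:
    """A single gene's states over the taxa actually scored for it."""

    gene: str
    taxa: tuple[str, ...]
    states: np.ndarray  # int array, aligned with taxa
    space: StateSpace

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int64))
        if self.states.shape != (len(self.taxa),):
            raise SchemaError("states/taxa length mismatch")
        if np.any((self.states < 0) | (self.states >= self.space.k)):
            raise SchemaError(f"{self.gene}: state index out of range")

    @property
    def k(self) -> int:
        return self.space.k

    @property
    def taxon_set(self) -> frozenset[str]:
        return frozenset(self.taxa)

    def state_of(self, taxon: str) -> int:
        return int(self.states[self.taxa.index(taxon)])


class CharacterMatrix:
    """Taxa x genes table of state indices, with ``None`` for missing."""

    def __init__(
        self,
        taxa: Iterable[str],
        data: Mapping[str, Mapping[str, int | None]],
        spaces: Mapping[str, StateSpace],
    ):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise SchemaError("duplicate taxa in matrix")
        self.spaces = dict(spaces)
        self.data: dict[str, dict[str, int | None]] = {}
        for gene, col in data.items():
            if gene not in self.spaces:
                raise SchemaError(f"no state space for gene {gene!r}")
            k = self.spaces[gene].k
            full: dict[str, int | None] = {}
            for t in self.taxa:
                v = col.get(t)
                if v is not None and not (0 <= int(v) < k):
                    raise SchemaError(f"{gene}/{t}: state index {v} out of [0,{k})")
                full[t] = None if v is None else int(v)
            self.data[gene] = full

    @property
    def genes(self) -> list[str]:
        return list(self.data)

    def scored_taxa(self, gene: str) -> list[str]:
        col = self.data[gene]
        return [t for t in self.taxa if col[t] is not None]

    def restrict(self, gene: str, taxa: Iterable[str] | None = None) -> GenePattern:
        """Single-gene pattern over the taxa with non-missing data.

        ``taxa`` optionally intersects the scored set (e.g. for pruned
        sensitivity analyses).  Raises if fewer than 2 taxa remain.
        """
        if gene not in self.data:
            raise SchemaError(f"gene {gene!r} not in matrix")
        col = self.data[gene]
        chosen = [t for t in self.taxa if col[t] is not None]
        if taxa is not None:
            allow = set(taxa)
            chosen = [t for t in chosen if t in allow]
        if len(chosen) < 2:
            raise SchemaError(f"{gene}: fewer than 2 scored taxa")
        states = np.array([col[t] for t in chosen], dtype=np.int64)
        return GenePattern(gene, tuple(chosen), states, self.spaces[gene])

    # -- IO ---------------------------------------------------------------

    def to_frame(self, *, labels: bool = True) -> pd.DataFrame:
        """Matrix as a DataFrame (state labels, ``?`` for missing)."""
        rows = {}
        for t in self.taxa:
            row = {}
            for g in self.genes:
                v = self.data[g][t]
                if v is None:
                    row[g] = MISSING
                else:
                    row[g] = self.spaces[g].labels[v] if labels else v
            rows[t] = row
        return pd.DataFrame.from_dict(rows, orient="index")[self.genes]

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("taxon").to_csv(path, sep="\t")

    def to_nexus(self) -> str:
        """NEXUS CHARACTERS block (state indices as symbols), for interoperability."""
        genes = self.genes
        maxk = max(self.spaces[g].k for g in genes)
        symbols = "".join(str(i) for i in range(maxk))
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(genes)};",
            f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING={MISSING};',
            "    MATRIX",
        ]
        width = max(len(t) for t in self.taxa) + 2
        for t in self.taxa:
            cells = "".join(
                MISSING if self.data[g][t] is None else str(self.data[g][t])
                for g in genes
            )
            lines.append(f"    {t:<{width}}{cells}")
        lines += ["    ;", "END;", ""]
        return "\n".join(lines)


def read_matrix(source, schema: Mapping[str, StateSpace]) -> CharacterMatrix:
    """Read a tab-separated matrix (taxa rows x gene columns, state labels).

    ``source`` is a path or file-like object.  The header row names the
    genes; the first column holds taxon names; cells hold state labels from
    the per-gene schema or ``?`` for missing.
    """
    df = pd.read_csv(source, sep="\t", index_col=0, dtype=str)
    taxa = [str(t) for t in df.index]
    if len(set(taxa)) != len(taxa):
        raise SchemaError("duplicate taxon rows")
    data: dict[str, dict[str, int | None]] = {}
    for gene in df.columns:
        if gene not in schema:
            raise SchemaError(f"no state space for gene {gene!r}")
        space = schema[gene]
        col: dict[str, int | None] = {}
        for t in taxa:
            cell = df.at[t, gene]
            if pd.isna(cell) or str(cell).strip() in (MISSING, "", "-"):
                col[t] = None
            else:
                try:
                    col[t] = space.index(str(cell).strip())
                except SchemaError:
                    raise SchemaError(
                        f"{gene}/{t}: unknown state label {str(cell).strip()!r}"
                    ) from None
        data[gene] = col
    return CharacterMatrix(taxa, data, schema)


def restrict(matrix: CharacterMatrix, gene: str, taxa: Iterable[str] | None = None) -> GenePattern:
    return matrix.restrict(gene, taxa)
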