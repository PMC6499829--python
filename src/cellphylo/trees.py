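"""Rooted time-calibrated trees and tree samples.

The central container is :class:`Chronogram`, an array-backed rooted tree
with branch lengths, intended for ultrametric (time-calibrated) phylogenies
but usable for any rooted tree with lengths.  Parsing of Newick strings and
NEXUS ``TREES`` blocks is delegated to :mod:`dendropy`; writing is done
directly so that round-trips are stable up to float formatting.

Node indexing convention: nodes are integers ``0 .. n_nodes-1`` in an
arbitrary but stable order; the root is the unique node whose parent is
``-1``.  Tips carry unique non-empty labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "TreeSample",
    "TreeError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "mrca",
    "scale_branches",
    "prune_to_taxa",
]


class TreeError(ValueError):
    """Invalid tree structure or operation."""


class NewickParseError(TreeError):
    """Malformed Newick/NEXUS input."""


class Chronogram:
    """Rooted tree with branch lengths, array-backed.

    Parameters
    ----------
    parent : array of int
        ``parent[i]`` is the parent node of ``i``; the root has ``-1``.
    edge_length : array of float
        Length of the branch subtending each node (ignored for the root;
        stored as 0.0 there).  ``nan`` marks an absent length (only allowed
        when ``require_lengths=False``, e.g. for bare topologies).
    labels : sequence of str or None
        Tip labels; internal nodes may be ``None``.
    """

    def __init__(self, parent, edge_length, labels, *, require_lengths=True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float).copy()
        self.labels = list(labels)
        n = self.parent.shape[0]
        if not (len(self.labels) == n == self.edge_length.shape[0]):
            raise TreeError("parent/edge_length/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.edge_length[self.root] = 0.0
        # children adjacency
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                self._children[p].append(i)
        self._tips = [i for i in range(n) if not self._children[i]]
        for i in self._tips:
            lab = self.labels[i]
            if not lab:
                raise TreeError(f"tip node {i} has an empty label")
        tip_labels = [self.labels[i] for i in self._tips]
        if len(set(tip_labels)) != len(tip_labels):
            dup = sorted({t for t in tip_labels if tip_labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        self._tip_index = {self.labels[i]: i for i in self._tips}
        if require_lengths:
            nonroot = np.ones(n, bool)
            nonroot[self.root] = False
            if np.any(~np.isfinite(self.edge_length[nonroot])):
                raise TreeError("missing or non-finite branch lengths")
            if np.any(self.edge_length[nonroot] < 0):
                raise TreeError("negative branch lengths")
        self._postorder = self._compute_postorder()

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tips(self) -> list[int]:
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self._tips]

    @property
    def tip_set(self) -> frozenset[str]:
        return frozenset(self._tip_index)

    def children(self, node: int) -> list[int]:
        return list(self._children[node])

    def is_tip(self, node: int) -> bool:
        return not self._children[node]

    def tip_node(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown taxon {label!r}") from None

    def _compute_postorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self._children[v])
        return np.asarray(order[::-1], dtype=np.int64)

    def postorder(self) -> np.ndarray:
        """All nodes, children before parents."""
        return self._postorder

    def internal_nodes(self) -> list[int]:
        return [int(v) for v in self._postorder if self._children[v]]

    # -- ages and depths -------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Path length from the root to each node."""
        depth = np.zeros(self.n_nodes)
        for v in self._postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.edge_length[v]
        return depth

    def node_ages(self) -> np.ndarray:
        """Age of each node = tree height minus depth (tips at ~0 if ultrametric)."""
        depth = self.node_depths()
        return depth.max() - depth

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.node_depths()[self._tips]
        return bool(np.ptp(d) <= tol) if len(d) else True

    def tree_height(self) -> float:
        return float(self.node_depths().max())

    # -- queries ---------------------------------------------------------

    def mrca(self, taxa: Iterable[str]) -> int:
        """Most recent common ancestor of a set of tip labels.

        ``mrca({t})`` is the tip itself.
        """
        nodes = [self.tip_node(t) for t in taxa]
        if not nodes:
            raise TreeError("mrca of an empty taxon set")
        anc = nodes[0]
        for u in nodes[1:]:
            # ancestors of current anc
            path = set()
            v = anc
            while v >= 0:
                path.add(v)
                v = int(self.parent[v])
            v = u
            while v not in path:
                v = int(self.parent[v])
            anc = v
        return anc

    def clade_tips(self, node: int) -> frozenset[str]:
        """Tip labels descended from ``node``."""
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(self.labels[v])
            else:
                stack.extend(self._children[v])
        return frozenset(out)

    # -- transforms ------------------------------------------------------

    def scale_branches(self, target_mean: float) -> "Chronogram":
        """Multiply all branch lengths by one constant so their mean is ``target_mean``."""
        if target_mean <= 0:
            raise TreeError("target_mean must be positive")
        mask = np.ones(self.n_nodes, bool)
        mask[self.root] = False
        mean = float(self.edge_length[mask].mean())
        if mean == 0.0:
            raise TreeError("cannot scale a tree whose branch lengths are all zero")
        factor = target_mean / mean
        return Chronogram(self.parent, self.edge_length * factor, self.labels)

    def prune_to_taxa(self, keep: Iterable[str]) -> "Chronogram":
        """Induced subtree on ``keep``; unary nodes suppressed, lengths summed."""
        keep = set(keep)
        if len(keep) < 2:
            raise TreeError("prune_to_taxa requires at least 2 taxa")
        for t in keep:
            self.tip_node(t)  # raises on unknown taxon
        keep_nodes = np.zeros(self.n_nodes, dtype=np.int64)  # kept tip count below
        for v in self._postorder:
            if self.is_tip(v):
                keep_nodes[v] = int(self.labels[v] in keep)
            else:
                keep_nodes[v] = sum(keep_nodes[c] for c in self._children[v])
        new_root = self.mrca(keep)
        # retained nodes: tips in keep; internal nodes below/at new_root whose
        # >=2 children have kept descendants; plus new_root itself
        retained = []
        for v in self._postorder:
            if self.is_tip(v):
                if self.labels[v] in keep:
                    retained.append(v)
            else:
                nkids = sum(1 for c in self._children[v] if keep_nodes[c] > 0)
                if keep_nodes[v] > 0 and self._is_below_or_self(v, new_root) and (
                    nkids >= 2 or v == new_root
                ):
                    retained.append(v)
        retained_set = set(retained)
        old2new = {v: i for i, v in enumerate(retained)}
        n_new = len(retained)
        parent = np.full(n_new, -1, dtype=np.int64)
        elen = np.zeros(n_new)
        labels: list[str | None] = [self.labels[v] if self.is_tip(v) else None for v in retained]
        for v in retained:
            if v == new_root:
                continue
            # walk up accumulating length until a retained ancestor
            length = self.edge_length[v]
            p = int(self.parent[v])
            while p not in retained_set:
                length += self.edge_length[p]
                p = int(self.parent[p])
            parent[old2new[v]] = old2new[p]
            elen[old2new[v]] = length
        return Chronogram(parent, elen, labels)

    def _is_below_or_self(self, node: int, ancestor: int) -> bool:
        v = node
        while v >= 0:
            if v == ancestor:
                return True
            v = int(self.parent[v])
        return False

    # -- IO ----------------------------------------------------------------

    def to_newick(self, *, precision: int = 10) -> str:
        fmt = f"%.{precision}g"

        def rec(v: int) -> str:
            if self.is_tip(v):
                base = _quote_label(self.labels[v])
            else:
                base = "(" + ",".join(rec(c) for c in self._children[v]) + ")"
            if v == self.root:
                return base
            ln = self.edge_length[v]
            if np.isnan(ln):
                return base
            return base + ":" + (fmt % ln)

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, *, require_lengths: bool = True) -> "Chronogram":
        return parse_newick(text, require_lengths=require_lengths)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Chronogram {self.n_tips} tips, height {self.tree_height():.4g}>"


def _quote_label(label: str) -> str:
    if any(c in label for c in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(tree: dendropy.Tree, *, require_lengths: bool) -> Chronogram:
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    elen = np.full(n, np.nan)
    labels: list[str | None] = [None] * n
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is not None:
                elen[i] = float(nd.edge.length)
            elif require_lengths:
                who = nd.taxon.label if nd.taxon else "an internal node"
                raise NewickParseError(f"missing branch length on the edge above {who}")
        else:
            elen[i] = 0.0
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickParseError("tip without a label")
            labels[i] = nd.taxon.label
        elif nd.taxon is not None:
            labels[i] = nd.taxon.label
    try:
        return Chronogram(parent, elen, labels, require_lengths=require_lengths)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc


def parse_newick(text: str, *, require_lengths: bool = True) -> Chronogram:
    """Parse a single rooted Newick string into a :class:`Chronogram`.

    Raises :class:`NewickParseError` on malformed input, duplicate tips, or
    (by default) missing branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(tree, require_lengths=require_lengths)


def write_newick(tree: Chronogram, *, precision: int = 10) -> str:
    return tree.to_newick(precision=precision)


def mrca(tree: Chronogram, taxa: Iterable[str]) -> int:
    return tree.mrca(taxa)


def scale_branches(tree: Chronogram, target_mean: float) -> Chronogram:
    return tree.scale_branches(target_mean)


def prune_to_taxa(tree: Chronogram, keep: Iterable[str]) -> Chronogram:
    return tree.prune_to_taxa(keep)


@dataclass
class TreeSample:
    """An ordered collection of chronograms sharing one tip set.

    ``provenance`` is ``"sampled"`` for trees drawn by the calibration
    sampler and ``"file"`` for externally supplied samples.
    """

    trees: list[Chronogram]
    provenance: str = "sampled"

    def __post_init__(self):
        if not self.trees:
            raise TreeError("empty tree sample")
        tipset = self.trees[0].tip_set
        for i, t in enumerate(self.trees):
            if t.tip_set != tipset:
                raise TreeError(f"tree {i} has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Chronogram:
        return self.trees[i]

    @property
    def tip_set(self) -> frozenset[str]:
        return self.trees[0].tip_set

    def map(self, fn) -> "TreeSample":
        return TreeSample([fn(t) for t in self.trees], provenance=self.provenance)

    # -- IO ---------------------------------------------------------------

    def write_newick_file(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.to_newick() + "\n")

    @classmethod
    def read_newick_file(cls, path) -> "TreeSample":
        trees = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    trees.append(parse_newick(line))
        return cls(trees, provenance="file")

    @classmethod
    def read_nexus(cls, path) -> "TreeSample":
        """Read a NEXUS TREES block (translate tables supported)."""
        try:
            tl = dendropy.TreeList.get(path=str(path), schema="nexus",
                                       rooting="force-rooted",
                                       preserve_underscores=True)
        except Exception as exc:
            raise NewickParseError(f"malformed NEXUS: {exc}") from exc
        trees = [_from_dendropy(t, require_lengths=True) for t in tl]
        return cls(trees, provenance="file")
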