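"""Phylogeny handling: Newick IO, pruning/alignment, Brownian covariance.

Under Brownian motion on a rooted tree with branch lengths, the expected
covariance of a trait between two tips equals the length of their shared
root-to-tip path (the depth of their most recent common ancestor), and the
variance at a tip equals its root-to-tip depth. Generalized least squares
on such a covariance is performed by whitening data with C^(-1/2).

Tree parsing, writing and pruning are delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import AlignmentError, NumericalError, ValidationError

#: refuse to invert covariances with condition number above this
MAX_CONDITION = 1e12


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and unique tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({s for s in labels if labels.count(s) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def write_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on non-root edges)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"malformed Newick: {exc}") from exc
    phy = Phylogeny(tree=tree)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValidationError("tree has edges without branch lengths")
    return phy


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def prune_and_align(
    phy: Phylogeny, labels: Sequence[str]
) -> tuple[Phylogeny, dict[str, int]]:
    """Restrict a tree to ``labels`` (exact match after whitespace trim).

    Returns the pruned tree and a label -> row index map; all downstream
    matrices (covariance, trait tables) follow this row order, which is
    the order of ``labels``.
    """
    wanted = [str(s).strip() for s in labels]
    if len(set(wanted)) != len(wanted):
        raise ValidationError("requested labels contain duplicates")
    have = set(phy.tip_labels)
    missing = [s for s in wanted if s not in have]
    if missing:
        raise AlignmentError(f"labels absent from tree: {missing}")
    tree = phy.tree.clone(depth=1)
    tree.retain_taxa_with_labels(wanted)
    pruned = Phylogeny(tree=tree)
    return pruned, {s: i for i, s in enumerate(wanted)}


@dataclass
class PhyloCovariance:
    """Expected Brownian trait covariance among tips (n x n, PSD)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.values, dtype=float)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("covariance shape does not match labels")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValidationError("covariance is not symmetric")
        self.values = (c + c.T) / 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "PhyloCovariance":
        idx = {s: i for i, s in enumerate(self.labels)}
        missing = [s for s in labels if s not in idx]
        if missing:
            raise AlignmentError(f"labels absent from covariance: {missing}")
        sel = [idx[s] for s in labels]
        return PhyloCovariance(
            labels=list(labels), values=self.values[np.ix_(sel, sel)]
        )


def vcv(phy: Phylogeny, order: Sequence[str] | None = None) -> PhyloCovariance:
    """Brownian covariance matrix: C[i, j] = depth of MRCA(i, j)."""
    tree = phy.tree
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[id(node)] = edge + (depth[id(parent)] if parent is not None else 0.0)

    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    c = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            c[i, i] = depth[id(node)]
            tipsets[id(node)] = [i]
            continue
        children = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        h = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                c[np.ix_(ia, ib)] = h
                c[np.ix_(ib, ia)] = h
        tipsets[id(node)] = [i for ch in children for i in ch]
    cov = PhyloCovariance(labels=labels, values=c)
    if order is not None:
        cov = cov.reorder([str(s).strip() for s in order])
    return cov


def inv_sqrt(C: PhyloCovariance | np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Symmetric inverse square root P = C^(-1/2), so P C P = I.

    Computed by eigendecomposition. Raises on (numerically) singular C and
    suggests a small ridge; the ridge is off by default and, when given,
    is added as ridge * I before decomposition.
    """
    c = C.values if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    if ridge:
        c = c + ridge * np.eye(c.shape[0])
    eigval, eigvec = np.linalg.eigh((c + c.T) / 2)
    if eigval[0] <= 0 or eigval[-1] / eigval[0] > MAX_CONDITION:
        n = c.shape[0]
        suggestion = 1e-10 * np.trace(c) / n
        raise NumericalError(
            "covariance is singular or ill-conditioned "
            f"(min eigenvalue {eigval[0]:.3e}); consider ridge={suggestion:.3e}"
        )
    return (eigvec * (1.0 / np.sqrt(eigval))) @ eigvec.T
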