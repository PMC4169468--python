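"""Strain phylogenies and the shared-ancestry covariance structure.

The comparative model assumes that, under Brownian trait evolution on an
ultrametric tree, the covariance of phylogenetic effects between strains
*j* and *k* is proportional to ``a_jk``, the proportion of time since the
root during which the two lineages were one (the depth of their most recent
common ancestor divided by the root-to-tip depth).  The matrix ``A`` of
these proportions has unit diagonal and is positive semi-definite; all of
the magnitude of phylogenetic variance then lives in the trait covariance
``V_p`` of the Kronecker structure ``V_p (x) A``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "SharedAncestryMatrix",
    "read_newick",
    "write_newick",
    "shared_ancestry_matrix",
    "brownian_covariance",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths over uniquely labelled strains."""

    tree: dendropy.Tree

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per strain label."""
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = np.array(list(self.leaf_depths().values()))
        dmax = depths.max()
        if dmax <= 0:
            return True
        return (depths.max() - depths.min()) / dmax <= rel_tol


@dataclass
class SharedAncestryMatrix:
    """Pairwise shared-ancestry proportions ``a_jk`` with strain labels."""

    labels: list[str]
    A: np.ndarray
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="strain")

    @classmethod
    def from_tsv(cls, path) -> "SharedAncestryMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), A=df.to_numpy(dtype=float))

    def reorder(self, labels: list[str]) -> "SharedAncestryMatrix":
        idx = [self.labels.index(l) for l in labels]
        return SharedAncestryMatrix(list(labels), self.A[np.ix_(idx, idx)],
                                    list(self.degenerate_pairs))


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string into a rooted :class:`Phylogeny`.

    Raises
    ------
    NewickParseError
        On malformed newick, with the approximate character offset.
    ValueError
        On duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "column", None)
        where = f" near character offset {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed newick{where}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return Phylogeny(tree=tree)


def write_newick(phy: Phylogeny) -> str:
    out = io.StringIO()
    phy.tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()


def shared_ancestry_matrix(phy: Phylogeny, rel_tol: float = 1e-6) -> SharedAncestryMatrix:
    """Shared-ancestry proportions from an ultrametric rooted tree.

    ``a_jk`` is the depth (from the root) of the MRCA of leaves *j* and *k*,
    divided by the common root-to-leaf depth; ``a_jj = 1``.

    Raises
    ------
    ValueError
        If the tree is non-ultrametric beyond ``rel_tol`` relative leaf-depth
        spread, has fewer than two leaves, or has zero total depth.
    """
    leaves = list(phy.tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("shared ancestry requires a tree with >= 2 leaves")
    depths = phy.leaf_depths()
    dvals = np.array([depths[l.taxon.label] for l in leaves])
    dmax = float(dvals.max())
    if dmax <= 0:
        raise ValueError("degenerate tree: zero root-to-leaf depth")
    if (dvals.max() - dvals.min()) / dmax > rel_tol:
        raise ValueError(
            "tree is not ultrametric: relative leaf-depth spread "
            f"{(dvals.max() - dvals.min()) / dmax:.3g} exceeds {rel_tol:.3g}"
        )

    # Node depths from the root, then a_jk = depth(MRCA)/depth(root-to-leaf).
    node_depth: dict[int, float] = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            node_depth[id(node)] = 0.0
        else:
            node_depth[id(node)] = node_depth[id(node.parent_node)] + (node.edge.length or 0.0)

    labels = [l.taxon.label for l in leaves]
    n = len(labels)
    A = np.eye(n)
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxa = {l.taxon.label: l.taxon for l in leaves}
    for i in range(n):
        for j in range(i + 1, n):
            mrca = pdm.mrca(taxa[labels[i]], taxa[labels[j]])
            A[i, j] = A[j, i] = node_depth[id(mrca)] / dmax

    degenerate = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if A[i, j] >= 1.0 - 1e-12
    ]
    if degenerate:
        logger.warning(
            "shared-ancestry matrix is singular: %d tip pair(s) with zero "
            "divergence (a_jk = 1): %s", len(degenerate), degenerate,
        )
    return SharedAncestryMatrix(labels=labels, A=A, degenerate_pairs=degenerate)


def brownian_covariance(A: SharedAncestryMatrix | np.ndarray, sigma2: float) -> np.ndarray:
    """Phylogenetic trait covariance ``sigma2 * A`` under Brownian evolution."""
    if sigma2 < 0:
        raise ValueError(f"variance must be non-negative, got {sigma2}")
    mat = A.A if isinstance(A, SharedAncestryMatrix) else np.asarray(A, dtype=float)
    return sigma2 * mat
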