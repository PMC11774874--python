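"""Species phylogenies and Brownian-motion covariance structure.

A rooted tree with branch lengths induces, under Brownian motion, a
covariance between any two tips equal to the summed branch length from
the root to their most recent common ancestor (MRCA).  That matrix C is
the backbone of every phylogenetically corrected statistic in this
package.  Trees are held as thin wrappers over :mod:`dendropy` trees so
that Newick I/O, pruning and polytomy resolution all go through a
well-tested library, while the covariance computation itself is explicit
here.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloVCV",
    "parse_newick",
    "resolve_polytomies",
    "vcv_matrix",
    "lambda_transform",
]

#: relative tolerance on the smallest eigenvalue when checking positive
#: semi-definiteness of a covariance matrix
_PSD_RTOL = 1e-8


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be turned into a valid tree."""


@dataclass(frozen=True)
class PhyloVCV:
    """Phylogenetic variance-covariance matrix under Brownian motion.

    Attributes
    ----------
    labels : tuple of str
        Tip labels in the order of the matrix rows/columns.
    matrix : ndarray of shape (n, n)
        ``matrix[i, j]`` is the root-to-MRCA path length of tips i and j;
        the diagonal holds root-to-tip depths.  Units are the tree's
        branch-length units.
    lam : float or None
        Pagel's lambda applied to the off-diagonal, if any.
    """

    labels: tuple
    matrix: np.ndarray = field(repr=False)
    lam: float | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if len(self.labels) != m.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def is_psd(self) -> bool:
        return self.min_eigenvalue() >= -_PSD_RTOL * max(np.trace(self.matrix), 1.0)

    def lambda_max(self) -> float:
        """Largest lambda keeping the transformed matrix PSD.

        For an ultrametric tree this is depth / (height of the deepest
        internal node) and is always >= 1.
        """
        off = self.matrix[~np.eye(self.n, dtype=bool)]
        m = off.max(initial=0.0)
        if m <= 0:
            return np.inf  # star tree: any lambda leaves C diagonal
        return float(self.matrix.diagonal().min() / m)

    def transform(self, lam: float) -> "PhyloVCV":
        return lambda_transform(self, lam)

    def subset(self, labels) -> "PhyloVCV":
        """Reorder/restrict to the given tip labels."""
        idx = [self.labels.index(l) for l in labels]
        return PhyloVCV(tuple(labels), self.matrix[np.ix_(idx, idx)], self.lam)


class PhyloTree:
    """Rooted phylogeny with branch lengths, wrapping a dendropy tree.

    Invariants enforced at construction: unique non-empty tip labels,
    non-negative branch lengths on every non-root edge, a single root.
    Unequal root-to-tip depths (non-ultrametric trees) only warn.
    """

    def __init__(self, tree: dendropy.Tree, default_branch_length: float | None = None):
        self._tree = tree
        self._validate(default_branch_length)

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, default_branch_length: float | None = None) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(t, default_branch_length=default_branch_length)

    def _validate(self, default_branch_length):
        seen = set()
        for leaf in self._tree.leaf_node_iter():
            lbl = None if leaf.taxon is None else leaf.taxon.label
            if not lbl:
                raise NewickParseError("tip with empty label")
            if lbl in seen:
                raise NewickParseError(f"duplicate tip label {lbl!r}")
            seen.add(lbl)
        if len(seen) < 2:
            raise NewickParseError("tree must have at least two tips")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                if default_branch_length is None:
                    raise NewickParseError(
                        f"missing branch length above {_node_name(node)} "
                        "(no default configured)"
                    )
                node.edge.length = float(default_branch_length)
            if node.edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.edge.length} above {_node_name(node)}"
                )
            if node.edge.length == 0 and node.is_leaf():
                warnings.warn(
                    f"zero-length terminal branch at {_node_name(node)}",
                    UserWarning,
                    stacklevel=3,
                )
        depths = [_root_distance(lf) for lf in self._tree.leaf_node_iter()]
        if max(depths) <= 0:
            raise NewickParseError("all root-to-tip path lengths are zero")
        if not np.allclose(depths, depths[0], rtol=1e-8, atol=1e-12):
            warnings.warn("tree is not ultrametric (unequal tip depths)",
                          UserWarning, stacklevel=3)

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> tuple:
        return tuple(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_binary(self) -> bool:
        return all(len(n.child_nodes()) == 2
                   for n in self._tree.preorder_internal_node_iter())

    def tip_depths(self) -> dict:
        return {lf.taxon.label: _root_distance(lf)
                for lf in self._tree.leaf_node_iter()}

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True)
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def prune_to(self, labels) -> "PhyloTree":
        """Tree restricted to the given tips (order irrelevant)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        t = self._tree.clone(depth=1)
        taxa = [tx for tx in t.taxon_namespace if tx.label in keep]
        t.retain_taxa(taxa)
        return PhyloTree(t)

    def normalize_labels(self) -> "PhyloTree":
        """Replace underscores with spaces in tip labels (opt-in)."""
        t = self._tree.clone(depth=1)
        for tx in t.taxon_namespace:
            tx.label = tx.label.replace("_", " ")
        return PhyloTree(t)

    # -- structure -----------------------------------------------------

    def resolve_polytomies(self) -> "PhyloTree":
        """Return a strictly bifurcating tree.

        Multifurcations are split deterministically in child input order
        by inserting zero-length internal edges, so root-to-tip path sums
        — and hence the covariance matrix — are unchanged.
        """
        t = self._tree.clone(depth=1)
        for node in list(t.preorder_internal_node_iter()):
            children = node.child_nodes()
            while len(children) > 2:
                # pull the first two children under a new zero-length node
                a, b = children[0], children[1]
                node.remove_child(a)
                node.remove_child(b)
                new = dendropy.Node()
                new.edge.length = 0.0
                new.add_child(a)
                new.add_child(b)
                node.insert_child(0, new)
                children = node.child_nodes()
        return PhyloTree(t)

    def vcv(self) -> PhyloVCV:
        """Brownian-motion covariance matrix over the tips.

        ``C[i, j]`` = summed branch length from the root down to
        MRCA(i, j); the diagonal holds tip depths.  Filled by a single
        preorder sweep: at each internal node of depth d, every tip pair
        split across two different child subtrees has MRCA exactly there,
        so the corresponding block of C is set to d.
        """
        labels = self.tip_labels
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))

        # node depth and descendant-tip index lists, bottom-up
        tips_below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tips_below[node] = [index[node.taxon.label]]
            else:
                tips_below[node] = [i for c in node.child_nodes()
                                    for i in tips_below[c]]

        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                node._depth = 0.0
            else:
                node._depth = node.parent_node._depth + (node.edge.length or 0.0)
            if node.is_leaf():
                C[index[node.taxon.label], index[node.taxon.label]] = node._depth
            else:
                kids = node.child_nodes()
                for ai in range(len(kids)):
                    for bi in range(ai + 1, len(kids)):
                        ia = tips_below[kids[ai]]
                        ib = tips_below[kids[bi]]
                        C[np.ix_(ia, ib)] = node._depth
                        C[np.ix_(ib, ia)] = node._depth
        return PhyloVCV(labels, C)


def _root_distance(node) -> float:
    d = 0.0
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return "<internal node>"


# ---------------------------------------------------------------------
# functional surface


def parse_newick(text: str, default_branch_length: float | None = None) -> PhyloTree:
    """Parse a single Newick tree with branch lengths."""
    return PhyloTree.from_newick(text, default_branch_length=default_branch_length)


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    return tree.resolve_polytomies()


def vcv_matrix(tree: PhyloTree) -> PhyloVCV:
    return tree.vcv()


def lambda_transform(vcv: PhyloVCV, lam: float) -> PhyloVCV:
    """Pagel's lambda: multiply off-diagonal covariances by ``lam``.

    ``lam`` must lie in [0, lambda_max], where lambda_max is the largest
    value keeping the matrix positive semi-definite (>= 1 for ultrametric
    trees).
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    C = vcv.matrix.copy()
    off = ~np.eye(vcv.n, dtype=bool)
    C[off] *= lam
    out = PhyloVCV(vcv.labels, C, lam=float(lam))
    if lam > 1.0 and not out.is_psd():
        raise ValueError(
            f"lambda={lam} exceeds lambda_max={vcv.lambda_max():.6g}: "
            "transformed matrix is not positive semi-definite"
        )
    return out
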