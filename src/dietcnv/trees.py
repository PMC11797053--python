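"""Phylogenies and the Brownian-motion among-species covariance.

Every comparative statistic downstream (the phylogenetic GLMM, Pagel's
lambda, Blomberg's K, phylogenetic discriminant analysis) consumes the
among-species covariance matrix C implied by Brownian motion on a rooted
tree with branch lengths: ``C[i, j]`` is the shared root-to-MRCA path
length of tips i and j, and the diagonal holds root-to-tip distances.

Newick parsing and topology manipulation are delegated to :mod:`dendropy`;
this module owns validation, the covariance computation, Pagel's
lambda-scaling of that covariance, and simple ultrametricization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCov",
    "read_newick",
    "write_newick",
    "vcv_matrix",
    "lambda_transform",
    "lambda_max",
    "make_ultrametric",
    "prune_to_species",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


@dataclass
class PhyloTree:
    """A rooted phylogeny with non-negative branch lengths and unique tips.

    Thin wrapper around a :class:`dendropy.Tree`; construct via
    :func:`read_newick` or the simulators rather than directly.
    """

    _tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in a fixed (preorder) traversal order."""
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def newick(self) -> str:
        return (
            self._tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        depths: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            edge = node.edge.length or 0.0
            node._depth = (0.0 if node.parent_node is None
                           else node.parent_node._depth + edge)
            if node.is_leaf():
                depths[node.taxon.label] = node._depth
        return depths

    def validate(self) -> None:
        labels = [lf.taxon.label if lf.taxon else "" for lf in
                  self._tree.leaf_node_iter()]
        if any(not lab for lab in labels):
            raise TreeValidationError("empty tip label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeValidationError(
                f"duplicate tip labels: {sorted(dupes)}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is not None:
                if node.edge.length < 0:
                    raise TreeValidationError(
                        f"negative branch length {node.edge.length} above "
                        f"node {node.taxon.label if node.taxon else '<internal>'}")


@dataclass
class PhyloCov:
    """Brownian-motion covariance C with its explicit species order."""

    species: list[str]
    C: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.species)
        if self.C.shape != (n, n):
            raise ValueError(
                f"C shape {self.C.shape} does not match {n} species")
        if not np.allclose(self.C, self.C.T, rtol=0, atol=1e-10):
            raise ValueError("C must be symmetric")

    def reorder(self, species: list[str]) -> "PhyloCov":
        idx = [self.species.index(s) for s in species]
        return PhyloCov(list(species), self.C[np.ix_(idx, idx)])


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Unquoted labels, ``:``-suffixed branch lengths and ``[...]`` comments
    are accepted; polytomies are preserved.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "duplicate" in str(exc).lower():
            raise TreeValidationError(f"duplicate tip label: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    out = PhyloTree(tree)
    out.validate()
    return out


def write_newick(tree: PhyloTree) -> str:
    return tree.newick()


def _node_depths(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        node._depth = (0.0 if node.parent_node is None
                       else node.parent_node._depth + edge)


def vcv_matrix(tree: PhyloTree) -> PhyloCov:
    """Brownian-motion variance–covariance matrix of a rooted tree.

    ``C[i, j]`` equals the root-to-MRCA path length of tips i and j;
    the diagonal is the root-to-tip distance.
    """
    t = tree._tree
    leaves = t.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("vcv_matrix needs a tree with at least 2 tips")
    _node_depths(t)
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    C = np.zeros((n, n))
    # postorder: each node contributes its depth to all tip pairs whose
    # MRCA it is; accumulate leaf sets bottom-up.
    index = {id(lf): i for i, lf in enumerate(leaves)}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            node._leafset = [index[id(node)]]
            C[node._leafset[0], node._leafset[0]] = node._depth
        else:
            kids = [ch._leafset for ch in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = node._depth
            node._leafset = [i for k in kids for i in k]
    return PhyloCov(labels, C)


def lambda_max(cov: PhyloCov, tol: float = 1e-10) -> float:
    """Largest lambda keeping ``lambda_transform(cov, lam)`` positive definite.

    Found by bisection on the smallest eigenvalue; can exceed 1 slightly
    (fitted values such as 1.002 occur in practice).
    """
    def min_eig(lam: float) -> float:
        M = _scaled(cov.C, lam)
        return float(np.linalg.eigvalsh(M)[0])

    hi = 1.0
    while min_eig(hi) > tol * np.trace(cov.C) and hi < 16:
        hi *= 2
    if hi >= 16:
        return 16.0
    lo = hi / 2 if hi > 1 else 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_eig(mid) > tol * np.trace(cov.C):
            lo = mid
        else:
            hi = mid
    return lo


def _scaled(C: np.ndarray, lam: float) -> np.ndarray:
    M = lam * C
    np.fill_diagonal(M, np.diag(C))
    return M


def lambda_transform(cov: PhyloCov, lam: float) -> PhyloCov:
    """Pagel's lambda scaling: multiply off-diagonals by lam, keep diagonal.

    lam = 1 is the Brownian-motion covariance unchanged; lam = 0 removes
    all phylogenetic covariance (star phylogeny).
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if lam > 1:
        lmax = lambda_max(cov)
        if lam > lmax + 1e-9:
            raise ValueError(
                f"lambda {lam} exceeds admissible maximum {lmax:.6f} "
                "(transformed matrix not positive definite)")
    return PhyloCov(list(cov.species), _scaled(cov.C, lam))


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-9) -> bool:
    depths = list(tree.tip_depths().values())
    dmax = max(depths)
    if dmax <= 0:
        return False
    return (dmax - min(depths)) <= rel_tol * dmax


def make_ultrametric(tree: PhyloTree, method: str = "extend") -> PhyloTree:
    """Force equal root-to-tip depths without re-dating the tree.

    ``extend`` lengthens each terminal branch to reach the maximum depth;
    ``mean_path_length`` adjusts terminal branches to the mean depth and
    refuses if that would make a branch negative. Topology is unchanged.
    """
    if method not in ("extend", "mean_path_length"):
        raise ValueError(f"unknown method {method!r}; "
                         "use 'extend' or 'mean_path_length'")
    out = tree.copy()
    t = out._tree
    _node_depths(t)
    depths = {id(lf): lf._depth for lf in t.leaf_nodes()}
    if max(depths.values()) <= 0:
        raise ValueError("tree has zero total depth")
    target = (max(depths.values()) if method == "extend"
              else float(np.mean(list(depths.values()))))
    for lf in t.leaf_nodes():
        delta = target - depths[id(lf)]
        new_len = (lf.edge.length or 0.0) + delta
        if new_len < -1e-12:
            raise ValueError(
                f"mean_path_length would make the branch above "
                f"{lf.taxon.label} negative; use method='extend'")
        lf.edge.length = max(new_len, 0.0)
    return out


def prune_to_species(tree: PhyloTree, keep) -> PhyloTree:
    """Induced subtree on ``keep``; unary nodes collapsed, lengths summed."""
    keep = set(keep)
    tips = set(tree.tip_labels)
    unknown = keep - tips
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 species to keep")
    out = tree.copy()
    t = out._tree
    # dendropy suppresses unifurcations while pruning, summing edge lengths;
    # a unary root (keep set inside one subtree) is left as-is so original
    # root-to-tip depths survive.
    t.retain_taxa_with_labels(sorted(keep))
    return PhyloTree(t)
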