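"""Phylogenetic covariance structure from newick trees.

Under Brownian trait evolution on a rooted tree, the expected covariance
between two tips is the length of the root path they share; the matrix of
shared path lengths C (diagonal: root-to-tip depth) is therefore the natural
random-effect covariance for comparative models. For trees with branch
lengths in substitutions per site (not ultrametric), the standardized
correlation form R[i, j] = C[i, j] / sqrt(C[i, i] C[j, j]) is the default
structure fed to the sampler.

dendropy handles newick parsing and tree surgery; the covariance derivation
and species matching live here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import TreeError

__all__ = [
    "PhyloCovariance",
    "parse_newick",
    "phylo_vcv",
    "vcv_to_correlation",
    "prune_and_match",
    "normalize_name",
]


def normalize_name(name: str) -> str:
    """Case-insensitive species-name key: whitespace/underscores unified."""
    return re.sub(r"[\s_]+", "_", name.strip().lower())


@dataclass
class PhyloCovariance:
    """Tip-labelled symmetric matrix of shared root-to-tip path lengths."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise TreeError("covariance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise TreeError("covariance matrix must be symmetric")
        self.matrix = m

    def index_of(self, name: str) -> int:
        key = normalize_name(name)
        for i, lab in enumerate(self.labels):
            if normalize_name(lab) == key:
                return i
        raise TreeError(f"tip {name!r} not in covariance matrix")


def parse_newick(text: str, missing_lengths: str = "error") -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    ``missing_lengths``: "error" (default) rejects edges without a length;
    "zero" treats them as zero-length.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(normalize_name(l) for l in labels)):
        raise TreeError("duplicate tip labels in tree")
    if len(labels) < 2:
        raise TreeError("tree must have at least two tips")

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge
            continue
        if edge.length is None:
            if missing_lengths == "zero":
                edge.length = 0.0
            else:
                raise TreeError("edge without branch length (set missing_lengths='zero' to allow)")
        elif edge.length < 0:
            raise TreeError("negative branch length")
    return tree


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_vcv(tree: dendropy.Tree, zero_branch_epsilon: float = 1e-8) -> PhyloCovariance:
    """Shared root-path covariance C from a rooted tree.

    C[i, j] is the summed branch length from the root to the most recent
    common ancestor of tips i and j; the diagonal holds root-to-tip depths.
    Zero-length terminal branches receive ``zero_branch_epsilon`` times the
    maximum depth on the diagonal so C stays invertible.
    """
    root = tree.seed_node
    if root is None or len(root.child_nodes()) == 0:
        raise TreeError("empty tree")
    if len(root.child_nodes()) == 1:
        raise TreeError("degenerate root; reroot the tree upstream (midpoint or outgroup)")

    # Depth of every node, then C via postorder accumulation of tip sets.
    depth: dict[dendropy.Node, float] = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    leaves = [leaf for leaf in tree.leaf_node_iter()]
    labels = [leaf.taxon.label for leaf in leaves]
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            C[i, i] = depth[node]
            tipsets[node] = [i]
        else:
            children = node.child_nodes()
            sets = [tipsets.pop(ch) for ch in children]
            d = depth[node]
            for si in range(len(sets)):
                for sj in range(si + 1, len(sets)):
                    for a in sets[si]:
                        C[a, sets[sj]] = d
                        C[sets[sj], a] = d
            merged: list[int] = []
            for s in sets:
                merged.extend(s)
            tipsets[node] = merged

    maxdepth = float(C.diagonal().max())
    if maxdepth <= 0:
        raise TreeError("tree has zero depth")
    for leaf in leaves:
        if (leaf.edge.length or 0.0) == 0.0:
            i = index[leaf]
            C[i, i] += zero_branch_epsilon * maxdepth
    return PhyloCovariance(labels=labels, matrix=C)


def vcv_to_correlation(cov: PhyloCovariance) -> PhyloCovariance:
    """Standardize C to unit diagonal: R[i, j] = C[i, j]/sqrt(C[i, i] C[j, j])."""
    d = cov.matrix.diagonal()
    if (d <= 0).any():
        bad = [cov.labels[i] for i in np.where(d <= 0)[0]]
        raise TreeError(f"zero root-to-tip depth for tips {bad}")
    s = 1.0 / np.sqrt(d)
    R = cov.matrix * np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return PhyloCovariance(labels=list(cov.labels), matrix=R)


def prune_and_match(
    tree: dendropy.Tree, species: list[str]
) -> tuple[dendropy.Tree, dict[str, int]]:
    """Restrict the tree to the requested species, in a stable matrix order.

    Matching is case-insensitive with spaces and underscores unified; any
    species absent from the tree is an error naming it (never fuzzy-matched).
    Returns the pruned tree (internal unifurcations coalesced, branch lengths
    summed) and a map from the *requested* names to row indices of the
    covariance matrix subsequently produced by :func:`phylo_vcv`.
    """
    keys = {}
    for sp in species:
        k = normalize_name(sp)
        if k in keys:
            raise TreeError(f"duplicate species requested: {sp!r}")
        keys[k] = sp

    by_key = {}
    for leaf in tree.leaf_node_iter():
        by_key[normalize_name(leaf.taxon.label)] = leaf.taxon
    missing = [keys[k] for k in keys if k not in by_key]
    if missing:
        raise TreeError(f"species not found in tree: {missing}")

    pruned = tree.clone(depth=1)
    keep = set(keys)
    taxa = [t for t in pruned.taxon_namespace if normalize_name(t.label) in keep]
    pruned.retain_taxa(taxa)
    pruned.purge_taxon_namespace()

    order = [leaf.taxon.label for leaf in pruned.leaf_node_iter()]
    index_map = {
        keys[normalize_name(lab)]: i for i, lab in enumerate(order)
    }
    return pruned, index_map
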