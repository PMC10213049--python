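"""Trees, monophyly and the normalized phylogenetic distance (nPD).

Trees are inferred by neighbor joining on SNP-count distance matrices
(adequate for the topology/branch-length decisions made here; negative NJ
branches are clamped to zero) and midpoint-rooted before any monophyly
test. nPD between two leaves is their patristic distance divided by the
tree's total branch length; two samples are called as sharing a strain
when nPD < 0.001 (strict), the calibration point at which isolate-confirmed
identical strains separate from distinct lineages. A looser 0.01 cutoff is
known to overcount sharing and is deliberately not the default.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _nj

from straindyad.distance import DistanceMatrix
from straindyad.errors import InputError, ParameterError

NPD_SHARE_THRESHOLD = 0.001


def build_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a SNP distance matrix.

    Taxa are ordered lexicographically before joining so the agglomeration
    order (and hence tie-breaking) is deterministic and independent of the
    input taxon order. Negative NJ branch lengths are clamped to zero.
    For exactly two taxa the trivial two-leaf tree with the distance split
    evenly is returned.
    """
    if matrix.kind != "snp_count":
        raise InputError(f"build_tree expects a snp_count matrix, got {matrix.kind!r}")
    if len(matrix) < 2:
        raise InputError("need at least 2 taxa to build a tree")
    order = sorted(matrix.taxa)
    sub = matrix.submatrix(order)
    if len(order) == 2:
        d = sub.values[0, 1] / 2.0
        return TreeNode.read([f"({order[0]}:{d:.10g},{order[1]}:{d:.10g});"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns when clamping negatives
        tree = _nj(_SkbioDM(sub.values, ids=order))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Patristic distances are preserved; the input tree is not modified.
    """
    n_tips = tree.count(tips=True)
    if n_tips < 2:
        raise InputError("midpoint rooting needs at least 2 leaves")
    if n_tips == 2:
        # the midpoint halves the single leaf-to-leaf path
        a, b = tree.tips()
        half = ((a.length or 0.0) + (b.length or 0.0)) / 2.0
        return TreeNode.read([f"({a.name}:{half:.10g},{b.name}:{half:.10g});"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rooted = tree.copy().root_at_midpoint()
    return rooted


def is_monophyletic(tree: TreeNode, taxa: set[str]) -> bool:
    """True iff some clade of the rooted tree contains exactly ``taxa``."""
    leaf_names = {t.name for t in tree.tips()}
    unknown = set(taxa) - leaf_names
    if unknown:
        raise InputError(f"labels not in tree: {sorted(unknown)}")
    if not taxa:
        raise InputError("taxa set must be non-empty")
    if len(taxa) == 1:
        return True
    lca = tree.lca(list(taxa))
    return {t.name for t in lca.tips()} == set(taxa)


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=False)))


def npd_matrix(tree: TreeNode) -> DistanceMatrix:
    """Normalized phylogenetic distance between every leaf pair.

    nPD(i, j) = patristic(i, j) / total branch length, so entries lie in
    [0, 1] and are invariant to uniform branch-length scaling (and to
    rooting, since rooting preserves both numerator and denominator).
    A zero-total-branch-length tree (all taxa identical) yields an all-zero
    matrix with a warning rather than an error.
    """
    tt = tree.tip_tip_distances()
    ids = list(tt.ids)
    total = total_branch_length(tree)
    if total == 0.0:
        warnings.warn("total branch length is 0; all taxa identical, nPD set to 0")
        values = np.zeros((len(ids), len(ids)))
    else:
        values = np.asarray(tt.data, dtype=float) / total
    return DistanceMatrix(ids, values, "npd")


def npd_share_call(npd: float, threshold: float = NPD_SHARE_THRESHOLD) -> bool:
    """Strain-sharing rule on nPD: strictly less than the threshold."""
    if npd < 0 or not np.isfinite(npd):
        raise ParameterError(f"npd must be finite and >= 0, got {npd}")
    return npd < threshold


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
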