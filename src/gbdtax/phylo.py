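"""Distance-based tree inference, rooting, monophyly and branch support.

Trees are scikit-bio ``TreeNode`` objects.  Inference is neighbor joining
(deterministic under fixed input order; negative branch length estimates
are clamped to zero), optionally followed by nearest-neighbor-interchange
rearrangement under balanced minimum evolution.

Branch support comes from pseudo-bootstrap replicate distance matrices:
each replicate matrix is run through the same tree builder and an internal
branch's support is the percentage of replicate trees containing the same
bipartition of the leaf set.  All supports are kept on the tree; hiding
values <= 50 is purely a rendering convention applied when writing Newick
with ``hide_below``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from skbio.tree import TreeNode, nj, nni, TreeError

from .distance import DistanceMatrix

__all__ = [
    "build_tree",
    "root_with_outgroup",
    "is_monophyletic",
    "bipartitions",
    "annotate_support",
    "to_newick",
    "from_newick",
    "TreeError",
]


def build_tree(matrix: DistanceMatrix, improve: bool = False) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    With ``improve=True`` the NJ topology is refined by NNI under balanced
    minimum evolution.  Negative branch lengths are clamped to 0.
    """
    if len(matrix) < 3:
        raise ValueError("tree inference needs at least 3 strains")
    dm = matrix.to_skbio()
    tree = nj(dm)
    if improve:
        tree = nni(tree, dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def root_with_outgroup(tree: TreeNode, outgroup: Iterable[str]) -> TreeNode:
    """Root on the branch separating the outgroup clade from the ingroup.

    Raises ``TreeError`` if the outgroup is not monophyletic in the
    unrooted tree, or if it does not leave any ingroup leaf.
    """
    outgroup = list(outgroup)
    leaves = {t.name for t in tree.tips()}
    missing = set(outgroup) - leaves
    if missing:
        raise KeyError(f"outgroup labels not in tree: {sorted(missing)}")
    return tree.root_by_outgroup(outgroup)


def is_monophyletic(tree: TreeNode, labels: Iterable[str]) -> bool:
    """True iff some node's leaf-descendant set equals ``labels`` exactly.

    The test is taken on the rooted topology: a group that is only a clade
    after re-rooting does not count.
    """
    target = set(labels)
    leaves = {t.name for t in tree.tips()}
    unknown = target - leaves
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    for node in tree.traverse(include_self=True):
        node_set = (
            {node.name} if node.is_tip() else {t.name for t in node.tips()}
        )
        if node_set == target:
            return True
    return False


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, canonically encoded.

    Each internal branch splits the leaves in two; the bipartition is
    encoded as the side containing the lexicographically smallest leaf, so
    the encoding is invariant to (re)rooting.
    """
    leaves = sorted(t.name for t in tree.tips())
    full = frozenset(leaves)
    anchor = leaves[0]
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(full) - 1:
            continue
        canon = side if anchor in side else full - side
        out.add(canon)
    return out


def annotate_support(
    tree: TreeNode,
    replicate_matrices: Sequence[DistanceMatrix],
    improve: bool = False,
) -> TreeNode:
    """Attach pseudo-bootstrap supports (0-100) to internal branches.

    Each replicate matrix is turned into a tree with the same builder; the
    support of an internal branch is the percentage of replicate trees
    whose bipartition set contains it.  Returns a copy of ``tree`` with
    ``node.support`` set on internal nodes.
    """
    if not replicate_matrices:
        raise ValueError("need at least one replicate matrix")
    leaves = sorted(t.name for t in tree.tips())
    for m in replicate_matrices:
        if sorted(m.labels) != leaves:
            raise ValueError("replicate matrix labels do not match the tree")
    counts: dict[frozenset[str], int] = {}
    for m in replicate_matrices:
        for bp in bipartitions(build_tree(m, improve=improve)):
            counts[bp] = counts.get(bp, 0) + 1
    full = frozenset(leaves)
    anchor = leaves[0]
    out = tree.copy()
    n_rep = len(replicate_matrices)
    for node in out.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(full) - 1:
            continue
        canon = side if anchor in side else full - side
        node.support = 100.0 * counts.get(canon, 0) / n_rep
    return out


def to_newick(tree: TreeNode, hide_below: float | None = None) -> str:
    """Serialize with supports as internal node labels.

    ``hide_below`` omits supports at or below the given value (the
    conventional rendering shows supports only if larger than 50%); the
    tree object itself always keeps every support.
    """
    t = tree.copy()
    for node in t.non_tips(include_self=True):
        sup = getattr(node, "support", None)
        if sup is None or (hide_below is not None and sup <= hide_below):
            node.name = None
        else:
            node.name = format(sup, "g")
        node.support = None  # keep skbio's writer from duplicating it
    return str(t).strip()


def from_newick(newick: str) -> TreeNode:
    """Read a Newick string, interpreting numeric internal labels as supports."""
    tree = TreeNode.read([newick])
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
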