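"""General-public preparation of a taxonomy tree.

Three cleanup passes precede layout: dropping clades whose names flag them as
unidentified/unclassified/environmental/uncultured material, pruning everything
below the species level so species become the tips, and auto-naming unnamed
internal nodes from their descendants so every clade can carry a label on the
map. All passes return a new tree and re-derive leaf counts and depths.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .errors import FilterError, UnnamedLeafError
from .treeio import Tree

__all__ = [
    "BANNED_WORDS",
    "BELOW_SPECIES_RANKS",
    "filter_banned",
    "prune_below_species",
    "autoname_nodes",
    "annotate_counts",
]

#: Name fragments that mark a taxon as uninformative for a general audience.
#: Matching is case-sensitive substring; both capitalisations are listed.
BANNED_WORDS: tuple[str, ...] = (
    "unidentified",
    "Unidentified",
    "unclassified",
    "Unclassified",
    "environmental",
    "Environmental",
    "uncultured",
    "Uncultured",
)

#: Ranks treated as below the species level even without a species ancestor.
BELOW_SPECIES_RANKS: frozenset[str] = frozenset({"subspecies", "varietas", "forma"})


def filter_banned(tree: Tree, banned: Sequence[str] = BANNED_WORDS) -> Tree:
    """Remove every node whose name contains a banned word, with its subtree.

    A banned internal node takes its whole clade with it: such containers hold
    exactly the material the filter is meant to exclude. Idempotent. Raises
    :class:`~treetiles.errors.FilterError` if the root itself matches.
    """
    def matches(name: str) -> bool:
        return any(w in name for w in banned)

    if matches(tree.root.name):
        raise FilterError("root matched filter")

    keep: set[int] = set()
    for node in tree.preorder():
        if node.parent_id is not None and node.parent_id not in keep:
            continue
        if matches(node.name):
            continue
        keep.add(node.node_id)
    return tree.restricted_to(keep)


def prune_below_species(
    tree: Tree,
    species_rank: str = "species",
    below_ranks: Iterable[str] = BELOW_SPECIES_RANKS,
) -> Tree:
    """Drop everything below the species level; species become leaves.

    A node is removed when any strict ancestor has rank ``species_rank``, or
    when its own rank is in ``below_ranks`` (subspecies-like ranks are below
    species even where the species node itself is absent). A tree with no rank
    annotations is returned unchanged.
    """
    below_ranks = frozenset(below_ranks)
    keep: set[int] = set()
    for node in tree.preorder():
        if node.parent_id is not None and node.parent_id not in keep:
            continue
        parent_rank = (
            tree.nodes[node.parent_id].rank if node.parent_id is not None else ""
        )
        if parent_rank == species_rank:
            continue
        if node.rank in below_ranks and node.node_id != tree.root_id:
            continue
        keep.add(node.node_id)
    return tree.restricted_to(keep)


def autoname_nodes(tree: Tree, sep: str = "+") -> Tree:
    """Name every unnamed internal node from its first two children.

    Tips-to-root traversal: descendants are named before their ancestors, so a
    parent of unnamed children composes the names those children just received
    (e.g. ``A+B``, then ``A+B+C`` one level up). Already-named nodes are left
    untouched; unnamed leaves are an error since they leave nothing to compose.
    """
    unnamed_leaves = [n.node_id for n in tree.leaves() if not n.name]
    if unnamed_leaves:
        raise UnnamedLeafError(unnamed_leaves)
    out = tree.copy()
    for node in out.postorder():
        if node.name:
            continue
        child_names = [out.nodes[c].name for c in node.children]
        node.name = sep.join(child_names[:2])
    return out.rebuild_index()


def annotate_counts(tree: Tree) -> Tree:
    """Refresh ``n_leaves`` and ``depth`` on every node (in place)."""
    return tree.annotate()
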