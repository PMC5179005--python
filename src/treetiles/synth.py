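"""Deterministic synthetic trees for exercising the whole pipeline offline.

Real taxonomies are dominated by polytomies (in the NCBI taxonomy the large
majority of internal nodes are non-binary), so the generator makes
multifurcation-rich trees first-class: with probability ``multifurcation_prob``
a split fans out into 3-6 children instead of 2. Optional knobs leave a
fraction of internal nodes unnamed (exercising auto-naming) and inject
banned filter words into a fraction of names (exercising the cleanup pass).
"""

from __future__ import annotations

import numpy as np

from .treeio import Tree, TreeNode

__all__ = ["random_tree", "fixture_tree"]

_BANNED_POOL = ("unclassified", "environmental", "uncultured", "unidentified")


def random_tree(n_leaves: int, multifurcation_prob: float = 0.5,
                unnamed_fraction: float = 0.0, banned_fraction: float = 0.0,
                seed: int = 0) -> Tree:
    """Generate a random multifurcating tree with exactly ``n_leaves`` leaves.

    Leaf counts are partitioned recursively: each internal node draws its
    child count (2, or uniform on 3..6 with probability
    ``multifurcation_prob``, capped by the leaves available) and splits its
    leaf budget uniformly at random among the children. Same seed, same tree,
    byte for byte.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    for frac, label in ((multifurcation_prob, "multifurcation_prob"),
                        (unnamed_fraction, "unnamed_fraction"),
                        (banned_fraction, "banned_fraction")):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{label} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    nodes: dict[int, TreeNode] = {}
    next_id = 0

    def build(budget: int) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        node = TreeNode(node_id=nid)
        nodes[nid] = node
        if budget == 1:
            return nid
        if budget >= 3 and rng.random() < multifurcation_prob:
            k = min(budget, int(rng.integers(3, 7)))
            multi = True
        else:
            k = 2
            multi = False
        # budget leaves into k positive parts, uniformly
        cuts = np.sort(rng.choice(np.arange(1, budget), size=k - 1,
                                  replace=False))
        parts = np.diff(np.concatenate(([0], cuts, [budget]))).tolist()
        if multi:
            # a part of 2 would force a binary node below a polytomy; turn it
            # into two sibling leaves instead (keeps the tree polytomy-rich)
            expanded = []
            for part in parts:
                if part == 2 and rng.random() < multifurcation_prob:
                    expanded.extend([1, 1])
                else:
                    expanded.append(part)
            parts = expanded
        for part in parts:
            cid = build(int(part))
            nodes[cid].parent_id = nid
            node.children.append(cid)
        return nid

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * n_leaves + 100))
    try:
        root_id = build(n_leaves)
    finally:
        sys.setrecursionlimit(old_limit)

    leaf_idx = internal_idx = 0
    for nid in sorted(nodes):
        node = nodes[nid]
        if node.is_leaf:
            node.name = f"L{leaf_idx}"
            leaf_idx += 1
        else:
            if rng.random() < unnamed_fraction:
                node.name = ""
            else:
                node.name = f"N{internal_idx}"
            internal_idx += 1
    for nid in sorted(nodes):
        node = nodes[nid]
        if node.name and rng.random() < banned_fraction:
            word = _BANNED_POOL[int(rng.integers(len(_BANNED_POOL)))]
            node.name = f"{word} {node.name}"

    return Tree(nodes, root_id)


def fixture_tree() -> Tree:
    """The canonical hand-written test tree (26 nodes, 16 leaves).

    Structure (ids in brackets, rank after the colon where set)::

        [0] cellular organisms
         +- [1] Bacteria : superkingdom
         |   +- [2] environmental samples        <- banned clade: 3 leaves
         |   |   +- [3..5] env sample 1..3         (filter removes ids 2-5,
         |   |                                      leaf count 16 -> 13)
         |   +- [6] Proteobacteria : phylum
         |       +- [7] Escherichia coli : species
         |       |   +- [8] E. coli K-12 : strain      <- below species
         |       |   +- [9] E. coli O157 : strain      <- below species
         |       +- [10] Salmonella enterica : species
         +- [11] Eukaryota : superkingdom
         |   +- [12] ""                           <- unnamed: autonames to
         |   |   +- [13] Homo sapiens : species      "Homo sapiens+Pan
         |   |   |   +- [14] Homo sapiens neanderthalensis : subspecies
         |   |   |   +- [15] Homo sapiens sapiens : subspecies
         |   |   +- [16] Pan troglodytes : species   troglodytes"
         |   +- [17] ""                           <- unnamed: autonames to
         |   |   +- [18] Mus musculus : species      "Mus musculus+Rattus
         |   |   +- [19] Rattus norvegicus : species norvegicus"
         |   +- [20] Primates : order (leaf stand-in)
         +- [21] Archaea : superkingdom
             +- [22] Haloferax : genus
             +- [23] Methanococcus : genus
             +- [24] Sulfolobus : genus
             +- [25] Thermococcus : genus

    Known facts used across the test-suite: 16 leaves before filtering;
    ``filter_banned`` removes exactly nodes {2,3,4,5} (3 leaves);
    ``prune_below_species`` removes exactly {8,9,14,15};
    ``autoname_nodes`` fills exactly nodes 12 and 17.
    """
    spec = [
        # (id, parent, name, rank, common_name)
        (0, None, "cellular organisms", "", ""),
        (1, 0, "Bacteria", "superkingdom", "eubacteria"),
        (2, 1, "environmental samples", "", ""),
        (3, 2, "env sample 1", "", ""),
        (4, 2, "env sample 2", "", ""),
        (5, 2, "env sample 3", "", ""),
        (6, 1, "Proteobacteria", "phylum", ""),
        (7, 6, "Escherichia coli", "species", ""),
        (8, 7, "E. coli K-12", "strain", ""),
        (9, 7, "E. coli O157", "strain", ""),
        (10, 6, "Salmonella enterica", "species", ""),
        (11, 0, "Eukaryota", "superkingdom", "eukaryotes"),
        (12, 11, "", "", ""),
        (13, 12, "Homo sapiens", "species", "human"),
        (14, 13, "Homo sapiens neanderthalensis", "subspecies", ""),
        (15, 13, "Homo sapiens sapiens", "subspecies", ""),
        (16, 12, "Pan troglodytes", "species", "chimpanzee"),
        (17, 11, "", "", ""),
        (18, 17, "Mus musculus", "species", "house mouse"),
        (19, 17, "Rattus norvegicus", "species", "Norway rat"),
        (20, 11, "Primates", "order", ""),
        (21, 0, "Archaea", "superkingdom", "archaea"),
        (22, 21, "Haloferax", "genus", ""),
        (23, 21, "Methanococcus", "genus", ""),
        (24, 21, "Sulfolobus", "genus", ""),
        (25, 21, "Thermococcus", "genus", ""),
    ]
    nodes: dict[int, TreeNode] = {}
    for nid, parent, name, rank, common in spec:
        nodes[nid] = TreeNode(node_id=nid, name=name, rank=rank,
                              common_name=common, parent_id=parent)
    for nid, parent, *_ in spec:
        if parent is not None:
            nodes[parent].children.append(nid)
    return Tree(nodes, 0)
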