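"""Tree queries: most recent common ancestor, routes, and name search.

The route between two taxa climbs from the source to their MRCA and descends
to the destination; its length is depth(a) + depth(b) - 2*depth(mrca) + 1
nodes. The search index joins the tree's names (scientific and common) with
layout coordinates and zoom-of-appearance, so a hit is directly a
"zoom-to-here" instruction.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional

from .layout import Layout
from .treeio import Tree

__all__ = ["PathResult", "SearchHit", "SearchIndex",
           "mrca", "path_between", "full_ancestry", "search_name"]


@dataclass(frozen=True)
class PathResult:
    source_id: int
    dest_id: int
    mrca_id: int
    route: tuple[int, ...]

    def to_dict(self) -> dict:
        return {"source": self.source_id, "destination": self.dest_id,
                "mrca": self.mrca_id, "route": list(self.route)}


@dataclass(frozen=True)
class SearchHit:
    node_id: int
    matched_name: str
    point: tuple[float, float]
    zoom_first: int

    def to_dict(self) -> dict:
        return {"node_id": self.node_id, "name": self.matched_name,
                "point": list(self.point), "zoom_first": self.zoom_first}


def mrca(tree: Tree, a: int, b: int) -> int:
    """Deepest node ancestral to (or equal to) both ``a`` and ``b``."""
    na, nb = tree.node(a), tree.node(b)
    ia, ib = na.node_id, nb.node_id
    da, db = na.depth, nb.depth
    while da > db:
        ia = tree.nodes[ia].parent_id
        da -= 1
    while db > da:
        ib = tree.nodes[ib].parent_id
        db -= 1
    while ia != ib:
        ia = tree.nodes[ia].parent_id
        ib = tree.nodes[ib].parent_id
    return ia


def path_between(tree: Tree, source: int, destination: int) -> PathResult:
    """Route from source up to the MRCA and down to the destination."""
    m = mrca(tree, source, destination)
    up = []
    nid = source
    while nid != m:
        up.append(nid)
        nid = tree.nodes[nid].parent_id
    down = []
    nid = destination
    while nid != m:
        down.append(nid)
        nid = tree.nodes[nid].parent_id
    route = tuple(up + [m] + list(reversed(down)))
    return PathResult(source_id=source, dest_id=destination, mrca_id=m,
                      route=route)


def full_ancestry(tree: Tree, a: int) -> PathResult:
    """Route from a node to the root (``path_between(a, root)``)."""
    return path_between(tree, a, tree.root_id)


class SearchIndex:
    """Name lookup with exact and prefix modes, case-insensitive.

    Built from a tree and (optionally) its layout; hits carry the node's map
    point and the zoom at which its label appears. Homonyms all match.
    """

    def __init__(self, tree: Tree, layout: Optional[Layout] = None):
        self._entries: list[tuple[str, str, int]] = []  # (folded, name, id)
        for node in tree.nodes.values():
            for name in (node.name, node.common_name):
                if name:
                    self._entries.append((name.casefold(), name, node.node_id))
        self._entries.sort()
        self._keys = [e[0] for e in self._entries]
        self._layout = layout

    def _hit(self, name: str, node_id: int) -> SearchHit:
        if self._layout is not None:
            point = self._layout.points.get(node_id, (0.5, 0.5))
            zoom = self._layout.zoom_label.get(node_id, 0)
        else:
            point, zoom = (0.5, 0.5), 0
        return SearchHit(node_id=node_id, matched_name=name, point=point,
                         zoom_first=zoom)

    def search(self, query: str, mode: str = "exact") -> list[SearchHit]:
        if mode not in ("exact", "prefix"):
            raise ValueError(f"unknown search mode {mode!r}")
        q = query.casefold()
        lo = bisect.bisect_left(self._keys, q)
        hits = []
        for folded, name, nid in self._entries[lo:]:
            if mode == "exact" and folded != q:
                break
            if mode == "prefix" and not folded.startswith(q):
                break
            hits.append(self._hit(name, nid))
        hits.sort(key=lambda h: (h.node_id, h.matched_name))
        return hits


def search_name(index: SearchIndex, query: str, mode: str = "exact") -> list[SearchHit]:
    """Functional wrapper over :meth:`SearchIndex.search`."""
    return index.search(query, mode)
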