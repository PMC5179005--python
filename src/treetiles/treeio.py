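"""Trees and their on-disk formats.

The in-memory model is a flat table of :class:`TreeNode` records addressed by
integer id, wrapped in a :class:`Tree` that maintains a name index and the
derived annotations (``n_leaves``, ``depth``) every other module relies on.
Multifurcations are first-class: a node may have any number of children, and
child order is preserved from the input.

Supported formats:

* Newick with single-quoted labels, internal node labels and optional branch
  lengths (lengths are stored but ignored by the layout, which is driven by
  topology and leaf counts only);
* the NCBI taxdump table dialect (``nodes``/``names`` files, pipe-and-tab
  separated), in which case node ids are the taxids.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from .errors import NewickParseError, NodeLookupError, StructuralError

__all__ = [
    "TreeNode",
    "Tree",
    "parse_newick",
    "write_newick",
    "read_taxdump",
]


@dataclass
class TreeNode:
    """One taxon: identity, labels, rank and tree-structural fields."""

    node_id: int
    name: str = ""
    common_name: str = ""
    rank: str = ""
    parent_id: Optional[int] = None
    children: list[int] = field(default_factory=list)
    n_leaves: int = 1
    depth: int = 0
    branch_length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A rooted multifurcating tree over a ``node_id -> TreeNode`` table.

    ``name_index`` maps names (scientific and common) to the *set* of node ids
    carrying them; taxonomic names are not unique, so homonyms coexist.
    """

    def __init__(self, nodes: dict[int, TreeNode], root_id: int):
        if root_id not in nodes:
            raise NodeLookupError(f"root id {root_id} not in node table")
        self.nodes = nodes
        self.root_id = root_id
        self.name_index: dict[str, set[int]] = {}
        self.annotate()
        self.rebuild_index()

    # -- accessors ---------------------------------------------------------

    def node(self, node_id: int) -> TreeNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise NodeLookupError(f"unknown node id {node_id}") from None

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    def children(self, node_id: int) -> list[TreeNode]:
        return [self.nodes[c] for c in self.node(node_id).children]

    def preorder(self, node_id: Optional[int] = None) -> Iterator[TreeNode]:
        """Root-first traversal; children visited in stored order."""
        stack = [self.root_id if node_id is None else node_id]
        while stack:
            node = self.node(stack.pop())
            yield node
            stack.extend(reversed(node.children))

    def postorder(self, node_id: Optional[int] = None) -> Iterator[TreeNode]:
        """Children-first traversal (ancestors after all descendants)."""
        out: list[int] = []
        stack = [self.root_id if node_id is None else node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        for nid in reversed(out):
            yield self.nodes[nid]

    def leaves(self, node_id: Optional[int] = None) -> list[TreeNode]:
        return [n for n in self.preorder(node_id) if n.is_leaf]

    def ancestors(self, node_id: int) -> list[TreeNode]:
        """Strict ancestors from parent up to the root."""
        out = []
        pid = self.node(node_id).parent_id
        while pid is not None:
            node = self.nodes[pid]
            out.append(node)
            pid = node.parent_id
        return out

    def subtree_ids(self, node_id: int) -> set[int]:
        return {n.node_id for n in self.preorder(node_id)}

    def find_by_name(self, name: str) -> set[int]:
        return set(self.name_index.get(name, ()))

    # -- maintenance -------------------------------------------------------

    def annotate(self) -> "Tree":
        """Recompute ``depth`` (root=0) and ``n_leaves`` bottom-up."""
        self.root.depth = 0
        for node in self.preorder():
            for cid in node.children:
                self.nodes[cid].depth = node.depth + 1
        for node in self.postorder():
            if node.is_leaf:
                node.n_leaves = 1
            else:
                node.n_leaves = sum(self.nodes[c].n_leaves for c in node.children)
        return self

    def rebuild_index(self) -> "Tree":
        index: dict[str, set[int]] = {}
        for node in self.nodes.values():
            for name in (node.name, node.common_name):
                if name:
                    index.setdefault(name, set()).add(node.node_id)
        self.name_index = index
        return self

    def copy(self) -> "Tree":
        nodes = {
            nid: TreeNode(
                node_id=n.node_id,
                name=n.name,
                common_name=n.common_name,
                rank=n.rank,
                parent_id=n.parent_id,
                children=list(n.children),
                n_leaves=n.n_leaves,
                depth=n.depth,
                branch_length=n.branch_length,
            )
            for nid, n in self.nodes.items()
        }
        return Tree(nodes, self.root_id)

    def restricted_to(self, keep: Iterable[int]) -> "Tree":
        """New tree over ``keep`` (must be closed under taking parents)."""
        keep = set(keep)
        if self.root_id not in keep:
            raise StructuralError("kept set does not contain the root")
        nodes = {}
        for nid in keep:
            n = self.nodes[nid]
            if n.parent_id is not None and n.parent_id not in keep:
                raise StructuralError("kept set not ancestor-closed", [nid])
            nodes[nid] = TreeNode(
                node_id=n.node_id,
                name=n.name,
                common_name=n.common_name,
                rank=n.rank,
                parent_id=n.parent_id,
                children=[c for c in n.children if c in keep],
                branch_length=n.branch_length,
            )
        return Tree(nodes, self.root_id)


# -- Newick ---------------------------------------------------------------

_SPECIALS = "(),:;"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Accepts multifurcations, internal labels, single-quoted labels (with the
    doubled-quote escape) and branch lengths. Raises
    :class:`~treetiles.errors.NewickParseError` with the offending character
    offset on malformed input.
    """
    s = text
    n = len(s)

    def skip_ws(i: int) -> int:
        while i < n and s[i].isspace():
            i += 1
        return i

    def parse_label(i: int) -> tuple[str, Optional[float], int]:
        i = skip_ws(i)
        if i < n and s[i] == "'":
            buf = []
            j = i + 1
            while True:
                if j >= n:
                    raise NewickParseError("unterminated quoted label", i)
                if s[j] == "'":
                    if j + 1 < n and s[j + 1] == "'":
                        buf.append("'")
                        j += 2
                    else:
                        j += 1
                        break
                else:
                    buf.append(s[j])
                    j += 1
            name, i = "".join(buf), j
        else:
            j = i
            while j < n and s[j] not in _SPECIALS:
                j += 1
            name, i = s[i:j].strip(), j
        blen = None
        i = skip_ws(i)
        if i < n and s[i] == ":":
            j = i + 1
            k = j
            while k < n and (s[k].isdigit() or s[k] in "+-.eE"):
                k += 1
            try:
                blen = float(s[j:k])
            except ValueError:
                raise NewickParseError("invalid branch length", j) from None
            i = k
        return name, blen, i

    nodes: dict[int, TreeNode] = {}
    next_id = 0

    def make(name: str, blen: Optional[float], children: list[TreeNode]) -> TreeNode:
        nonlocal next_id
        node = TreeNode(node_id=next_id, name=name, branch_length=blen)
        for ch in children:
            ch.parent_id = node.node_id
            node.children.append(ch.node_id)
        nodes[next_id] = node
        next_id += 1
        return node

    i = skip_ws(0)
    if i >= n:
        raise NewickParseError("empty input", 0)

    stack: list[list[TreeNode]] = []
    while True:
        i = skip_ws(i)
        if i < n and s[i] == "(":
            stack.append([])
            i += 1
            continue
        name, blen, i = parse_label(i)
        node = make(name, blen, [])
        # absorb separators and closing parentheses around the finished node
        while True:
            i = skip_ws(i)
            if i >= n:
                raise NewickParseError("missing ';' terminator", n)
            c = s[i]
            if c == ",":
                if not stack:
                    raise NewickParseError("',' outside parentheses", i)
                stack[-1].append(node)
                i += 1
                break
            if c == ")":
                if not stack:
                    raise NewickParseError("unbalanced ')'", i)
                stack[-1].append(node)
                children = stack.pop()
                i += 1
                name, blen, i = parse_label(i)
                node = make(name, blen, children)
                continue
            if c == ";":
                if stack:
                    raise NewickParseError("unbalanced '(': missing ')'", i)
                i = skip_ws(i + 1)
                if i < n:
                    raise NewickParseError("trailing characters after ';'", i)
                return Tree(nodes, node.node_id)
            raise NewickParseError(f"unexpected character {c!r}", i)


def _quote_if_needed(name: str) -> str:
    if name and not any(c in name for c in "(),:; '"):
        return name
    if not name:
        return name
    return "'" + name.replace("'", "''") + "'"


def write_newick(tree: Tree, node_id: Optional[int] = None,
                 branch_lengths: bool = True) -> str:
    """Serialize the subtree rooted at ``node_id`` (default: root) to Newick.

    Names containing Newick metacharacters or spaces are single-quoted.
    """
    if node_id is None:
        node_id = tree.root_id
    root = tree.node(node_id)
    parts: dict[int, str] = {}
    for node in tree.postorder(root.node_id):
        label = _quote_if_needed(node.name)
        if branch_lengths and node.branch_length is not None and node.node_id != node_id:
            label += f":{node.branch_length:g}"
        if node.is_leaf:
            parts[node.node_id] = label
        else:
            inner = ",".join(parts.pop(c) for c in node.children)
            parts[node.node_id] = f"({inner}){label}"
    return parts[root.node_id] + ";"


# -- NCBI taxdump dialect --------------------------------------------------

PathOrFile = Union[str, "io.TextIOBase"]


def _dmp_rows(source: PathOrFile) -> Iterator[list[str]]:
    if isinstance(source, (str, bytes)):
        fh = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[:-2]
            yield [f.strip() for f in line.split("\t|\t")]
    finally:
        if close:
            fh.close()


def read_taxdump(nodes_table: PathOrFile, names_table: PathOrFile) -> Tree:
    """Build a :class:`Tree` from NCBI-style ``nodes``/``names`` tables.

    ``nodes`` rows carry (taxid, parent taxid, rank, ...); ``names`` rows carry
    (taxid, name, unique name, name class). The root is the row whose parent is
    itself. Scientific names populate ``name``; the "common name" classes
    populate ``common_name``. Orphan parents, multiple roots and parent-chain
    cycles raise :class:`~treetiles.errors.StructuralError`.
    """
    nodes: dict[int, TreeNode] = {}
    parents: dict[int, int] = {}
    roots: list[int] = []
    for row in _dmp_rows(nodes_table):
        if len(row) < 3:
            raise StructuralError("nodes row needs taxid, parent, rank", row[:1])
        taxid, parent, rank = int(row[0]), int(row[1]), row[2]
        nodes[taxid] = TreeNode(node_id=taxid, rank=rank)
        if taxid == parent:
            roots.append(taxid)
        else:
            parents[taxid] = parent

    if not roots:
        # no self-parented row: a cycle or an orphan chain must exist
        raise StructuralError("no root row (taxid == parent taxid)",
                              sorted(nodes))
    if len(roots) > 1:
        raise StructuralError("multiple roots", roots)
    root_id = roots[0]

    orphans = sorted(t for t, p in parents.items() if p not in nodes)
    if orphans:
        raise StructuralError("parent taxid absent from table", orphans)

    for taxid, parent in parents.items():
        nodes[taxid].parent_id = parent
        nodes[parent].children.append(taxid)

    # reachability from the root exposes cycles
    reached = {root_id}
    stack = [root_id]
    while stack:
        for cid in nodes[stack.pop()].children:
            if cid not in reached:
                reached.add(cid)
                stack.append(cid)
    stranded = sorted(set(nodes) - reached)
    if stranded:
        raise StructuralError("cyclic parent chain", stranded)

    for row in _dmp_rows(names_table):
        if len(row) < 2:
            continue
        taxid = int(row[0])
        if taxid not in nodes:
            continue
        name, name_class = row[1], row[3] if len(row) > 3 else "scientific name"
        if name_class == "scientific name":
            nodes[taxid].name = name
        elif name_class in ("common name", "genbank common name"):
            if not nodes[taxid].common_name:
                nodes[taxid].common_name = name

    return Tree(nodes, root_id)
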