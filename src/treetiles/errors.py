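"""Exception hierarchy shared across the package."""


class TreetilesError(Exception):
    """Base class for all package errors."""


class NewickParseError(TreetilesError):
    """Malformed Newick input.

    Carries ``offset``, the 0-based character position where parsing failed.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character offset {offset})")
        self.offset = offset


class NodeLookupError(TreetilesError, KeyError):
    """A node id or name does not resolve in the tree."""


class StructuralError(TreetilesError):
    """The node table does not describe a single rooted tree.

    ``taxids`` lists the offending identifiers.
    """

    def __init__(self, message: str, taxids=()):
        self.taxids = list(taxids)
        suffix = f": {self.taxids}" if self.taxids else ""
        super().__init__(message + suffix)


class FilterError(TreetilesError):
    """A preparation filter would produce an empty or invalid tree."""


class GeometryError(TreetilesError):
    """Layout recursion produced degenerate geometry (non-positive radius)."""


class UnnamedLeafError(TreetilesError):
    """Auto-naming requires every leaf to carry a name.

    ``node_ids`` lists the unnamed leaves.
    """

    def __init__(self, node_ids):
        self.node_ids = sorted(node_ids)
        super().__init__(f"unnamed leaves: {self.node_ids}")
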