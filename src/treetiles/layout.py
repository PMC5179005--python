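"""Recursive half-circle layout for multifurcating trees.

Every clade occupies a half-disc nested inside its parent's. The angular share
of a child among its siblings follows the leaf-count rule: with counts
``n_1..n_k`` and parent aperture ``T`` degrees, child ``i`` receives
``T * w_i / sum(w)`` where ``w_i = n_i`` (linear mode) or ``sqrt(n_i)`` (the
default: the square root damps the size contrast between species-poor and
species-rich clades). For the two-child case in linear mode this is the
classic ``alpha = 180 * n_A / (n_A + n_B)``.

The root is a full 360-degree disc centred at (0.5, 0.5) with radius 0.45 in
the unit-square world; optionally its children get equal spans regardless of
counts (the tree-of-life convention of giving the superkingdoms the same
size). Every other internal node is a half-disc with a 180-degree aperture
facing away from its parent.

Sibling sectors are a seeded random permutation of child order, so a given
(tree, seed) pair always yields the identical map. Child ``i``'s half-disc is
centred at distance ``rho * R`` from the parent centre along its sector
bisector with radius

    r_i = (1 - padding) * min(R * (1 - rho), rho * R * sin(span_i / 2)),

which keeps it inside both the parent's rim and its own sector wedge; nesting
therefore guarantees containment, sibling disjointness, and straight
parent-to-child branches that never cross.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError, TreetilesError
from .treeio import Tree

__all__ = [
    "HalfCircle",
    "LayoutConfig",
    "Layout",
    "allocate_angles",
    "place_children",
    "layout_tree",
    "assign_zoom_levels",
    "compute_labels",
]

Point = tuple[float, float]

#: Pixel width of the world at zoom z: 256 * 2**(z+1) (a 2x2 tile grid at z=0).
TILE_SIZE = 256


def pixels_per_world(z: int) -> float:
    return TILE_SIZE * 2.0 ** (z + 1)


@dataclass(frozen=True)
class HalfCircle:
    """A clade's geometric footprint.

    ``heading`` (degrees) points from the flat side into the disc along the
    axis of symmetry; ``span`` is the angular share the clade received inside
    its parent. The root's full disc is the one exception, with span 360.
    """

    center: Point
    radius: float
    heading: float
    span: float

    def heading_vector(self) -> Point:
        a = math.radians(self.heading)
        return (math.cos(a), math.sin(a))

    def arc_points(self, n_segments: int = 64, radius_frac: float = 1.0,
                   full: bool = False) -> list[Point]:
        """Polyline along the rim, from heading-90 to heading+90 (or 0..360)."""
        cx, cy = self.center
        r = self.radius * radius_frac
        if full:
            angles = np.linspace(0.0, 360.0, n_segments + 1)
        else:
            angles = np.linspace(self.heading - 90.0, self.heading + 90.0,
                                 n_segments + 1)
        rad = np.radians(angles)
        return [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in rad]


@dataclass(frozen=True)
class LayoutConfig:
    """Tunables of the layout recursion.

    transform
        ``"sqrt"`` (default) or ``"linear"`` weighting of leaf counts.
    equalize_root
        Give the root's children equal spans regardless of counts.
    radial_fraction
        rho: distance of a child centre from its parent centre, as a fraction
        of the parent radius.
    padding
        Shrink factor applied to every child radius, leaving visual breathing
        room between sibling half-discs.
    label_min_px / shape_min_px
        Minimum on-screen radius (pixels) before a label / shape is drawn;
        they set each element's zoom-of-appearance.
    """

    transform: str = "sqrt"
    equalize_root: bool = True
    seed: int = 0
    radial_fraction: float = 0.5
    padding: float = 0.1
    label_min_px: int = 64
    shape_min_px: int = 2

    def __post_init__(self):
        if self.transform not in ("sqrt", "linear"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not 0.0 < self.radial_fraction < 1.0:
            raise ValueError("radial_fraction must be in (0,1)")
        if not 0.0 <= self.padding < 0.5:
            raise ValueError("padding must be in [0,0.5)")


@dataclass
class Layout:
    """Complete geometry for one tree under one config."""

    points: dict[int, Point] = field(default_factory=dict)
    half_circles: dict[int, HalfCircle] = field(default_factory=dict)
    root_disc: Optional[HalfCircle] = None
    #: nominal radius per node (leaves too): drives zoom-of-appearance
    slot_radius: dict[int, float] = field(default_factory=dict)
    #: angular share (degrees) each node received inside its parent
    spans: dict[int, float] = field(default_factory=dict)
    label_anchors: dict[int, Point] = field(default_factory=dict)
    rank_arcs: dict[int, list[Point]] = field(default_factory=dict)
    zoom_shape: dict[int, int] = field(default_factory=dict)
    zoom_label: dict[int, int] = field(default_factory=dict)
    #: (parent_id, child_id, parent point, child point)
    branches: list[tuple[int, int, Point, Point]] = field(default_factory=list)
    extent: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)
    names: dict[int, str] = field(default_factory=dict)
    root_id: int = 0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        hc = lambda h: {"center": list(h.center), "radius": h.radius,
                        "heading": h.heading, "span": h.span}
        return {
            "root_id": self.root_id,
            "extent": list(self.extent),
            "points": {str(k): list(v) for k, v in self.points.items()},
            "half_circles": {str(k): hc(v) for k, v in self.half_circles.items()},
            "root_disc": hc(self.root_disc) if self.root_disc else None,
            "slot_radius": {str(k): v for k, v in self.slot_radius.items()},
            "spans": {str(k): v for k, v in self.spans.items()},
            "label_anchors": {str(k): list(v) for k, v in self.label_anchors.items()},
            "rank_arcs": {str(k): [list(p) for p in v]
                          for k, v in self.rank_arcs.items()},
            "zoom_shape": {str(k): v for k, v in self.zoom_shape.items()},
            "zoom_label": {str(k): v for k, v in self.zoom_label.items()},
            "branches": [[p, c, list(a), list(b)] for p, c, a, b in self.branches],
            "names": {str(k): v for k, v in self.names.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict) -> "Layout":
        hc = lambda h: HalfCircle(center=tuple(h["center"]), radius=h["radius"],
                                  heading=h["heading"], span=h["span"])
        return cls(
            points={int(k): tuple(v) for k, v in d["points"].items()},
            half_circles={int(k): hc(v) for k, v in d["half_circles"].items()},
            root_disc=hc(d["root_disc"]) if d.get("root_disc") else None,
            slot_radius={int(k): v for k, v in d["slot_radius"].items()},
            spans={int(k): v for k, v in d.get("spans", {}).items()},
            label_anchors={int(k): tuple(v) for k, v in d["label_anchors"].items()},
            rank_arcs={int(k): [tuple(p) for p in v]
                       for k, v in d["rank_arcs"].items()},
            zoom_shape={int(k): v for k, v in d["zoom_shape"].items()},
            zoom_label={int(k): v for k, v in d["zoom_label"].items()},
            branches=[(p, c, tuple(a), tuple(b)) for p, c, a, b in d["branches"]],
            extent=tuple(d["extent"]),
            names={int(k): v for k, v in d.get("names", {}).items()},
            root_id=d["root_id"],
        )

    @classmethod
    def from_json(cls, text: str) -> "Layout":
        return cls.from_dict(json.loads(text))

    def to_geojson(self) -> dict:
        """Half-circles as 64-segment polygons, branches as lines."""
        features = []
        items = list(self.half_circles.items())
        if self.root_disc is not None:
            items.append((self.root_id, self.root_disc))
        for nid, h in items:
            ring = h.arc_points(64, full=(h.span >= 360.0))
            if h.span < 360.0:
                ring.append(ring[0])
            features.append({
                "type": "Feature",
                "properties": {"node_id": nid, "kind": "half_circle",
                               "name": self.names.get(nid, ""),
                               "zoom_first": self.zoom_shape.get(nid, 0)},
                "geometry": {"type": "Polygon",
                             "coordinates": [[list(p) for p in ring]]},
            })
        for pid, cid, a, b in self.branches:
            features.append({
                "type": "Feature",
                "properties": {"parent": pid, "child": cid, "kind": "branch"},
                "geometry": {"type": "LineString",
                             "coordinates": [list(a), list(b)]},
            })
        return {"type": "FeatureCollection", "features": features}


# -- angle allocation ------------------------------------------------------

def allocate_angles(counts: Sequence[float], transform: str = "sqrt",
                    total_span: float = 180.0) -> list[float]:
    """Split ``total_span`` degrees among clades proportionally to weights.

    Weights are the counts (linear) or their square roots (sqrt). The result
    preserves order and sums to ``total_span`` exactly (last span takes the
    rounding slack, well below 1e-9 degrees).
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(c <= 0 for c in counts):
        raise ValueError("counts must be positive")
    if not 0.0 < total_span <= 360.0:
        raise ValueError("total_span must be in (0, 360]")
    if transform == "sqrt":
        w = [math.sqrt(c) for c in counts]
    elif transform == "linear":
        w = [float(c) for c in counts]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    total_w = sum(w)
    spans = [total_span * wi / total_w for wi in w]
    spans[-1] += total_span - sum(spans)
    return spans


def _child_seed(seed: int, node_id: int) -> int:
    # stable per-node stream; numpy seeds must stay below 2**31
    return (seed * 1_000_003 + node_id * 7919 + 17) % (2**31 - 1)


def place_children(parent: HalfCircle, spans: Sequence[float], seed: int,
                   radial_fraction: float = 0.5, padding: float = 0.1,
                   aperture: Optional[float] = None,
                   node_name: str = "?") -> list[HalfCircle]:
    """Place child half-circles into consecutive sectors of the parent.

    Sector order is a seeded random permutation of the input (the "randomly
    distributed within their parental half-circle" rule, made reproducible).
    Returned list is aligned with ``spans``. ``aperture`` defaults to the
    parent's span capped at 180 (the half-disc case); pass 360 for the root
    disc. Raises :class:`~treetiles.errors.GeometryError` on a non-positive
    child radius.
    """
    if aperture is None:
        aperture = min(parent.span, 180.0)
    total = sum(spans)
    if total > aperture + 1e-6:
        raise GeometryError(
            f"child spans {total:.6f} exceed aperture {aperture:.6f} at {node_name}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(spans))

    R = parent.radius
    rho = radial_fraction
    start = parent.heading - aperture / 2.0
    # sector boundaries in permuted drawing order
    sector_bisector = [0.0] * len(spans)
    acc = start
    for idx in order:
        sector_bisector[idx] = acc + spans[idx] / 2.0
        acc += spans[idx]

    out: list[HalfCircle] = []
    cx, cy = parent.center
    for i, span in enumerate(spans):
        bis = sector_bisector[i] % 360.0
        a = math.radians(bis)
        center = (cx + rho * R * math.cos(a), cy + rho * R * math.sin(a))
        half = math.radians(min(span, 180.0) / 2.0)
        r = (1.0 - padding) * min(R * (1.0 - rho), rho * R * math.sin(half))
        if r <= 0.0:
            raise GeometryError(f"degenerate child radius at {node_name}")
        out.append(HalfCircle(center=center, radius=r, heading=bis, span=span))
    return out


# -- full-tree recursion ---------------------------------------------------

def layout_tree(tree: Tree, config: Optional[LayoutConfig] = None) -> Layout:
    """Lay out a prepared tree (named, counted) in the unit square.

    Internal nodes get half-circles; every node gets an attachment point (the
    flat-side midpoint of its half-disc, i.e. its centre); leaves get points
    only. Branches are straight parent-point to child-point segments. Label
    anchors and zoom levels are filled in by :func:`compute_labels` and
    :func:`assign_zoom_levels`, which this function calls.
    """
    if config is None:
        config = LayoutConfig()
    if len(tree) == 0:
        raise TreetilesError("empty tree")
    tree.annotate()

    lay = Layout(root_id=tree.root_id)
    lay.names = {n.node_id: n.name for n in tree.nodes.values()}

    root_disc = HalfCircle(center=(0.5, 0.5), radius=0.45, heading=90.0,
                           span=360.0)
    lay.root_disc = root_disc
    lay.points[tree.root_id] = root_disc.center
    lay.slot_radius[tree.root_id] = root_disc.radius
    lay.spans[tree.root_id] = 360.0

    stack: list[tuple[int, HalfCircle, float]] = [
        (tree.root_id, root_disc, 360.0)]
    while stack:
        nid, shape, aperture = stack.pop()
        node = tree.node(nid)
        if node.is_leaf:
            continue
        counts = [tree.nodes[c].n_leaves for c in node.children]
        if nid == tree.root_id and config.equalize_root:
            spans = [aperture / len(counts)] * len(counts)
        else:
            spans = allocate_angles(counts, config.transform, aperture)
        placed = place_children(
            shape, spans, _child_seed(config.seed, nid),
            config.radial_fraction, config.padding, aperture=aperture,
            node_name=node.name or str(nid))
        for cid, child_shape in zip(node.children, placed):
            child = tree.nodes[cid]
            lay.points[cid] = child_shape.center
            lay.slot_radius[cid] = child_shape.radius
            lay.spans[cid] = child_shape.span
            lay.branches.append((nid, cid, lay.points[nid], child_shape.center))
            if not child.is_leaf:
                lay.half_circles[cid] = child_shape
                stack.append((cid, child_shape, 180.0))

    assign_zoom_levels(lay, config)
    compute_labels(lay)
    return lay


def _zoom_first(radius_world: float, min_px: float) -> int:
    """Smallest z with radius_world * 256 * 2**(z+1) >= min_px."""
    if radius_world <= 0.0:
        return 0
    z = 0
    while radius_world * pixels_per_world(z) < min_px:
        z += 1
        if z > 64:
            break
    return z


def assign_zoom_levels(layout: Layout, config: Optional[LayoutConfig] = None) -> Layout:
    """Set each node's zoom-of-appearance for its shape and its label.

    An element first appears at the smallest zoom where its world radius maps
    to at least ``shape_min_px`` (or ``label_min_px``) pixels. Children are
    clamped to appear no earlier than their parents, though the strictly
    shrinking radii make that automatic.
    """
    if config is None:
        config = LayoutConfig()
    for nid, r in layout.slot_radius.items():
        layout.zoom_shape[nid] = _zoom_first(r, config.shape_min_px)
        layout.zoom_label[nid] = _zoom_first(r, config.label_min_px)
    # enforce child >= parent monotonicity along branches
    for pid, cid, _, _ in layout.branches:
        layout.zoom_shape[cid] = max(layout.zoom_shape[cid], layout.zoom_shape[pid])
        layout.zoom_label[cid] = max(layout.zoom_label[cid], layout.zoom_label[pid])
    return layout


def compute_labels(layout: Layout) -> Layout:
    """Anchor clade names at half-disc centroids; rank arcs hug the rim.

    The centroid of a half-disc of radius r sits 4r/(3*pi) from the flat-side
    midpoint along the heading. The rank-name path is the arc at 0.95 r from
    heading-90 to heading+90, for text that follows the rim.
    """
    items = list(layout.half_circles.items())
    if layout.root_disc is not None:
        items.append((layout.root_id, layout.root_disc))
    for nid, h in items:
        if h.span >= 360.0:
            layout.label_anchors[nid] = h.center
            layout.rank_arcs[nid] = h.arc_points(64, radius_frac=0.95, full=True)
            continue
        dx, dy = h.heading_vector()
        off = 4.0 * h.radius / (3.0 * math.pi)
        layout.label_anchors[nid] = (h.center[0] + off * dx,
                                     h.center[1] + off * dy)
        layout.rank_arcs[nid] = h.arc_points(64, radius_frac=0.95)
    # leaves: label at their point
    for nid, p in layout.points.items():
        layout.label_anchors.setdefault(nid, p)
    return layout
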