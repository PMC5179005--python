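"""Slippy-map tile pyramid over a layout.

Zoom level z is a 2**(z+1) x 2**(z+1) grid of 256x256 px tiles covering the
unit-square world, so level 0 is the four tiles on which the whole map fits
and level z holds 4**(z+1) addresses. Each tile has exactly four children at
the next zoom (dyadic subdivision). Tiles whose region contains no drawable
geometry render as uniform background and are never written to disk — with
deep pyramids the overwhelming majority of addresses are such blanks, which
is what makes on-demand rendering tractable at all.

Rendering is vector-clipped: every arc, chord and branch is a polyline in
world coordinates, clipped (via shapely) to the tile's bbox and drawn with
Pillow. Identical layout + style always produce byte-identical PNGs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterator, Optional

from PIL import Image, ImageDraw
from shapely.geometry import LineString, Point, box
from shapely.strtree import STRtree

from .layout import Layout, pixels_per_world

__all__ = [
    "TileAddress",
    "TileImage",
    "Style",
    "tiles_at_level",
    "children_of",
    "parent_of",
    "world_to_pixel",
    "render_tile",
    "render_pyramid",
]

TILE_PX = 256


@dataclass(frozen=True, order=True)
class TileAddress:
    z: int
    x: int
    y: int

    def __post_init__(self):
        n = 2 ** (self.z + 1)
        if self.z < 0 or not (0 <= self.x < n and 0 <= self.y < n):
            raise ValueError(f"invalid tile address z={self.z} x={self.x} y={self.y}")

    def world_bbox(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) in world coordinates, y down."""
        n = 2 ** (self.z + 1)
        return (self.x / n, self.y / n, (self.x + 1) / n, (self.y + 1) / n)


@dataclass
class TileImage:
    address: TileAddress
    image: Image.Image
    blank: bool

    def png_bytes(self) -> bytes:
        import io
        buf = io.BytesIO()
        self.image.save(buf, format="PNG")
        return buf.getvalue()


def tiles_at_level(z: int) -> int:
    """Number of tile addresses at zoom z: 4**(z+1) (4, 16, 64, ...)."""
    if z < 0:
        raise ValueError("zoom level must be non-negative")
    return 4 ** (z + 1)


def children_of(addr: TileAddress) -> list[TileAddress]:
    """The four tiles at z+1 that subdivide this one."""
    return [TileAddress(addr.z + 1, 2 * addr.x + i, 2 * addr.y + j)
            for j in (0, 1) for i in (0, 1)]


def parent_of(addr: TileAddress) -> TileAddress:
    if addr.z == 0:
        raise ValueError("level-0 tiles have no parent")
    return TileAddress(addr.z - 1, addr.x // 2, addr.y // 2)


def world_to_pixel(p: tuple[float, float], z: int) -> tuple[TileAddress, tuple[int, int]]:
    """Map a world point to (tile, in-tile pixel) at zoom z; y axis down."""
    x, y = p
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError(f"point {p} outside unit square")
    size = int(pixels_per_world(z))
    gx = min(int(x * size), size - 1)
    gy = min(int(y * size), size - 1)
    return (TileAddress(z, gx // TILE_PX, gy // TILE_PX),
            (gx % TILE_PX, gy % TILE_PX))


@dataclass(frozen=True)
class Style:
    """Colours and stroke widths; flat key=value file round-trip."""

    background: str = "#000000"
    halfcircle_color: str = "#4f7f9f"
    branch_color: str = "#c8b273"
    label_color: str = "#e8e8e8"
    stroke_width: int = 1
    draw_labels: bool = True

    @classmethod
    def from_file(cls, path: str) -> "Style":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                kv[k.strip()] = v.strip()
        kwargs = {}
        for f in ("background", "halfcircle_color", "branch_color", "label_color"):
            if f in kv:
                kwargs[f] = kv[f]
        if "stroke_width" in kv:
            kwargs["stroke_width"] = int(kv["stroke_width"])
        if "draw_labels" in kv:
            kwargs["draw_labels"] = kv["draw_labels"].lower() in ("1", "true", "yes")
        return cls(**kwargs)


class _SceneIndex:
    """Per-layout cache of clippable world geometries with zoom thresholds."""

    def __init__(self, layout: Layout):
        self.layout = layout
        geoms = []
        meta = []  # (zoom_first, kind, node_id)
        items = list(layout.half_circles.items())
        if layout.root_disc is not None:
            items.append((layout.root_id, layout.root_disc))
        for nid, h in items:
            pts = h.arc_points(64, full=(h.span >= 360.0))
            if h.span < 360.0:
                pts.append(pts[0])  # close with the flat chord
            geoms.append(LineString(pts))
            meta.append((layout.zoom_shape.get(nid, 0), "shape", nid))
        for pid, cid, a, b in layout.branches:
            if a == b:
                continue
            geoms.append(LineString([a, b]))
            meta.append((layout.zoom_shape.get(cid, 0), "branch", cid))
        if layout.label_anchors:
            for nid, h in items:
                anchor = layout.label_anchors.get(nid)
                if anchor is None:
                    continue
                geoms.append(Point(anchor))
                meta.append((layout.zoom_label.get(nid, 0), "label", nid))
        self.geoms = geoms
        self.meta = meta
        self.tree = STRtree(geoms) if geoms else None

    def query(self, bbox, z: Optional[int] = None) -> Iterator[int]:
        """Indices of geometries intersecting bbox (visible at z, if given)."""
        if self.tree is None:
            return
        region = box(*bbox)
        for i in self.tree.query(region):
            i = int(i)
            if z is not None and self.meta[i][0] > z:
                continue
            if self.geoms[i].intersects(region):
                yield i


def _scene(layout: Layout) -> _SceneIndex:
    idx = getattr(layout, "_scene_index", None)
    if idx is None:
        idx = _SceneIndex(layout)
        layout._scene_index = idx
    return idx


def _draw_clipped(draw: ImageDraw.ImageDraw, geom, bbox, scale, color, width):
    x0, y0 = bbox[0], bbox[1]
    clipped = geom.intersection(box(x0 - 2 / scale, y0 - 2 / scale,
                                    bbox[2] + 2 / scale, bbox[3] + 2 / scale))
    if clipped.is_empty:
        return False
    parts = getattr(clipped, "geoms", [clipped])
    drew = False
    for part in parts:
        coords = list(getattr(part, "coords", []))
        if len(coords) < 2:
            continue
        pix = [((px - x0) * scale, (py - y0) * scale) for px, py in coords]
        draw.line(pix, fill=color, width=width)
        drew = True
    return drew


def render_tile(layout: Layout, addr: TileAddress,
                style: Optional[Style] = None) -> TileImage:
    """Rasterize one tile; ``blank`` is set when nothing was drawn."""
    if style is None:
        style = Style()
    bbox = addr.world_bbox()
    scale = pixels_per_world(addr.z)
    img = Image.new("RGB", (TILE_PX, TILE_PX), style.background)
    draw = ImageDraw.Draw(img)
    scene = _scene(layout)
    drew = False
    labels: list[int] = []
    for i in scene.query(bbox, z=addr.z):
        zoom_first, kind, nid = scene.meta[i]
        if kind == "shape":
            drew |= _draw_clipped(draw, scene.geoms[i], bbox, scale,
                                  style.halfcircle_color, style.stroke_width)
        elif kind == "branch":
            drew |= _draw_clipped(draw, scene.geoms[i], bbox, scale,
                                  style.branch_color, style.stroke_width)
        elif kind == "label":
            labels.append(nid)
    if style.draw_labels:
        x0, y0 = bbox[0], bbox[1]
        for nid in sorted(labels):
            name = layout.names.get(nid, "")
            if not name:
                continue
            ax, ay = layout.label_anchors[nid]
            px, py = (ax - x0) * scale, (ay - y0) * scale
            if -128 <= px <= TILE_PX + 128 and -16 <= py <= TILE_PX + 16:
                draw.text((px, py), name, fill=style.label_color, anchor="mm")
                drew = True
    return TileImage(address=addr, image=img, blank=not drew)


def render_pyramid(layout: Layout, z_max: int, cache_dir: str,
                   style: Optional[Style] = None) -> list[TileAddress]:
    """Render the pyramid down to ``z_max`` into ``cache_dir``.

    Breadth-first from the four level-0 tiles, descending only where some
    geometry (at any zoom-of-appearance) intersects the tile region; tiles
    that render blank are never written. Existing files are left untouched, so
    a warm rerun is a no-op. Returns the sorted manifest of non-blank
    addresses, also written to ``cache_dir/manifest.json``.
    """
    if style is None:
        style = Style()
    scene = _scene(layout)
    manifest: list[TileAddress] = []
    frontier = [TileAddress(0, x, y) for x in range(2) for y in range(2)]
    while frontier:
        next_frontier: list[TileAddress] = []
        for addr in frontier:
            hits = list(scene.query(addr.world_bbox()))
            if not hits:
                continue  # nothing here at any zoom: whole subtree is blank
            tile = render_tile(layout, addr, style)
            if not tile.blank:
                manifest.append(addr)
                path = os.path.join(cache_dir, str(addr.z), str(addr.x),
                                    f"{addr.y}.png")
                if not os.path.exists(path):
                    os.makedirs(os.path.dirname(path), exist_ok=True)
                    tile.image.save(path, format="PNG")
            if addr.z < z_max:
                next_frontier.extend(children_of(addr))
        frontier = next_frontier
    manifest.sort()
    os.makedirs(cache_dir, exist_ok=True)
    with open(os.path.join(cache_dir, "manifest.json"), "w") as fh:
        json.dump([[a.z, a.x, a.y] for a in manifest], fh)
    return manifest
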