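"""Half-circle layout: angle allocation, placement geometry, invariants."""

import math

import numpy as np
import pytest

import treetiles as tt
from treetiles.errors import GeometryError
from treetiles.layout import HalfCircle, _zoom_first, pixels_per_world

from conftest import in_half_disc, sample_half_disc, segments_cross


class TestAllocateAngles:
    def test_symmetric_linear(self):
        assert tt.allocate_angles([50, 50], "linear", 180) == [90.0, 90.0]

    def test_linear_formula(self):
        spans = tt.allocate_angles([100, 300], "linear", 180)
        assert spans == pytest.approx([45.0, 135.0], abs=1e-12)

    def test_sqrt_weights(self):
        # w = (1, 10): spans 180/11 and 1800/11
        spans = tt.allocate_angles([1, 100], "sqrt", 180)
        assert spans == pytest.approx([180 / 11, 1800 / 11], abs=1e-12)

    def test_sum_is_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(1, 10**6, size=rng.integers(2, 9)).tolist()
            for transform in ("linear", "sqrt"):
                spans = tt.allocate_angles(counts, transform, 180)
                assert abs(sum(spans) - 180) < 1e-9
                assert len(spans) == len(counts)

    def test_monotone_in_counts_sqrt(self):
        spans = tt.allocate_angles([5, 500, 50], "sqrt", 180)
        assert spans[1] > spans[2] > spans[0]

    @pytest.mark.parametrize("counts,err", [([], ValueError),
                                            ([0, 3], ValueError),
                                            ([-1, 3], ValueError)])
    def test_invalid_counts(self, counts, err):
        with pytest.raises(err):
            tt.allocate_angles(counts, "linear", 180)


class TestPlaceChildren:
    parent = HalfCircle(center=(0.5, 0.5), radius=0.4, heading=90.0, span=180.0)

    def test_single_child_closed_form(self):
        (child,) = tt.place_children(self.parent, [180.0], seed=0,
                                     radial_fraction=0.5, padding=0.1)
        R, rho = self.parent.radius, 0.5
        assert child.center == pytest.approx((0.5, 0.5 + rho * R))
        assert child.radius == pytest.approx(0.9 * R * min(1 - rho, rho))
        assert child.heading == pytest.approx(90.0)

    def test_determinism(self):
        a = tt.place_children(self.parent, [90.0, 90.0], seed=123)
        b = tt.place_children(self.parent, [90.0, 90.0], seed=123)
        assert a == b

    def test_different_seeds_can_permute(self):
        spans = [30.0, 60.0, 90.0]
        headings = {tuple(c.heading for c in
                          tt.place_children(self.parent, spans, seed=s))
                    for s in range(10)}
        assert len(headings) > 1

    def test_children_inside_parent_and_disjoint(self):
        """Point-sampling oracle on a 5-child placement."""
        rng = np.random.default_rng(5)
        spans = tt.allocate_angles([3, 1, 7, 2, 5], "sqrt", 180)
        children = tt.place_children(self.parent, spans, seed=99)
        for i, ch in enumerate(children):
            pts = sample_half_disc(rng, ch.center, ch.radius, ch.heading,
                                   n=2000)
            for p in pts:
                assert in_half_disc(p, self.parent.center, self.parent.radius,
                                    self.parent.heading)
            for j, other in enumerate(children):
                if i == j:
                    continue
                inside = sum(
                    in_half_disc(p, other.center, other.radius, other.heading,
                                 eps=-1e-12)
                    for p in pts)
                assert inside == 0

    def test_degenerate_radius_rejected(self):
        tiny = HalfCircle(center=(0.5, 0.5), radius=0.0, heading=0.0, span=180.0)
        with pytest.raises(GeometryError):
            tt.place_children(tiny, [180.0], seed=0)


class TestLayoutTree:
    def test_equalized_root_spans(self):
        tree = tt.parse_newick("(A,B,C);")
        lay = tt.layout_tree(tree, tt.LayoutConfig(equalize_root=True, seed=0))
        spans = [lay.spans[c] for c in tree.root.children]
        assert spans == pytest.approx([120.0, 120.0, 120.0])

    def test_equalized_root_ignores_counts(self):
        tree = tt.parse_newick("((A1,A2,A3,A4,A5,A6,A7,A8,A9,A10),"
                               "(B1,B2),C);")
        lay = tt.layout_tree(tree, tt.LayoutConfig(equalize_root=True, seed=0))
        spans = [lay.spans[c] for c in tree.root.children]
        assert spans == pytest.approx([120.0, 120.0, 120.0])

    def test_unequalized_root_uses_counts(self):
        tree = tt.parse_newick("((A1,A2,A3),(B1,B2,B3),(C1,C2,C3));")
        lay = tt.layout_tree(tree, tt.LayoutConfig(equalize_root=False,
                                                   transform="linear", seed=0))
        spans = [lay.spans[c] for c in tree.root.children]
        assert spans == pytest.approx([120.0, 120.0, 120.0])

    def test_every_node_appears_once(self, fixture_layout, prepared_fixture):
        assert set(fixture_layout.points) == set(prepared_fixture.nodes)
        assert len(fixture_layout.branches) == len(prepared_fixture) - 1

    def test_internal_nodes_have_half_circles(self, fixture_layout,
                                              prepared_fixture):
        internals = {n.node_id for n in prepared_fixture.preorder()
                     if not n.is_leaf and n.node_id != prepared_fixture.root_id}
        assert set(fixture_layout.half_circles) == internals

    def test_empty_tree_rejected(self):
        with pytest.raises(Exception):
            tt.layout_tree(tt.parse_newick("A;").restricted_to([]), None)

    def test_serialization_roundtrip(self, fixture_layout):
        again = tt.Layout.from_json(fixture_layout.to_json())
        assert again.to_json() == fixture_layout.to_json()

    def test_geojson_has_all_elements(self, fixture_layout):
        gj = fixture_layout.to_geojson()
        kinds = [f["properties"]["kind"] for f in gj["features"]]
        assert kinds.count("half_circle") == len(fixture_layout.half_circles) + 1
        assert kinds.count("branch") == len(fixture_layout.branches)


class TestZoomLevels:
    def test_root_children_visible_at_zero(self, fixture_layout,
                                           prepared_fixture):
        for cid in prepared_fixture.root.children:
            assert fixture_layout.zoom_shape[cid] == 0

    def test_closed_form_inversion(self):
        r = 1e-6
        z = _zoom_first(r, 2)
        assert r * pixels_per_world(z) >= 2
        assert z == 0 or r * pixels_per_world(z - 1) < 2

    def test_monotone_on_large_layout(self):
        tree = tt.autoname_nodes(tt.random_tree(250, multifurcation_prob=0.6,
                                                seed=8))
        lay = tt.layout_tree(tree, tt.LayoutConfig(seed=8))
        parent_of = {c: p for p, c, _, _ in
                     [(p, c, a, b) for p, c, a, b in lay.branches]}
        for cid, pid in parent_of.items():
            assert lay.zoom_shape[cid] >= lay.zoom_shape[pid]
            assert lay.zoom_label[cid] >= lay.zoom_label[pid]


class TestLabels:
    def test_centroid_formula(self):
        h = HalfCircle(center=(0.3, 0.3), radius=0.1, heading=90.0, span=180.0)
        lay = tt.Layout(half_circles={1: h}, points={1: h.center}, root_id=0)
        tt.compute_labels(lay)
        ax, ay = lay.label_anchors[1]
        assert ax == pytest.approx(0.3)
        assert ay == pytest.approx(0.3 + 4 * 0.1 / (3 * math.pi))

    def test_arc_endpoints_on_flat_axis(self):
        h = HalfCircle(center=(0.5, 0.5), radius=0.2, heading=0.0, span=180.0)
        lay = tt.Layout(half_circles={1: h}, points={1: h.center}, root_id=0)
        tt.compute_labels(lay)
        arc = lay.rank_arcs[1]
        for end, ang in ((arc[0], -90.0), (arc[-1], 90.0)):
            ex = 0.5 + 0.95 * 0.2 * math.cos(math.radians(ang))
            ey = 0.5 + 0.95 * 0.2 * math.sin(math.radians(ang))
            assert end == pytest.approx((ex, ey))

    def test_anchor_inside_own_half_disc(self):
        tree = tt.autoname_nodes(tt.random_tree(250, multifurcation_prob=0.5,
                                                seed=3))
        lay = tt.layout_tree(tree, tt.LayoutConfig(seed=3))
        for nid, h in lay.half_circles.items():
            assert in_half_disc(lay.label_anchors[nid], h.center, h.radius,
                                h.heading)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_angle_conservation(self, seed):
        tree = tt.autoname_nodes(tt.random_tree(80, multifurcation_prob=0.6,
                                                seed=seed))
        lay = tt.layout_tree(tree, tt.LayoutConfig(seed=seed))
        for node in tree.preorder():
            if node.is_leaf:
                continue
            total = sum(lay.spans[c] for c in node.children)
            aperture = 360.0 if node.node_id == tree.root_id else 180.0
            assert abs(total - aperture) < 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_containment_and_disjointness(self, seed):
        rng = np.random.default_rng(seed)
        tree = tt.autoname_nodes(tt.random_tree(60, multifurcation_prob=0.6,
                                                seed=seed))
        lay = tt.layout_tree(tree, tt.LayoutConfig(seed=seed))
        for node in tree.preorder():
            if node.is_leaf:
                continue
            parent_shape = (lay.root_disc if node.node_id == tree.root_id
                            else lay.half_circles[node.node_id])
            kids = [lay.half_circles[c] for c in node.children
                    if c in lay.half_circles]
            for i, ch in enumerate(kids):
                pts = sample_half_disc(rng, ch.center, ch.radius, ch.heading,
                                       n=150)
                for p in pts:
                    assert in_half_disc(p, parent_shape.center,
                                        parent_shape.radius,
                                        parent_shape.heading,
                                        parent_shape.span)
                for j, other in enumerate(kids):
                    if i != j:
                        assert not any(
                            in_half_disc(p, other.center, other.radius,
                                         other.heading, eps=-1e-12)
                            for p in pts)

    def test_no_branch_crossings_300_leaves(self):
        tree = tt.autoname_nodes(tt.random_tree(300, multifurcation_prob=0.6,
                                                seed=77))
        lay = tt.layout_tree(tree, tt.LayoutConfig(seed=77))
        segs = [(a[0], a[1], b[0], b[1]) for _, _, a, b in lay.branches]
        assert segments_cross(segs) == 0

    def test_byte_identical_reruns(self):
        tree1 = tt.autoname_nodes(tt.random_tree(100, seed=4))
        tree2 = tt.autoname_nodes(tt.random_tree(100, seed=4))
        cfg = tt.LayoutConfig(seed=21)
        assert tt.layout_tree(tree1, cfg).to_json() == \
            tt.layout_tree(tree2, cfg).to_json()

    def test_sibling_span_monotone_in_counts(self):
        tree = tt.autoname_nodes(tt.random_tree(150, multifurcation_prob=0.8,
                                                seed=13))
        lay = tt.layout_tree(tree, tt.LayoutConfig(seed=13,
                                                   equalize_root=False))
        for node in tree.preorder():
            for a in node.children:
                for b in node.children:
                    if tree.nodes[a].n_leaves > tree.nodes[b].n_leaves:
                        assert lay.spans[a] > lay.spans[b]
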