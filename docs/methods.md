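# Methods

## The layout model

The map lives in the unit square; the tree occupies a disc of radius 0.45
centred at (0.5, 0.5). Each clade is a half-disc nested in its parent's,
described by a centre (the midpoint of its flat side, which is also the
point branches attach to), a radius, a heading (the direction from the flat
side into the disc) and an angular span.

**Angular allocation.** An internal node with children of leaf counts
n₁…n_k splits its aperture T (360° at the root, 180° elsewhere) as
span_i = T·w_i/Σw_j. The default weighting is w_i = √n_i; `transform="linear"`
uses w_i = n_i, which for two children reduces to α = 180·n_A/(n_A+n_B).
The square-root default exists because taxonomic leaf counts span seven
orders of magnitude: linear weighting collapses small clades to invisible
slivers, while the square root keeps them findable without hiding the true
imbalance. The allocation is order-preserving and exact (the last span
absorbs floating-point slack, far below the 1e-9° tolerance asserted in
tests). With `equalize_root=true` (the tree-of-life convention) the root's
children get equal spans regardless of counts, so the superkingdoms read as
peers.

**Placement.** Children are assigned consecutive sectors of the parent's
aperture in a seeded random permutation of their stored order — "random"
placement that is nonetheless a pure function of (tree, seed). Child i's
half-disc is centred at distance ρR from the parent centre along its sector
bisector (ρ = `radial_fraction`, default 0.5; R the parent radius), faces
along the bisector, and has radius

    r_i = (1 − padding) · min(R(1 − ρ), ρR·sin(span_i/2)),

padding defaulting to 0.1. The two min-terms are the whole geometric
argument: ρR + r_i ≤ R keeps the child inside the parent's rim, and
r_i ≤ ρR·sin(span_i/2) keeps the child's full disc inside its own sector
wedge (the distance from the child centre to a sector boundary ray is
exactly ρR·sin(span_i/2)). Disjoint wedges give disjoint siblings;
the bisector sits at least span_i/2 away from the parent's diameter line,
so the child also stays on the parent's open side. Containment plus the
fact that each branch is the radial segment from the parent centre to the
child centre (entering the child from behind its flat side) makes the whole
drawing planar: branches can meet only at shared endpoints. These
properties are asserted by point-sampling and O(n²) segment-intersection
oracles in the test-suite rather than trusted from the proof sketch.

**Degenerate cases.** A single child receives the full aperture; its span
is capped at 180° inside the radius formula (sin is evaluated at min(span,
180)/2) so root-level spans above 180° remain well-defined. A non-positive
radius (possible only with a zero-radius parent) raises a geometry error
naming the node. Branch lengths, when present in the input, are parsed and
round-tripped but never influence geometry: taxonomies carry no meaningful
lengths, and the layout is defined on topology and counts alone.

**Zoom of appearance.** Pixel scale at zoom z is 256·2^(z+1) px per world
unit (a 2×2 tile grid at level 0). An element first appears at the smallest
z where its world radius covers `shape_min_px` (default 2 px); labels use
`label_min_px` (default 64 px, roughly when a name fits inside its
half-disc). Radii strictly shrink down the tree, so children never appear
before parents; the implementation clamps anyway. The pixel thresholds are
display choices, not measured constants.

**Labels.** A clade's name anchors at its half-disc centroid, 4r/(3π) from
the flat-side midpoint along the heading; rank names follow the arc at
0.95r between heading±90°.

## Preparation

* `filter_banned` removes any node whose name contains one of the eight
  case-sensitive fragments (unidentified/Unidentified, unclassified/
  Unclassified, environmental/Environmental, uncultured/Uncultured),
  together with its entire subtree — such names label containers of exactly
  the material a general-public map should omit. Matching is substring, so
  "unclassified Bacteria" is caught. Removing the root is refused.
* `prune_below_species` removes every strict descendant of a rank="species"
  node, plus any node whose own rank is in a configurable below-species set
  (default: subspecies, varietas, forma) even when no species ancestor is
  annotated. "Below the species level" has no universally fixed rank set;
  this pair of rules is the package's reading and both halves are
  overridable. Trees without rank annotations pass through unchanged.
* `autoname_nodes` walks tips-to-root and gives each unnamed internal node
  the names of its first two children joined by "+". "Two of the
  descendants" is ambiguous for polytomies; stored child order makes the
  choice deterministic and input-stable.

## Tiling

Level z is a 2^(z+1)×2^(z+1) grid of 256×256 px tiles, 4^(z+1) addresses,
each tile subdividing into exactly four at z+1. Rendering is vector-first:
half-circles are 64-segment polylines closed by their chord, branches are
segments; everything visible at the tile's zoom is clipped (shapely) to the
tile's bbox and stroked (Pillow). A tile that draws nothing is *blank* and
is never written; the pyramid walk descends into a tile only when some
element — at any zoom of appearance, not just the current one — intersects
its region, so a tile skipped without rendering is provably blank at every
level below it too. Blankness is therefore decided geometrically, with
raster uniformity as the test-suite's independent check. Output is the
standard `{z}/{x}/{y}.png` directory layout plus a JSON manifest; existing
files are never rewritten, so warm reruns preserve mtimes.

Known rendering limitations: strokes are 1 px at every zoom (no
anti-aliased widths), arcs are 64-gon approximations which become visible
at very deep zooms, and a label is drawn only by tiles near its anchor, so
long names can clip at tile seams. None of these affect the geometry,
addressing or blank-skipping contracts.

## Queries

MRCA lifts the deeper node to equal depth and climbs both sides in
lockstep; routes are source→MRCA→destination with length depth(a) +
depth(b) − 2·depth(mrca) + 1. Search is case-insensitive over scientific
and common names, exact or prefix, returns all homonyms, and joins each hit
with its layout point and label zoom — a "zoom to here" instruction.

## Synthetic data

`random_tree` grows a tree by recursively partitioning a leaf budget:
each node draws 2 children, or 3–6 uniformly with probability
`multifurcation_prob`, and splits its budget uniformly at random. Under a
polytomy, a budget of exactly 2 would force a binary node, so such parts
become two sibling leaves (with the same probability), keeping generated
trees polytomy-rich — the regime real taxonomies live in, where most
internal nodes are non-binary. Optional knobs leave a fraction of internal
names empty and inject banned words into a fraction of names so the
preparation passes are exercised end to end. What the generator does *not*
emulate: realistic birth–death branching statistics, realistic name
morphology, rank hierarchies (ranks come only from the hand-written
fixture), or the extreme (10⁶-leaf) scale of the full taxonomy — passing
tests demonstrate geometric and algorithmic correctness, not performance at
planetary scale. Test problem sizes (trees up to ~500 nodes, pyramids to
zoom 3) were chosen so the whole suite exercises every invariant in
seconds.

`fixture_tree` is a fixed 26-node taxonomy with known MRCAs, species and
subspecies ranks, one banned-name clade and two unnamed internals; its
docstring enumerates every expectation the tests rely on.

## Determinism

Every stochastic choice flows from an explicit integer seed: the generator
from its `seed` argument, sector permutation from a per-node stream derived
from `LayoutConfig.seed` and the node id. Layout JSON (sorted keys) and PNG
tiles are byte-stable across runs, which the acceptance suite asserts.
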