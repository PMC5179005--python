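# treetiles

Explore arbitrarily large multifurcating trees — the NCBI taxonomy scale —
the way you explore a web map: a space-filling half-circle layout projected
into a slippy-map tile pyramid (256×256 px tiles at addresses *(z, x, y)*),
with tiles rendered on demand and blank regions never materialised. The
package is for anyone who needs to turn a big taxonomy or phylogeny into a
zoomable map offline: it covers tree I/O (Newick and NCBI-taxdump-style
tables), general-public cleanup filters, the layout itself, tile rendering,
and tree queries (MRCA, routes, name search, subtree export).

## The layout in one paragraph

Every clade is drawn as a half-disc nested inside its parent's. Among
siblings with leaf counts *n₁…n_k*, child *i* receives the angular span

  span_i = T · w_i / Σ_j w_j,  with w_i = √n_i (default) or w_i = n_i,

where *T* is the parent's aperture (360° at the root disc, 180° elsewhere).
For two siblings in linear mode this is α = 180·n_A/(n_A+n_B). The square
root damps the enormous size contrast between species-poor and species-rich
clades. Sibling sectors are a seeded random permutation of child order; a
child's half-disc sits at distance ρR from its parent's centre along its
sector bisector with radius

  r_i = (1 − padding) · min(R(1 − ρ), ρR·sin(span_i/2)),

which provably keeps every half-disc inside its parent, keeps siblings
disjoint, and makes the straight parent→child branches planar — branches
never cross. In tree-of-life mode the root's children (the superkingdoms)
are given equal spans regardless of counts. Zoom level *z* covers the world
with a 2^(z+1)×2^(z+1) grid of tiles, so level *z* holds 4^(z+1) addresses;
an element first appears at the zoom where it is at least a few pixels wide.

## Worked example

```python
import treetiles as tt

tree = tt.fixture_tree()                 # 26 nodes, 16 leaves, with ranks
tree = tt.filter_banned(tree)            # drops the "environmental samples" clade
tree = tt.prune_below_species(tree)      # species become the tips
tree = tt.autoname_nodes(tree)           # unnamed internals get "A+B" names
print(len(tree.leaves()), tree.nodes[12].name)

lay = tt.layout_tree(tree, tt.LayoutConfig(seed=7))
manifest = tt.render_pyramid(lay, z_max=3, cache_dir="tiles")
print(len(manifest), "tiles written of", sum(tt.tiles_at_level(z) for z in range(4)))

res = tt.path_between(tree, 13, 18)      # Homo sapiens -> Mus musculus
print([tree.nodes[i].name for i in res.route])
```

prints

```
11 Homo sapiens+Pan troglodytes
203 tiles written of 340
['Homo sapiens', 'Homo sapiens+Pan troglodytes', 'Eukaryota', 'Mus musculus+Rattus norvegicus', 'Mus musculus']
```

— 11 tips survive the two filters; only 203 of the 340 possible tile
addresses up to zoom 3 contain any geometry (the rest are blank and never
written); and the route climbs from human to the human/chimp ancestor, to
Eukaryota (the MRCA), then down through the murid clade to mouse.

The same pipeline from a shell:

```
treetiles build mytree.nwk -o out/ --seed 7
treetiles render out/ --z-max 4
treetiles path out/ --from "Homo sapiens" --to "Mus musculus"
treetiles search out/ "Ho" --mode prefix
treetiles export out/ "Primates"
```

Tiles land in the standard `{z}/{x}/{y}.png` directory layout, so any
slippy-map viewer pointed at the directory can browse the tree.

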