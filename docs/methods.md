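# Methods

## The measurement model

The package treats a contrast-stained lung micro-CT scan as a 3D 16-bit
gray-value field in which tissue density maps to gray value: stained
vessel lumina are bright, parenchyma darker, air spaces darkest. A vascular
tree is segmented by seeded region growing — the connected component,
under a configurable connectivity (default the full 26-neighbourhood, as
in commercial region growers; 6/18 selectable), of voxels whose gray value
lies within a symmetric tolerance window around the seed's reference value.
The half-width defaults to 1100 gray levels, the midpoint of the 1000–1200
range used on the real scans, and is always recorded in the run manifest.
Whether that window should be symmetric is not documented for the original
software; symmetric half-width is assumed here. Where the lumen gray value
changes along a vessel (blood-filled versus air-filled stretches), the
workflow re-seeds: `region_grow_multiseed` grows each seed around its own
reference value and unions the regions, warning about (but tolerating)
rejected seeds.

ROI volume is voxel count × voxel volume, reported in mm³ at full
precision; printed tables round to two decimals with ties away from zero
(the convention that maps a mean of 0.125 to 0.13, matching the published
cells).

## Centerline model and branching statistics

The binary ROI is reduced to a one-voxel-wide skeleton by parallel 3D
thinning (Lee's method via scikit-image). Thinning preserves topology but
can annihilate compact blob-shaped components outright; `skeletonize`
restores the deepest voxel (distance-transform argmax) of any component
the thinning erased, so component counts are preserved by contract.

The skeleton becomes a spatial graph: voxels with one 26-neighbour are
endpoints, voxels with three or more are junctions (26-adjacent junction
voxels merge into one node), and maximal junction-free chains become edges
carrying arc length (mm) and a radius equal to the mean Euclidean distance
transform of the ROI along the chain. Every skeleton voxel is owned by
exactly one node or one edge interior — an invariant the tests assert.

Terminal edges shorter than `min_length_factor` × local radius (default
2.0) are pruned as rasterization/thinning spurs; the surviving voxels are
re-thinned and the graph re-extracted after each round, which dissolves
junctions reduced to passthroughs and removes bump remnants of dissolved
junction clusters. The default factor reflects that a true branch under
the study's resolution limits is always at least several radii long,
whereas thinning spurs are shorter than the local vessel diameter; the
original visual workflow had no explicit rule, so this threshold is a
design choice of this package. Factor 0 disables pruning.

The graph is rooted at a user-supplied physical coordinate — where the
pulmonary trunk leaves the heart — matched to the nearest node within one
local radius (at least one voxel). Cycles, which arise from anastomoses or
segmentation bridges, are resolved by keeping the shortest-path tree in
geodesic edge length from the root; the number of removed edges is a
logged quality metric, as is the pruned-spur count.

Generations follow the printed convention: the main trunk is generation 0
and every child increments by exactly 1 regardless of sibling count; no
Strahler/Horsfield or diameter-defined ordering. "Number of vessels"
counts centerline segments, the only reading compatible with counts like
41 vessels under a maximum generation of 10. The median is over
*end-branch* generations, with the even-multiset median equal to the mean
of the two central values (hence printed half-integers such as 4.5). Side
labels split the tree at its first branch point: the trunk path is
"trunk", and each subtree is "left" or "right" by the sign of its centroid
along a declared anatomical axis; trunk segments count only toward the
"total" scope. The published left+right counts do not sum to the printed
totals and the discrepancy is not explained by trunk segments alone, so
side-level printed counts are reported under the stated conventions but
never used as construction targets.

## Synthetic phantoms

`generate_tree` grows parametric trees: children per branch point (2, or
2–3 in mixed mode), branch polar angle with jitter, geometric length decay,
and a Murray-type radius law (children of a segment of radius r get
r·n^(−1/k); k = 3, the laminar-flow optimum, since vessel calibres were
not measured in the source data). `prune_probability` drops individual
children, truncating subtrees early.

`generate_preset_tree` hits a prescribed whole-lung (median end-branch
generation, maximum generation, vessel count) triple exactly, by
construction: a spine of generations 0..max carries the maximum, and the
remaining segments are single terminal side branches attached one
generation up, their generations chosen so the order statistics around the
median are pinned while the rest are seeded draws near the median (so
different seeds give different trees with identical statistics).
Multifurcations at spine nodes are allowed — some published counts are
unreachable with strictly binary branching, and anatomically lobar
branches do arise sequentially from a continuing trunk. Infeasible triples
(count below the spine size, medians outside [1, max] with side terminals
present, half-integer medians with an odd number of terminals) raise an
explicit error. Preset trees are topology-exact but geometrically crowded
at their multifurcations; they are the ground truth for statistics and
file-format tests, while voxel-level recovery is validated on the random
binary phantoms below.

`rasterize` renders segments as capsules (cylinders with spherical caps,
closing junction gaps) on a voxel grid — physical mm, origin at the volume
corner, (z, y, x) index order, voxel centres at (index + 0.5) × voxel
size — then applies the intensity model and i.i.d. Gaussian noise, clipped
to 16 bits. The default model (parenchyma 12000, lumen 40000, air 2000,
noise SD 300) leaves a 28 000 gray-level contrast, so the 1000–1200
tolerance window separates lumen from parenchyma with a noise tail
probability below 10⁻⁴ per voxel. Voxel sizes are anisotropic-capable and
the study's 1.5–20.1 µm range is the intended regime; the phantom
experiments use 10 µm.

Two rasterization subtleties surfaced during validation and are handled
deliberately:

* A tube running exactly along a grid axis with its centerline exactly
  midway between voxel columns rasterizes to an even-width core that has
  no protected line end under parallel thinning — the entire branch can
  retract. Real scans never align vessels with the grid;
  `fit_tree_to_grid` adds a 0.37-voxel grid phase and the recovery
  experiment draws oblique root directions.
* Sensor noise occasionally pushes single lumen voxels out of the
  tolerance window. Interior dropouts become enclosed cavities; surface
  dropouts can form one-voxel tunnels (spurious handles).
  `repair_mask_defects` applies a 6-connected one-voxel closing followed
  by cavity filling before skeletonization; the closing cannot bridge
  structures more than two voxels apart.

## The recovery experiment

`recovery_experiment` draws random binary TreeSpecs inside the
resolvable-by-design envelope: root radius 50–62 µm (5–6.2 voxels at
10 µm), every branch radius ≥ 2 voxels after the Murray decay, branch
lengths ≥ 5× radius, branch angles 35–50° with 8° jitter, depth 3–4
(15–31 segments, grids around 150–200³ voxels), noise SD 300 and tolerance
1100. Two exclusions keep the claim honest rather than easy:

* no pruning (perfect binary trees): a parent with exactly one child is
  *by construction* indistinguishable from one longer segment in any
  centerline representation, so single-child chains cannot be "recovered";
* self-colliding trees are rejected (non-adjacent branches must clear each
  other by 2.5 voxels): touching subtrees rasterize into loops that no
  method can resolve back into the original topology.

Under these conditions the full chain — rasterize → region grow → repair →
skeletonize → prune → resolve → summarize — reproduced the ground-truth
triple exactly in 20/20 runs at the default experiment seed (and 80/80
across four seeds during development). What passing does *not* show:
robustness to scanner artifacts (beam hardening, reconstruction streaks),
to contact between anatomically distinct vessels, to partial-volume
effects at sub-voxel calibres, or to the visual editing steps of the
original workflow; the phantoms have piecewise-straight branches and
spatially uncorrelated noise.

## Cohort analyses

Per-age summaries use the sample SD (n − 1; the published {2.70, 1.73,
2.74} → 0.57 identifies the convention), with SD omitted for singleton age
groups. Allometric fits are ordinary least squares of log10(volume) on
log10(body mass); the fit-point convention (individual specimens versus
per-age means) is not documented for the original plots, so both are
offered with per-specimen as the default. Lung and bronchial-tree volumes
of the same specimens were reconstructed in earlier work and enter as
given columns; their recomputation is out of scope.

## Numerical and degenerate-input choices

Determinism: every stochastic step takes an explicit seed
(`numpy.random.default_rng`); identical configs give byte-identical
statistics tables, and the manifest records config hash, seeds, tolerance,
connectivity and pruning factor. Tie-breaks are fixed (node ids by voxel
order, children visited in node-id order, parallel edges collapsed to the
shortest, root matching prefers the smaller node id at equal distance).
Degenerate inputs have defined behaviour: single-voxel masks skeletonize
to themselves; empty masks, empty scopes, all-rejected seeds and missing
voxel-size metadata raise typed errors (a 1 µm voxel size is never
assumed); a never-bifurcating tree is all-trunk with a warning; exactly
tied side centroids raise rather than guess.

## Known limitations

Radii from the distance transform are biased high by about half a voxel;
segment counts and generations — the quantities the study reports — are
unaffected. The shortest-path cycle resolution is a topological
tie-breaker, not a hemodynamic model of anastomoses. Preset trees encode
only the whole-lung printed triples; they do not model lobar anatomy.
Branch lengths and diameters are not analysis outputs, mirroring the
source study's scope.
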