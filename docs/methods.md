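# Methods

This note records the models, conventions and numerical choices behind
`vemtools`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic data do and do not show.

## Coordinate and raster conventions

All volumes use 0-based voxel indices in axis order (x, y, z) with
half-open extents.  A voxel's physical position is
`(offset + index) · voxel_size` in nanometres; the default pitch is
14 × 14 × 25 nm³, the acquisition resolution needed to resolve the
thinnest neurites (~50 nm), synaptic vesicles (~40 nm) and postsynaptic
densities (25–50 nm).  Label 0 is background everywhere.  Connected
components are labeled 1..K in raster order of each component's first
voxel, so labelings are reproducible across runs.  Default connectivity is
26 in 3D and 8 in 2D; every public operation takes it explicitly, since
the choice is a genuine free parameter of component analysis.

Morphological erosion uses the digitized Euclidean ball in voxel index
space — a "radius 5" erosion is isotropic in index units and ignores
anisotropy, because that is the natural reading of a radius given without
physical units; a metric (nm) ball is available via a flag.

## Phantom generator

The generator emulates the structural properties the pipeline assumes,
not EM appearance.  Neurite tubes follow cubic-spline-smoothed random
paths along x, each confined to its own (y, z) lane corridor.  Lanes make
packing deterministic and guarantee at least one voxel of background
between any two tubes — exactly where synaptic clefts live.  Rejection
sampling remains as the fallback (soma placement, collision retries), with
a bounded retry budget; infeasible requests raise `PackingError` rather
than degrade silently.

Synapse pairs occupy adjacent lanes; at the synapse location both control
points are pulled to the shared lane boundary so the surface gap there
equals the cleft thickness (default 30 nm, in the 25–50 nm range of a
postsynaptic density — one to two voxels at default pitch).  The cleft is
carved from the background voxels lying between the two surfaces (sum of
distance transforms), trimmed so it touches exactly its two partner
cells.  The vesicle cloud is the set of presynaptic-tube voxels within
200 nm of the cleft centroid, so it always lies inside exactly one cell.
Skeleton nodes are placed at the voxel centres of the rasterized
centerline, which guarantees the point-in-mask property evaluation relies
on.

Oversegmentation errors are planted per object: a split cuts an object by
a random axis-aligned plane; a merge gives one supervoxel of each of two
adjacent objects (surface gap below `adjacency_nm`, default 120 nm) a
shared id.  Split decisions use one RNG substream per (seed, label), so
for a fixed seed the set of split objects is *nested* as the split rate
grows — accuracy curves across rates are then monotone per seed by
construction, isolating the metric's response from sampling noise.  An
exact merge count (`n_merges`) is available alongside the Bernoulli rate.

The focus phantom uses full-range binary texture with ~2-voxel grain —
coarse enough that its power survives the detector's own Gaussian, which
is the property that matters in contrast-normalized EM planes; defocused
regions are the same texture convolved with the stated Gaussian sigma.
What passing tests show: the filter chain separates this texture sharp
from sigma-8 blur at the fixed threshold.  What they do not show:
performance on real EM noise spectra, charging artifacts or knife marks.

## Defocus and soma chains

The defocus detector is a fixed filter chain per plane: Gaussian (σ = 1),
discrete 5-point Laplacian, population standard deviation over a centered
21 × 21 window (edge-truncated), 128× in-plane area-average downsampling,
and a strict `< 57` threshold on the 8-bit scale.  The Laplacian makes the
response invariant to intensity offsets, and scaling contrast up can only
move sites toward "in focus" — both property-tested.  Input is assumed
contrast-normalized; a CLAHE helper with fixed parameters (64 × 64 tiles,
clip limit 2.0, 8-bit output) is provided for reproducibility.

Soma candidates: zero every voxel of the excluded classes (default
`{nonneuropil, soma}`, configurable — the exclusion list is surfaced
rather than second-guessed), compute components, erode with a radius-5
ball to break false mergers, recompute components, and keep objects
strictly larger than 1000 voxels of the input grid.  The volume is
measured on the *eroded* component, following the order of operations.
Note that erosion can legitimately *increase* the candidate count by
splitting falsely merged objects; the count is monotone non-increasing in
erosion radius only for well-separated objects.

## Proofreading backend

The agglomeration graph lives in memory; its connected components are the
current reconstruction of each cell.  Every edit is validated, appended to
an on-disk JSONL log, and only then applied and acknowledged (write-ahead
discipline), so the live state always equals base ⊕ log.  Replay is
strict: a non-increasing sequence number or an inapplicable record halts
with the offending seq — divergence is loud.  Removing a base-proposal
edge and removing a user-added edge are logged identically; the
distinction carries no information for state reconstruction.

Writes are serialized through a single lock; reads may run concurrently.
The load harness deals a recorded log round-robin to N client threads,
funnels writes through a sequencer that preserves log order (making the
final partition independent of N), pairs each write with a component
query, and reports 1st/50th/99th percentile latencies per operation —
reporting only, with no pass/fail on absolute times.

Constrained agglomeration accepts scored candidate edges in descending
score order (ties by ascending id pair) and rejects any merge that would
put two distinct nucleus ids into one component; the invariant is
asserted post hoc on every run.

Replay verification strategy: live sessions record an order-independent
XOR fingerprint of the edge set after every edit; truncated-log replays
must reproduce the fingerprint at every prefix, with exact partition
comparisons at the full log and at sampled prefixes.  The fingerprint
check is O(1) per prefix and collision-safe to ~2⁻⁶⁴ per comparison.

## Segmentation evaluation

Edge accuracy maps each skeleton node to the segment label at its voxel
and classifies each edge: omitted (an endpoint on background), split
(different nonzero labels), merged (shared label also contains another
skeleton's node), else correct.  The merge witness is node-level by
default; a stricter same-connected-component witness is available behind
a flag.  Edges are pooled across skeletons; per-skeleton means are also
reported.

The oversegmentation consensus marks a voxel foreground iff both inputs
are nonzero and takes connected components of constant (labelA, labelB)
pairs — a refinement of both inputs by construction.  Post-processing
fills background components that cannot reach the volume border and whose
surround is a single label, and absorbs a segment into a neighbour when
all of its adjacent foreground is that one neighbour and none of its
adjacent background reaches the border; both rules iterate to a fixpoint
and the whole operation is idempotent.  "Interior" uses 6-connectivity
for background reachability.

Checkpoint-pair selection takes the top-k (default 7) candidates by edge
accuracy, scores every unordered pair by how many annotated adjacent-
neurite point pairs its consensus separates into two distinct nonzero
ids, and returns the argmax (ties by lexicographic indices).

## Skeletons and morphometrics

Skeletons are forests with nm positions; compartments (axon/dendrite/
soma) ride on the SWC structure type, synapse and branch tags on a
companion CSV.  Branch points are nodes of degree ≥ 3 unless explicit
annotations exist (annotations win).  Path length is the Euclidean edge
sum in µm; an edge counts toward a compartment when both endpoints carry
it.  Branch density is per µm of total length, synapse-out density per µm
of axon; zero-length denominators flag the row instead of producing
infinities.

Consensus skeletons: a node is retained iff at least quorum−1 *other*
tracings place a node within the tolerance (defaults: 1 µm tolerance,
majority quorum ⌈n/2⌉ — both configurable, since the upstream procedure's
exact values are not fixed here); retained nodes merge by greedy spatial
clustering in deterministic order, edges are induced from the supporting
tracings.  Tolerance 0 with jittered inputs yields a near-empty consensus
— the documented degenerate case.  Fragment sampling draws locations
uniformly along (compartment) path length and cuts out all nodes within
750 nm, the radius used for local diameter review; diameters themselves
are manual measurements and enter only as an input table.

## Synapse geometry and validation

Contact areas come from marching-cubes meshes of the cleft voxels at
physical scale.  A thin contact's closed mesh counts both faces, so the
reported area is half the mesh area; the convention is recorded in the
result and a flag switches to the full mesh.  On a 10 × 10 px single-voxel
slab this lands within 20% of the analytic face area (the rim and the
marching-cubes bevel account for the remainder); on digitized spheres of
radius ≥ 10 voxels the half-surface is within 10% of 2πr².

Per-section profile length is the Feret-type diameter of the largest
8-connected slice component: the maximum pairwise centre distance plus
the voxel support along the maximising direction.  This makes axis-aligned
runs measure exactly n · pitch and a single voxel measure the larger
in-plane extent; slices with > 500 voxels are reduced to their convex hull
first.  Sampled median reports (default 100 contacts per region) cover
both per-object areas and pooled per-section lengths, reproducibly by
seed.

Object-wise precision/recall uses any-overlap greedy one-to-one matching
in descending overlap order (ties by smaller id pair).  Greedy matching
can in principle differ from the optimal assignment on adversarial
overlap patterns; on realistic detector outputs (compact, mostly disjoint
objects) it coincides with maximum matching, which the tests verify
against an exhaustive oracle.

## Connectome assembly

For each cleft, cells with voxels within `dilation_nm` (default 100 nm ≈
cleft plus membrane thickness) are ranked by contact voxel count; the top
two are the partners, and the one with more vesicle-cloud overlap in the
same neighbourhood is presynaptic — the automatic counterpart of the
manual criterion that a vesicle cloud is seen in the axon.  Missing or
tied evidence leaves the direction null with a flag; clefts touching
fewer than two cells are reported unpaired.  Synapse count is conserved:
directed edge counts plus undirected plus unpaired equals the cleft
count.  Cycle detection and shared-partner fractions operate on the
directed edge list; cell-type labels are user-supplied metadata, not
computed.

## Tile planning and registration

The planner steps columns of the fixed scan width across each section's
mask bounding box (the final column placed flush with the box edge, so the
scanned union stays inside it) and covers each column's maximal occupied
y-interval with tiles of length in [y_min, y_max], consecutive tiles
overlapping by a fixed margin; disjoint y-intervals get separate tile
runs, minimizing scanned area.  One positioning move is counted per tile.
For a full rectangle this reduces to the closed form
`ceil(W/w) · ceil((H − o)/(y_max − o))`.  Coverage is reported against
both the whole-stack cuboid bounding box and the per-section boxes, since
both denominators are in use in practice.  Coverage fraction is monotone
under mask growth within a fixed bounding box; growth that changes the
box shifts the column anchor and the guarantee becomes box-relative.
Move counts are not monotone in general: filling the gap between two
y-intervals can merge two tile runs into one.

Block-wise registration fits one least-squares affine per block of the
source domain (default block 42 × 28 × 2 in the working resolution, fully
configurable) from all landmarks in the block's surround (default: the
block dilated by one block size).  Blocks with fewer than 4 usable points
or a rank-deficient configuration fall back to the global affine and are
flagged; transforms are piecewise-constant with no blending, and points
outside the grid map through the nearest block with a flag.  A single
global affine is recovered exactly regardless of the partition;
leave-one-out errors are reported per block.

## Problem sizes

Tests and the acceptance script run at sizes chosen to exercise every
code path while staying desk-scale: proofreading sessions of 1,000 edits
on 10,000-supervoxel graphs (20 sessions), evaluation phantoms of
160 × 512 × 96 voxels with 20 neurites, 50-pair merge-screening grids,
32³ consensus volumes, 512 × 512 focus planes, and 200-landmark
registration problems.

## Known limitations

- Phantoms have no EM texture, membranes or organelles; classifier
  outputs are simulated as geometry, so nothing here validates any CNN.
- Tube packing in lanes caps the number of neurites per volume and makes
  all tubes roughly axis-parallel; morphometrics on phantoms therefore
  probe bookkeeping, not biological geometry.
- The greedy PR matching and the convex-hull Feret reduction are exact
  only under the realistic-instance assumptions stated above.
- The load harness measures in-process latencies; network and
  serialization costs of a deployed service are out of scope.
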