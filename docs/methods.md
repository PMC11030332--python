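# Methods

`neuroskel` reconstructs neurons from 3D lightsheet-style image volumes
at desk scale: it enhances the raw volume, selects a sparse foreground,
finds somas, segments whole cells by seeded reachability, collapses each
cell surface into an SWC tree, and scores skeletons against ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not show.

## Working sets

The pipeline is organized around three nested views of the same data:
the dense volume `W` (every voxel), the spatially sparse foreground
`W_s` (voxels above the conversion threshold), and the causally sparse
set `W_c` (voxels reachable from detected somas). Every stage shrinks
the active set: `|W_c| <= |W_s| <= |W|` holds for every run and is
asserted in the working-set report.

## Image enhancement

**Destriping.** Stripe shadows are multiplicative, constant within an
image column (our convention: constant along the slice's first axis) and
vary across columns. Each z-slice is decomposed with a 2D multi-level
wavelet transform (Daubechies-3, depth `min(5, floor(log2(min slice
dim)))`); the detail band that condenses column-coherent structure is
Fourier-transformed along the stripe axis and multiplied by the Gaussian
notch `g(k) = 1 - exp(-k^2 / 2 sigma^2)` (default sigma 2 cycles per
band width), which annihilates the zero-frequency stripe component and
passes everything else. Constant images are fixed points because all
detail coefficients vanish. Deep decompositions on narrow slices incur
boundary effects; that trade is accepted because low stripe frequencies
(long periods) live in the deep bands.

**Debleaching** is flat-field correction: divide the volume by a
Gaussian low-pass estimate of itself (default sigma = 1/8 of the
smallest lateral extent) and rescale to preserve the mean. Two numerical
choices matter. The low-pass is computed after *odd* (antisymmetric)
reflection padding, which continues linear illumination ramps across the
border — plain reflection flattens ramps near edges and leaves a bias
comparable to the field being removed. And because the field is smooth
by construction, it is estimated on a block-mean grid of about 4 samples
per sigma and linearly interpolated back, which makes the stage O(n) with
a small constant. The divisor is floored at 1e-3 of the filtered maximum.

**Deconvolution** is Richardson–Lucy with a separable anisotropic
Gaussian PSF (defaults: lateral sigma 1 um, axial 2.5 um — the ~2.5x
axial smear typical of lightsheet optics — truncated at 3 sigma,
normalized to unit sum). Ten iterations by default; multiplicative
updates keep the estimate non-negative for any count and conserve
interior flux to within 1%. The volume is reflection-padded by the
kernel half-width before the FFT convolutions and cropped afterwards.
Where the re-blurred estimate carries no flux the update ratio is set to
0 (floor at 1e-6 of the data maximum) rather than divided out, which is
what keeps 32-bit arithmetic stable.

## Conversion and morphology

The conversion threshold is chosen so the fraction of voxels above it
best matches a target foreground percent (ties toward the smaller
foreground fraction). The default target is 0.8%, the density regime
where reconstruction accuracy tends to peak on real lightsheet volumes;
for synthetic phantoms the right target is known exactly (see below).

The sparse mask is a boolean occupancy array with O(1) membership.
Dilation and erosion use the exact Euclidean ball `{d : ||d|| <= r}` in
voxel units, realized by thresholding exact distance transforms, so they
agree voxel-for-voxel with a brute-force ball scan. Erosion treats
out-of-domain voxels as background. Closing tracks the dilation on an
r-padded domain before eroding and then crops, which preserves
extensivity (`close(m) >= m`) for masks touching the volume border;
without the padding, border voxels would erode away and closing would
not be a closing. Opening and closing are idempotent and bracket the
mask (`open(m) <= m <= close(m)`); all of this is property-tested
against the brute-force oracle.

Physical anisotropy is handled upstream: morphology is isotropic in
voxel units, and strongly anisotropic volumes should be z-downsampled
first (block mean, default factor 3 for the 2.5x axial blur regime).

## Seed (soma) detection

With surface-only labeling the somas image as hollow shells, so
detection operates on the surface representation: extract the 6-neighbor
boundary, close with radius 7, open with radius 3, split at
26-connectivity, and drop components below a size floor. The closing
radius must reach the soma cavity radius (soma radius minus shell
thickness; with the phantom geometry of 6–8.5 um somas and 2-voxel
shells, cavities are at most 6.5 um, hence 7). The opening radius must
exceed the thickest branch (phantom branches are at most 2 um). The size
floor defaults to the volume of the opening ball (123 voxels at radius
3) — anything smaller survived opening only as an artifact — and can be
disabled to reproduce the high-recall / low-precision regime in which
seed filtering is deferred to a human. Pipeline runs on phantoms raise
the floor to half the smallest expected soma volume, again derived from
the generator's parameters rather than tuned. Each instance is
summarized by its centroid (mean voxel position, um) and
equivalent-sphere radius.

On noisy volumes the detector deliberately over-reports: bright speckle
closes into soma-like blobs exactly as it does in real data. Downstream
stages tolerate this because spurious seed surfaces rarely coincide with
the foreground mask, so they seed little or nothing reachable.

## Cell segmentation by seeded fast sweeping

Arrival values from the soma surfaces are computed over the mask by fast
sweeping: 8 axis-ordering sweeps of a monotone local update, iterated
until the largest change drops below 1e-3 um. The local update is the
minimum of (a) the first-order Godunov upwind eikonal update on the
6-neighborhood with per-axis physical spacing and (b) direct step
candidates `u_n + |edge|` over the 26-neighborhood. The pure eikonal
update would overshoot the 26-neighbor graph distance at thin diagonal
corners (three voxels in an L: 2h versus sqrt(2) h); with the direct
candidates in the minimum, the converged field provably sits in the
envelope `Euclidean <= u <= Dijkstra-26`, equals the order-independent
Jacobi fixed point of the same update, and is independent of sweep
ordering. Speed is 1 everywhere — the field is used for reachability,
not path costs.

Unreached voxels are simply absent (stored as +inf internally) and a
linear scan prunes them; 26-connected components of the remainder are
the cell instances, annotated with their seeds (2+ seeds = a cluster).
An optional pre-sweep closing of the branch topology (radius 1 in
pipeline runs) bridges small path breaks at the documented risk of path
collisions between nearby branches.

## Skeletonization by local separators

Each instance surface becomes a graph (surface voxels as vertices at
voxel centres in um, edges between 26-adjacent surface voxels; built on
the instance bounding box so cost scales with the cell). Two passes of
light-edge matching coarsen it: contract a maximal matching preferring
the shortest edges (ties by vertex id) to weight-averaged midpoints.
Coarsening never changes the number of connected components and at most
halves the vertex count per pass.

Local separators are found by nearest-first ball growth: from a seed
vertex, grow until the wavefront splits into 2+ connected components,
return the ball, then greedily shed vertices (nearest to the seed first)
while the remainder still disconnects its neighborhood. Three details
make this robust on voxelized surfaces:

* front connectivity is evaluated on the band `front + its unvisited
  neighbors`, which bridges the one-voxel lattice dimples that
  momentarily disconnect a raw front on closed surfaces;
* during whole-surface collection, a front component only counts if it
  still has unexplored territory beyond the band — a ball sweeping a
  closed sphere splits trivially in its closing stage, and those splits
  are not separators (`find_local_separator` itself keeps the literal
  front-split semantics, where e.g. a star graph's hub is a valid
  separator with zero territory);
* the minimized set must also disconnect the component *globally*,
  which rejects remaining discretization artifacts.

Search seeds are taken centroid-outward so that tube mid-sections (cheap
splits) come before caps and tips (whole-surface sweeps), and every
vertex visited by any search is skipped as a future seed; this keeps the
total work near linear and spaces separators about one ball apart.
Candidates are packed greedily, smallest first, keeping a vertex-disjoint
subset.

Each packed separator becomes one node (weighted centroid; radius = mean
vertex distance to centroid, which for a ring around a tube estimates
the tube radius). Node connectivity comes from region growth: remove all
separator vertices, flood the remaining regions, and join two separators
that border a common region or touch directly. A region bordering
exactly one separator is a terminal cap — a branch tip or the soma bulb
beyond the last ring — and contributes its own node, so skeletons reach
the extremities; the soma cap node is what usually ends up as the root.
A surface with no separators at all (a bare sphere) collapses to a
single node.

One tree per seed: roots are the nodes nearest each seed centroid
(distinct, assigned by ascending distance), multi-source BFS assigns
every node to the first root that reaches it (never duplicated), parent
links follow the BFS. Type codes: root 1 (soma), everything else 3
(dendrite). `standardize` then re-indexes ids to 1..N parent-before-
child, merges coincident nodes (max radius), floors radii at half the
smallest voxel dimension, and is idempotent; multi-root tables are split
by `standardize_forest`.

Known limitation: on surfaces with genuine loops (path collisions fusing
branches), ring separators do not globally disconnect the surface and
are rejected, so looped sections carry fewer nodes; the BFS tree bridges
them through neighboring regions.

## Tree accuracy

Node matching between a gold and a test tree follows three criteria: a
Euclidean gate (default 8 um, the conventional branch-diameter-scale
threshold), a matching ancestor (some ancestor of the test node pairs
with some ancestor of the gold node within the gate), and path-length
agreement between node and ancestor on both sides (relative tolerance
0.2). Conflicts among surviving candidate pairs are resolved by a global
one-to-one assignment minimizing total distance (maximum cardinality
first) — resolving them in greedy distance order instead leaves nodes
unmatched purely because a neighbor claimed their candidate first, an
order artifact with no accuracy meaning.

The aggregate topology score weights matched gold *critical* nodes
(branch + terminal nodes, root excluded) by the number of terminals in
their subtree, normalized by the total; identical trees score exactly 1,
and deleting a subtree with k terminals costs exactly its summed weight.
The root is excluded from the critical set so that removing one of two
symmetric subtrees scores exactly 1/2. The decomposed suite reports
recall (all nodes), branch and leaf recall, direction (matched branch
nodes whose parent-pointing unit vectors agree in sign of dot product),
and precision; empty categories report not-applicable rather than NaN.
Cohort yield is the fraction of topology scores within 2 sample standard
deviations of the mean. Whole-forest scoring pairs each gold tree with
its best-scoring test tree (greedy one-to-one by descending topology),
so fragment trees rooted near a soma cannot displace the real
reconstruction. Seed detection is scored by greedy one-to-one matching
with a one-gold-radius tolerance.

## Synthetic phantoms

The generator emulates surface-labeled lightsheet data: somas as
spherical shells (radius 6–8.5 um, 2-voxel shell — interiors stay at
background), branches as solid capsules grown by a random recursive
process (2 trunks, depth-2 branching with probability 0.9 at ~40
degrees, segments 25–40 um, radii tapering 2.0 to 1.2 um), foreground
200 on background 10 (8-bit). Corruption applies, in order:
multiplicative sinusoidal stripes (amplitude 0.3, period 37 voxels —
deliberately incommensurate with dyadic wavelet scales — phase drifting
per slice), a bleach field (linear ramp 1.0 to 0.3 times a broad
Gaussian), the anisotropic PSF (sigma 1 / 2.5 um), and Gaussian noise
(sigma 4). Everything is reproducible to the byte from the spec seed;
centerlines are walked at a fixed 2 um arc step so the gold SWC sampling
density (default 6 um, comparable to reconstruction granularity) can be
changed without changing the drawn geometry. Optional distractor blobs
(radius 2.5 um, below the opening radius, so never seedable) exercise
reachability pruning. The default desk-scale volume is 256^3 at 1 um
isotropic with 3 neurons; tests use 96^3 as the small scale.

Runs against phantoms derive their configuration from the generator
instead of borrowing constants from real-data practice: the foreground
percent target is the fraction of voxels within one lateral PSF sigma of
true structure (the structure plus the halo over which the optics spread
its signal — a bare structure-count target starves thin distal branches
and breaks off their termini), the PSF parameters are the corrupting
ones, and the seed size floor is half the smallest soma volume.

What the phantoms do not show: real vasculature and autofluorescent
background, tissue-dependent stripe geometry, depth-dependent PSF
variation, or the severe inter-neuron collisions of densely labeled
tissue. Passing phantom benchmarks therefore demonstrates the pipeline's
mechanics (artifact removal, reachability, topology recovery), not
performance on any particular brain.

## Orchestration

`run_pipeline` executes enhance -> (optional z-downsample) -> convert ->
seeds -> segment -> skeletonize -> (optional benchmark), writing each
stage artifact plus a JSON manifest containing the stage parameters and
input content hashes; `resume` skips stages whose manifest matches, and
never mixes artifacts across configurations. Runs are single-process
and deterministic: identical input and config give byte-identical SWC
output (shortest round-trip decimal formatting). SWC positions are
`index * voxel_size` um, voxel-centre convention, x y z order, ids from
1, root parent -1.

Problem sizes used by the shipped test-suite: unit oracles run at
16^3–32^3; end-to-end checks run one neuron at 96^3 and the 256^3
three-neuron default across five generator seeds.
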