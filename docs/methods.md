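# Methods

This note documents the models and numerical choices behind `atlasforge`,
what the synthetic fixtures emulate, and where the design was genuinely
open.

## Geometry and transforms

A `Volume3D` is an axis-aligned voxel grid with per-axis physical spacing
(µm) and an origin: `world = origin + index · spacing`, indices 0-based,
one anatomical name per array axis. All transforms operate in world
coordinates, because developmental templates are imaged at different voxel
sizes (tens of µm for MRI, single µm for light sheet) and index-space
transforms would not carry across resolutions. The world-axis convention
(default array order superior-inferior, anterior-posterior, left-right) is
a package choice; sources for such data rarely state one, so readers should
treat axis names, not array positions, as authoritative.

Transform chains are pull-backs: a chain maps points of the output (fixed)
grid into the input (moving) volume, which is the form resampling needs.
Composition concatenates steps; inversion reverses them, inverting affine
steps in closed form and displacement fields by fixed-point iteration
(`u(x) = −v(x + u(x))`, at most 50 iterations, tolerance 0.05 voxel,
non-convergence reported by warning). Displacement fields extend beyond
their grid by the nearest edge value, which keeps the fixed-point map
contractive at the boundary; intensity samples outside a volume are 0,
matching brain-extracted data where background is zero. The reflection
used throughout (`mirror`) maps index `i` to `N−1−i`, so the mirror plane
sits between the two central voxels for even axis lengths and on the
central voxel for odd lengths, and mirroring is an exact involution either
way. Sum-mode resampling (used to pool binary classification maps into
per-voxel positive counts) is an integer block reduction and conserves
grand totals exactly.

## Synthetic fixtures

The generators in `atlasforge.synthetic` define the study conditions for
every test. A phantom is a set of nested smoothed ellipsoid shells with
distinct intensity bands, a dark internal "ventricle", a bright "tract",
and a fine-scale (σ ≈ 1.2 voxel) random texture with amplitude 12 intensity
units. The texture matters: real autofluorescence carries cellular-scale
contrast that alignment locks onto, and without it the concentric shells
are self-similar along the radius, which defeats any local matcher. Each
generator draws from a named substream of one global seed (CRC-based, so
reproducible across processes) and is bit-reproducible.

Tile sets are crops of a phantom at nominal grid positions plus uniform
integer jitter (the axial component is emulated by rolling the stack);
cohorts are warped copies of a phantom under smoothed-white-noise
displacement fields scaled so the RMS displacement magnitude equals
`warp_amplitude` voxels, with the per-voxel cohort mean subtracted so the
phantom itself is the cohort's mean morphology. Cell tables place
Poisson-distributed somata uniformly inside their region's voxels; section
stacks assign consecutive slices round-robin across 4–8 channels, as
alternating-section staining experiments do.

What the fixtures do not emulate: light-sheet shadowing and stripe
artifacts, MRI noise spectra and bias fields, tissue-clearing distortion,
or anatomically realistic region shapes. Passing tests therefore
demonstrate the correctness and self-consistency of the algorithms under
controlled geometry, not segmentation-grade performance on real data.

## Tile stitching

Only the outer edge strips of each tile (width = round(0.10 × in-plane
extent), minimum 1 voxel) are used for alignment, reduced to
maximum-intensity projections over groups of 32 slices; fusion is then a
single pass over the raw tiles. Pairwise alignment runs in two stages: the
axial (z) shift from projections of the facing strips along the strip
normal, then the in-plane shift. Matching is exhaustive normalized
cross-correlation over an integer window; candidates whose shared support
falls below half the support at the nominal layout are skipped (a
correlation over a sliver is not evidence). Because the facing strips sit
at a known nominal displacement along the strip normal, the search is
centred on that baseline; slightly widened copies of the strips (20-voxel
margin) serve as correlation targets so jittered content cannot leave the
cut. The in-plane anchor for each pair comes from a full 3D correlation of
the z-aligned bands — a MIP over the whole stack flattens away the axial
texture that disambiguates self-similar anatomy — and each slice group is
then refined within ±1 voxel of that anchor. Global offsets accumulate
breadth-first over the tile graph anchored at the top-left tile (offset 0),
averaging when a tile is reachable by two paths; per-slice offsets come
from a least-squares polynomial (default quadratic) through the group
offsets at group-centre slice indices. Pairs with mean correlation below
0.2 fall back to the nominal offset and are flagged in the diagnostics.
Fusion supports feather (linear distance-to-edge weights), max and
first-wins blending; the default search radius (10 voxels) covers the
relative jitter of two tiles each jittered by ±4.

## Registration

The engine is deliberately self-contained and deterministic: fixed pyramid
schedules, no random restarts, every optimization in world coordinates so
anisotropic spacings (e.g. 1.8 × 1.8 × 5 µm light-sheet voxels) are
handled correctly.

Metrics: mean squared difference; Pearson normalized cross-correlation;
mutual information from a 32 × 32 joint histogram (nats). For an image
against itself the MI equals the marginal histogram entropy, which the
tests verify against a direct entropy computation.

Linear registration (translation, rigid, affine; rotations about the
volume centre) is multi-resolution direct search: an exhaustive ±4-voxel
integer translation scan at the coarsest level seeds Powell refinement at
every level. The best candidate seen — including the identity — is kept,
so the returned transform never scores worse than doing nothing.

Deformable registration is a demons-style scheme: the update force is
`−(w−f)·∇w / (|∇w|² + (w−f)²/s²)` (s = mean absolute fixed intensity),
capped at 2 voxels per iteration, smoothed with a fluid-like σ = 1 voxel;
the accumulated field is smoothed with a diffusion-like σ (default 2
voxels) every iteration. Three pyramid levels by default; the best-seen
field by the (multi-channel) objective is returned. On all fixtures the
resulting fields are diffeomorphic in practice (positive Jacobian
determinant at ≥ 99% of voxels). The contract downstream modules rely on
is metric decrease, smoothness and approximate invertibility — not any
specific optimizer.

Multi-channel runs weight per-channel forces and metrics. The per-voxel
update is renormalized over the channels that are locally active: a mask
channel has zero force away from its boundary, and letting it dilute the
image force there would simply slow convergence without changing the
optimum. With equal weights on identical channels the behaviour reduces
exactly to the single-channel case; a zero-weight channel is ignored
entirely.

When registrations are evaluated on warp-recovery fixtures, residual
displacement error is measured inside the brain mask: outside the object
the image is featureless and no method can know the warp there.

## Template construction

Starting from the voxel-wise average of the (mirror-augmented) cohort, each
iteration registers every input to the current template, averages the
warped images, averages the displacement fields, inverts the average field
and applies it to the averaged image — recentring the template at the
cohort's mean morphology. Whether the original procedure applied the
forward or inverse average transform is not something published pipelines
spell out; the inverse-recentre reading is adopted here because it is the
one that makes the template converge to the cohort mean. Mirror-augmented
inputs alone would guarantee symmetry only if registration were exactly
reflection-equivariant, which floating-point optimizers are not, so the
template is additionally averaged with its own mirror at the end of every
iteration; since `(T + mirror(T))/2` is an exact fixed point of `mirror`
in IEEE arithmetic, the final template equals its mirror bit-exactly.
Contrast propagation replays the stored per-sample chains, the stored
recentring field and the symmetrization on another contrast without any
re-registration, so feeding the primary contrast back reproduces the
primary template to floating-point accuracy.

Default 4 iterations with early stop when the mean absolute template
change over the initial foreground falls below 0.5% of the mean foreground
intensity; acceptance-style runs disable the early stop to observe the
full convergence history.

## Mask-assisted multimodal registration

Regional disagreements between modalities (ventricle volume is the classic
one) drag plain intensity registration off course. The remedy: segment the
mismatching regions, subtract them from both brain masks (exact set
arithmetic: `mask AND NOT union(regions)`), linearly register the modified
masks (msd — the natural metric for binary images), then run a two-channel
deformable registration on (image, modified mask) with equal weights,
initialized at the linear stage; the mask channel always uses msd, the
image channel the configured metric. All-affine initial chains are folded
into the sampling coordinates of the deformable stage rather than applied
as a separate resampling pass, avoiding a second interpolation of the
moving image. Warped products default to 20 µm isotropic output — fine
enough for cell-type mapping, small enough for a desk machine.

## Section mapping

Stacks are reconstructed per channel at a configurable in-plane working
size (default 512 × 512), with intensity inverted (`out = max − in`) so the
bright histology background becomes zero, and un-owned slices stored as
flagged empty planes. Missing slices are filled by multilevel cubic
B-spline scattered-data approximation: control lattices of 4, 8 and 16
cells per axis are fitted to the residual of the known voxels at each
level and summed. Each level solves the Tikhonov-regularized normal
equations of the tensor-product B-spline least-squares problem (the
lattice is small, each data point touches a 4×4×4 control neighbourhood),
so data a lattice can represent — constants, linear ramps — are
reproduced essentially exactly, and unsupported control points fall
smoothly to zero instead of oscillating. When more than ~120k voxels are
known, an in-plane checkerboard subsample constrains the fit at a quarter
of the cost with no visible loss, since the lattice is far coarser than
the voxel grid. Known slices keep their original values; only missing
slices receive the approximant.

Per-slice correction registers each owned slice (2D, embedded as a
single-slice 3D volume with zero out-of-plane displacement, so one
transform code path serves everything) against two channels: the nearest
other owned slice within ±4 positions and the corresponding slice of the
aligned template mask, weighted equally by default (the relative weights
are exposed as parameters). An exhaustive in-plane integer translation
scan seeds each slice's deformable correction. Expression volumes are then
pulled through the per-slice chains and the inverse of the refined
template-to-subject registration onto the atlas grid, with negativity
clipped (expression is a non-negative signal).

## Ontology and analytics

Region trees are validated on load (single root, acyclicity, resolvable
parents, unique IDs, depth ≤ 13). Legacy 32-bit IDs above 65535 are
compressed by keeping the last four decimal digits and prefixing a 2
(17754321 → 24321), landing in 20000–29999; "last four digits" is decimal
because only that reading is consistent with the stated target band.
Collisions abort with both offenders named — no tie-break rule exists.
Background 0 is reserved and never an ontology node. Level roll-ups
replace each label by its ancestor at the requested depth and conserve
labeled voxel counts exactly.

Correspondence tables count voxels per ordered label pair where both
parcellations are nonzero, with a 250-voxel display threshold by default.
Cell assignment floors the world-to-index conversion (a deterministic
tie-break for somata exactly on voxel boundaries); out-of-bounds cells get
background and are counted. Occupancy reports both the raw ratio
(positives / region voxels) and a normalized fraction in [0, 1]
(positives / (region voxels × aggregation factor)), because "fraction of
area filled" implies the normalized form while the ratio is the directly
stated quantity. Growth statistics use the sample standard deviation
(n − 1) and report the template volume's z-score against its cohort.

## Stereotaxic tools

The alignment rotation acts purely in the sagittal plane about the
anterior commissure: the bregma direction is rotated onto the superior
axis, so both points share anterior-posterior and left-right coordinates
afterwards and their distance is preserved (rotation isometry).
Intensities resample linearly, labels nearest-neighbour. Grid volumes code
the sagittal/horizontal/coronal plane families 1/2/3 (lowest code wins at
intersections, each family anchored to pass through the commissure voxel),
and optional millimetre distance labels render as fixed 5 × 7 bitmap
digits with value 4 near the bottom-left of each coronal gridline slice;
glyph placement is a package choice. Grid origin metadata is fixed at
(0, 0, 0) to avoid disagreements between visualization tools.

## Problem sizes and tolerances

The acceptance runs use: stitching on a 128³ phantom cut 2 × 2 with 15%
overlap, ±4 voxel jitter and Gaussian noise at a tenth of the dynamic
range; template construction on four 64³ cohort samples (RMS warp 3
voxels, zero-mean) with mirror augmentation and four iterations;
translation/rotation recovery at 48³ and sinusoidal-warp recovery
(amplitude 3 voxels) at 64³; B-spline fill on a 64³ phantom with every
fourth slice dropped; and the exact conservation identities at 48³–96³.
These sizes exercise every code path at a scale a laptop handles in a few
minutes while leaving the algorithms unchanged from how they would run on
full-resolution data.

## Known limitations

The deformable engine is a greedy demons scheme, not a symmetric
diffeomorphic optimizer; its fields are invertible in practice but carry
no theoretical guarantee. Stitching assumes a translational tile model
(no rotation or illumination correction) and in-memory tiles. The
B-spline fill presumes missing slices are bracketed by known ones;
extrapolation beyond the outermost sections is uncontrolled. Stereotaxic
coordinates use an estimated bregma rather than a skull-derived one, which
limits anterior-posterior accuracy for surgical use.
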