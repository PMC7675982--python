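# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `meshstrain`, and what the synthetic validation does and does not
establish about real microscopy data.

## Coordinate and data conventions

All physical coordinates are micrometres with the origin at the frame
corner, `x` along the column axis and `y` along the row axis; positions are
reported at pixel centres and converted to micrometres by the pixel size.
Image series are `T(×Z)×Y×X` arrays with a scalar XY pixel size, an
optional z-step, and a frame interval `dt` in seconds (required for
movies).  Frame 0 — the mesh's as-applied state — is the zero-strain
reference everywhere; a different reference frame may be selected to
correct for deformation introduced while applying the mesh.

## Synthetic renderer (module `simulate`)

The renderer exists so every downstream stage can be validated against
exact kinematics.  A mesh is specified by pitch (node spacing), line
width, line counts, origin and orientation; deformation fields are
time-indexed planar maps `φ_t` with `φ_0 = identity`, plus an out-of-plane
stretch law `λ3(t)`:

- affine families: pure uniaxial (`λ2 = 1`), isotropic incompressible
  (`λ2 = λ3 = λ1^(-1/2)`), and compressible anisotropic with independent
  user-supplied `λ2(k)`, `λ3(k)` laws;
- oscillatory: sinusoidal displacement along a direction (default
  diagonal, so both line families move), uniform or per-x-region with
  periods and amplitudes per region.  Region weights are blended over half
  a pitch so the map never folds; the emitted ground-truth region masks
  use the unblended indicators;
- band-limited random warp: a sum of a few random plane-wave displacement
  modes, ramped linearly from zero.

Rasterisation: lattice centrelines are sampled densely (≤ 0.25 px
spacing), mapped through `φ_t`, and each pixel takes an intensity equal to
a clipped linear ramp of its distance to the nearest centreline sample
(half-pixel antialiasing of the ideal band of half-width `line_width/2`),
followed by a Gaussian PSF of σ = 0.5 px by default.  The experiments the
renderer emulates span widefield and confocal instruments whose exposure
models are not specified anywhere; this render model is a deliberately
simple stand-in, adequate because the pipeline's claims are geometric, not
photometric.  Noise is additive Gaussian (σ as a fraction of the
foreground amplitude) plus optional Poisson; noise requires an explicit
seed and rendering is byte-reproducible given one.  Fields are checked for
fold-over (non-positive Jacobian determinant) before rendering, and a mesh
leaving the frame is an error.

The out-of-plane stretch is never rendered — thickness is a rig-level
measurement in the experiments this emulates — and is emitted only as an
auxiliary per-step table, alongside exact node positions, per-frame
deformation gradients (affine fields) and per-region true frequencies.
Ground-truth construction asserts that the true cell-area ratio equals
`det F` for affine fields.

## Segmentation and node detection (module `segment`)

Binarisation is Otsu's threshold by default (a fixed threshold can be
configured), optionally after subtracting a rolling-ball-style background
estimated by grey opening; the threshold used is recorded for provenance.
Skeletonisation is topology-preserving thinning to a unit-width,
8-connected centreline.

Node candidates combine two cues:

1. **branch points** — skeleton pixels with ≥ 3 neighbours (T and X
   junctions);
2. **corner bends** — degree-2 pixels preselected by a local-PCA
   anisotropy test and confirmed by walking the skeleton a few pixels in
   both directions and requiring a turn sharper than 135°.  This is needed
   because the four outer corners of a lattice are bends, not branch
   points, yet they are real nodes.

Candidates are clustered within a line-width radius (capped at 0.4 pitch);
each cluster's peak is the candidate with the highest Euclidean distance
transform, ties broken by lower (row, col).  Detections closer than half
the pitch are merged, keeping the higher distance-transform score.

Subpixel refinement fits the incident line centrelines: skeleton pixels in
an annulus around the node are grouped by undirected arm direction, each
arm pixel is re-centred perpendicular to its arm by an intensity-weighted
centroid (bilinear sampling), a total-least-squares line is fitted per
arm, and the node is the least-squares intersection of the arm lines,
iterated twice from an intensity-centroid seed.  A plain windowed centroid
is biased by more than a pixel at boundary T-junctions (the window sees
three arms, not four); the intersection construction is unbiased for all
junction types and recovers noiseless node positions to ~10⁻³ px.  When
the local geometry is too sparse (very fine meshes), the annulus is
narrowed and, failing that, the centroid seed is kept.

For z-stacks, detection runs on the maximum-intensity XY projection and
each node's z is recovered as the intensity-weighted centroid across
slices in a window at the node.

## Lattice graph and tracking (module `lattice`)

Two nodes are paired iff a skeleton path connects them without passing
through a third node: the skeleton is partitioned into node
neighbourhoods (disks of ~1.5 line half-widths, capped well below the node
spacing) and residual arcs; an arc touching exactly two neighbourhoods
becomes a segment, and arcs touching fewer (broken lines) or more
(ambiguous loops) are skipped and logged for manual editing.  Manual pair
additions/removals are validated, applied to a copy, and appended to an
edit log; the cell enumeration is refreshed after edits.

Segments carry an x-like/y-like orientation label from the reference-frame
geometry; cells (the lattice's unit squares, stored counter-clockwise) are
enumerated by following each node's +x and +y neighbours and requiring the
two paths to commute — exact and deterministic for square lattices,
including deformed ones.

Tracking is greedy mutual-nearest-neighbour assignment between each
frame's detections and the last known position of every identity, accepted
within a gate of 0.45 pitch by default (no gate is prescribed by the
underlying experiments; displacements beyond half a pitch per frame are
fundamentally ambiguous for a periodic lattice, so faster motion needs
denser temporal sampling).  Unmatched identities are flagged missing —
strains over missing frames are reported absent rather than guessed —
with optional linear interpolation between flanking tracked frames (off
by default).  A frame losing more than half the identities raises a
tracking failure.

## Strain measures (module `mechanics`)

Segment strain is engineering strain `ε = l/l0 − 1` with stretch ratio
`λ = l/l0`, lengths Euclidean in 2D or 3D.  Element strain is the
Green-Lagrange tensor from a per-cell planar deformation gradient fitted
by least squares over the four edge vectors; this is exact for affine
deformation, robust to a single mislocalised node, and rotation-invariant
(rigid motion gives `E = 0` to machine precision).  Both measures are
reported side by side and never conflated; the stored `F` also permits an
infinitesimal-strain reading if a user prefers it.  The two measures are
linked on uniaxial deformation by `E_xx = ε + ε²/2`, which the tests use
as a cross-check between the two pipelines.

Segments with a reference length under 4 px are excluded from strain (the
node-localisation error would dominate); the floor is configurable.

Dilation is the per-cell area ratio, 1-centred by default with a
`ratio − 1` (0-centred) option — both conventions circulate and neither is
canonical.  Two estimators are provided: the shoelace area of the 4
tracked nodes (default), and a mask-projection variant that measures the
enclosed hole of each cell in the binary mesh mask, which also captures
bowing of the lines between nodes; the two agree within a few percent on
affine deformations.  Self-intersecting polygons are flagged and carry no
value.  Fractional shortening of a region is
`100 × (max − min)/max` of the summed cell areas over a time range.
Stress is `σ = E_mod · ε` only — no constitutive fitting.

The stretch-ratio summary reduces the segment table to per-step mean `λ1`
(x-oriented) and `λ2` (y-oriented), joins the auxiliary `λ3` series, and
reports the product `λ1λ2λ3`, the Pearson correlation and least-squares
slope of `λ3` on `λ2`, and correlations of microscopic vs macroscopic
strain where the macroscopic series carries them.

## Frequency mapping (module `frequency`)

Movies are block-mean downsampled (default factor 4) and Gaussian blurred
(default σ 1 px) to suppress noise; each pixel's intensity trace is
Savitzky-Golay smoothed (default window 9 frames, order 3), mean-removed
and Fourier transformed; power is the squared modulus and the dominant
frequency is the argmax over bins with `f > 0`, ties broken toward the
lower frequency.  None of these parameters is prescribed by the
experiments this emulates; all are configurable and recorded in the map's
provenance.  A pixel with no detectable oscillation reports 0 Hz with an
invalid flag, and the map is restricted to the mesh footprint at the
reference frame, then upsampled back to the original resolution by
nearest neighbour.

The FFT is taken at the native series length by default, so `N` frames at
interval `dt` put frequencies on an exact `1/(N·dt)` Hz grid — a 30 s
recording at 20 fps resolves 1.4 Hz exactly (bin 42 of Δf = 1/30 Hz).
Zero-padding to the next power of two is available (`pad="pow2"`) but is
not the default precisely because it shifts the bin grid off that natural
resolution.  Frequencies are bounded by Nyquist; the synthetic-movie
builder warns when a requested oscillation would alias or when fewer than
two full cycles are recorded.

## Validation fixtures and problem sizes

The test suite and `scripts/acceptance.py` use the coarse sensor geometry
(100 µm pitch, 10 µm lines, 5×5 lattice lines, 1 µm/px) for strain
fixtures: a 16-frame uniaxial series to 45 % in 3 % steps (noisy at 5 % of
foreground, and noiseless), and a 51-step compressible series with
`λ2 = 1 − 0.005k`, `λ3 = 1 − 0.0071k` (so the thickness-on-lateral slope
is 1.42 by construction) under an axial law `λ1 = 1 + 0.01k`.  Frequency
fixtures are small meshes oscillating diagonally with 3 µm amplitude:
30 s at 20 fps for the 1.4 Hz and two-region (1.3 / 0.6 Hz) movies, 240 s
at 2 fps for the one-contraction-per-12 s movie.  Unit tests use a 40 µm
pitch lattice for speed.  These sizes keep the full suite under a few
minutes on one CPU while leaving recovery errors far below the tolerances
being asserted.

## What the synthetic validation does not show

The renderer produces straight-line meshes, spatially uniform foreground,
flat backgrounds, Gaussian PSFs and additive/Poisson noise.  Real data add
autofluorescence and uneven illumination, mesh fibres that bow between
nodes and can tear or fold, out-of-focus light, photobleaching, and
surfaces that curve in z (here handled only via max-projection plus
per-node z recovery, which flattens strong curvature).  Passing the
synthetic suite therefore establishes the correctness of the geometry,
tracking, strain algebra and spectral analysis — not robustness to every
real-world imaging artefact; the manual pair-editing hooks and
configurable thresholds exist precisely because real data need them.

## Known limitations

- Tracking is positional only (no appearance model); contractions moving
  nodes more than the gate per frame require faster acquisition.
- Element strain is planar; on strongly curved surfaces the 2D projection
  underestimates in-plane stretch.
- The mask-projection dilation needs each cell's hole to be resolvable in
  the binary mask; very fine meshes at coarse sampling fall back to the
  node-polygon estimator.
- Stress estimates inherit all assumptions of the linear law and the
  supplied modulus.
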