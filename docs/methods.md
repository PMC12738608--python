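# Methods

## Problem and scope

`meshct` converts watertight triangle meshes — each tagged with a uniform
Hounsfield density and an integer overlap priority — into synthetic DICOM
CT series. The intended users are medical-physics researchers who need
controllable ground-truth CT data: QA phantoms, displacement phantoms for
registration validation, lesion phantoms for planning studies, and
cyclic-motion 4D series. Scene coordinates are interpreted directly as
patient LPS millimetres; grid index (i, j, k) maps to (+x left, +y
posterior, +z superior).

## Voxelisation model

The voxeliser is an adaptive two-pass parity ray-casting scheme.

**Grid.** The grid covers the combined vertex bounding box of the scene,
expanded by `padding` (default 0 mm), with `dims = ceil(extent /
spacing)` per axis so coverage is never truncated. Every voxel starts at
the background HU (air, −1000 HU by default).

**Inside test.** A point is inside a closed surface iff a ray from it
crosses the surface an odd number of times (even–odd parity). Rays are
cast along +x. For the bulk of the work the implementation exploits that
voxel-centre samples in one (y, z) column share a single ray line: each
structure's triangles are searched for candidate (triangle, line) pairs
by sorted-coordinate range queries, the crossing x of each pair is
evaluated with 2-D edge functions and barycentric interpolation, and all
samples in the column are classified at once by counting crossings to
their right (a keyed `searchsorted`). A per-structure BVH (median-split,
leaf size 8) serves arbitrary-direction ray queries through the same
index object.

**Degenerate casts.** A cast is numerically degenerate when the line
passes within a relative edge-function band (1e−9 of the projected
triangle area) of a triangle edge or vertex, when it lies in the plane of
a ray-parallel facet, or when a crossing falls within 1e−7 mm of a sample
point. Such samples are re-classified by a brute-force Möller–Trumbore
parity cast along a randomly perturbed direction (≤ 1e−3 rad, up to 3
retries, driven by the run seed). Degenerate casts are rare but real:
icosphere meshes, for example, carry facet rings exactly parallel to the
ray axis, and sub-voxel sample lattices can land exactly on their
equatorial edges.

**Two passes.** The first pass samples one point per voxel — the
geometric centre — and resolves overlaps by priority. Voxels whose HU or
winning-structure label differs from any face-adjacent (6-connected)
neighbour are marked boundary voxels; 6-connectivity is the minimal
neighbourhood that catches every face-crossing interface. Only boundary
voxels are re-sampled, on a cell-centred k×k×k lattice (default k = 3,
27 samples). The voxel HU becomes the arithmetic mean of the per-sample
resolved densities — an intrinsic partial-volume value. Samples outside
every structure contribute the background HU to the mean. Because
interior voxels of a homogeneous region are invariant under
supersampling, the adaptive result equals exhaustive supersampling of
every voxel (asserted exactly in the tests). k = 1 reproduces the
centre sample.

**Priority resolution.** Where structures overlap, the highest priority
wins; equal priorities break to the higher HU, which makes the output
independent of scene ordering. Background carries an effective priority
below any user value.

**Chunking.** The first pass runs slab-by-slab along z (`chunk_slices`,
default 8) purely to bound transient memory; outputs are bit-identical
for any chunk size (tested).

## Artefact simulators

All stages take and return volumes; a single integer seed drives the
stochastic stages through `SeedSequence` substreams.

- **Noise** — i.i.d. zero-mean Gaussian, `noise_std_dev` in HU.
- **Metal streaks** — per axial slice, every voxel above
  `metal_threshold` emits `num_angles` equally spaced in-plane rays;
  sample points stepped by the in-plane pixel pitch deposit
  `streak_intensity · exp(−streak_attenuation · r)` into the nearest
  voxel out to `streak_max_radius`. Deposits accumulate additively
  (streaks are strictly bright before clipping), so streak amplitude
  scales with the size of a connected metal blob — document-level
  choice, since each supra-threshold voxel is an independent source.
  The exponential decay is a one-parameter stand-in for physical
  attenuation.
- **Partial volume** — 3-D Gaussian blur (`scipy.ndimage.gaussian_filter`),
  sigma in voxels (isotropic in index space; `pve_sigma_from_mm`
  converts), reflect boundary mode to preserve local means near edges.
- **Rings** — per slice, `intensity · sin(2π · frequency · r / R)` about
  the shared slice centre, with R half the smaller in-plane extent so
  `frequency` counts rings across the radius.
- **Clip** — all values limited to [−1024, 3071].

Stage order is metal → partial volume → ring → noise → clip:
deterministic detector/reconstruction effects are layered before
stochastic noise, and clipping runs last so noise excursions cannot
escape the encodable range. The order is overridable via
`ArtefactParams.order`. Out of scope by design: scatter, beam hardening,
sinogram-domain simulation, tube-parameter (kV/mA) modelling.

## DICOM encoding

Unsigned 16-bit stored pixels, RescaleSlope 1, RescaleIntercept −1024 —
the 12-bit clinical CT convention, maximally compatible with TPS
importers. HU must lie in [−1024, 3071]; export rounds to the nearest
integer, so integer-valued HU round-trip bit-exactly and fractional
partial-volume values round-trip as `rint(hu)`. Geometry: axial identity
orientation, Head-First-Supine, ImagePositionPatient at the centre of
the first transmitted voxel (`bbox_min + spacing/2`), PixelSpacing =
(row, column) = (y, x) spacing. 4D series write each phase as its own
series under one study and frame of reference — the common layout for
4D-CT exports — tagging every slice with TemporalPositionIndex and
NumberOfTemporalPositions. UIDs are generated under a configurable
private root; dates default to export wall-clock unless pinned in the
config.

## Phantoms

Dimensions are declared package defaults chosen at anatomical scale (no
canonical values exist for these constructions):

- **Lung phantom** — body cylinder r = 120 mm stretched ×1.4 laterally,
  200 mm tall, 0 HU (water), priority 0; two lung cylinders r = 40 mm,
  150 mm tall at ±60 mm laterally, −200 HU, priority 1, translated along
  SI by the requested offset; optional metal sphere r = 5 mm, 2000 HU,
  priority 2, midway between the lungs. The ±10 mm offset pair provides
  a 20 mm SI displacement ground truth.
- **Lesion phantom** — head ellipsoid (80, 95, 105) mm at 0 HU; a 6 mm
  skull shell (outer semi-axes (70, 85, 95) mm) at 1000 HU, built as one
  mesh of two nested surfaces so the parity test classifies exactly the
  inter-surface region as inside; a solid brain ellipsoid at 200 HU
  (priority 1); three lesion spheres r = 8 mm at 250 HU, priority 2,
  fully inside the brain. This exercises every priority tier.
- **Breathing phases** — phase p scales designated structures by the
  cyclic profile a(p) = amplitude·sin²(πp/n). The local stretch grows
  linearly from the cranial plane (fixed) to the caudal plane, so
  displacement grows quadratically toward the diaphragm — a one-parameter
  surrogate for diaphragm-dominant respiratory motion. The AP axis is
  treated the same way about the posterior plane (supine patient, back
  fixed). Defaults: SI amplitude 0.10, AP amplitude 0.03 of the
  respective extents — at lung-phantom scale roughly 15–20 mm diaphragm
  excursion, a typical quiet-breathing magnitude. Phase 0 is the base
  scene bit-exactly and phase n wraps to phase 0. A lattice-based
  free-form deformation is out of scope.

What these phantoms do *not* emulate: tissue heterogeneity (every
structure is uniform by design), realistic organ shapes, bronchial
trees, cardiac motion. Passing tests therefore demonstrate correctness
of the geometry → HU → DICOM chain, not anatomical realism.

## Numerical choices

- Vertex merge tolerance 1e−6 mm on load (well below any clinical voxel
  size; removes STL facet duplication). Non-watertight meshes are
  loadable — parity may misclassify, surfaced via `check_watertight` —
  rather than rejected.
- Grid dimension computation subtracts 1e−12 before `ceil` so
  exact-multiple extents do not gain a voxel to round-off.
- Edge-band width 1e−9 (relative), length tolerance 1e−7 mm, ray
  perturbation ≤ 1e−3 rad: the band is far below mesh feature scales, so
  false flags are rare and every flagged sample is resolved robustly.
- `ray_intersections` deduplicates edge-band hits by position: a ray
  grazing an edge shared by two triangles reports one crossing.

## Problem sizes

The verification suite voxelises the lung phantom at 2.5 mm
(135×96×80 voxels), the lesion phantom at 2 mm (80×95×105), sphere
convergence series down to 1.25 mm, and a ten-phase 4D lung phantom at
5 mm; these sizes keep a full run in the order of a minute on one CPU
while leaving every measured quantity at its target resolution.

## Known limitations

- Uniform HU per structure; no texture or gradient fill.
- Artefacts are image-domain approximations, not physics simulations.
- Non-watertight input gives best-effort parity results.
- The breathing model deforms by axis scaling only; it does not bend or
  slide structures.
- CPU only; the scanline batching makes typical phantoms fast (seconds),
  but very high-polygon meshes at sub-millimetre spacing will be slow.
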