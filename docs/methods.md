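# Methods

This note documents the models and algorithms implemented in `dermapa`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic phantoms do and do not establish.

## Data model

A sample is a 4D PA intensity array indexed `(slice, depth z, lateral x,
wavelength)` plus a 3D US array on the same spatial grid. Index `z = 0` is
the surface side and z grows downward; the slice axis is the mechanical scan
direction. Geometry defaults: slice spacing 0.5 mm (the scan step of the
modeled acquisition), axial pitch 0.05 mm, lateral pitch 0.06 mm. The axial
pitch is taken equal to the instrument's quoted axial resolution (50 µm); the
lateral pitch is finer than the quoted 110 µm lateral resolution so that a
millimetre-scale lesion spans enough pixels for contour metrics to be
meaningful on desk-scale grids — pixel pitch and physical resolution are
distinct quantities, and geometry is always user-suppliable. The spectral
axis is strictly increasing and evenly spaced; the default sweep 680–970 nm
in 5 nm steps (59 lines) is the only range arithmetically consistent with a
59-wavelength acquisition at 5 nm steps. Samples are exchanged as single
HDF5 files (`/pa`, `/us`, `/axis`, `/geometry`, optional `/truth`).

## Background segmentation

Assumption: tissue scatters US strongly, the saline bath does not. Each US
cross-section is thresholded with Otsu's between-class-variance criterion
(256 bins). For strongly bimodal histograms the variance curve is flat
across the inter-mode gap and the argmax falls on the gap's lower edge,
where the background mode's tail leaks through; the threshold is therefore
re-centered by intermeans (ISODATA) iterations — `t ← (μ₀ + μ₁)/2` to a
fixed point — which preserves the variance-maximizing partition while
placing the cut mid-gap. The binary map is smoothed by morphological closing
then opening (disk, radius 2 px) and only the largest connected component
per slice is kept, which also discards bright artifacts (gel bubbles,
transducer plastic) detached from the sample. A slice with no histogram
contrast is flagged empty rather than guessed. Thresholding is per slice by
default (`per_slice=False` switches to one volume-wide threshold). The mask
transfers to the PA volume; in-mask spectra are never altered.

## Label generation

All in-mask pixel spectra of the whole 3D volume are pooled and split by
K-means with k = 2 (k-means++, 10 restarts, tolerance 1e-6, seeded). Raw
unstandardized spectra are clustered on purpose: the discriminating signal
is absolute amplitude, and standardization would destroy it. The cluster
with the higher mean total intensity is named *non-healthy* — melanin makes
tumor brighter — which makes the naming invariant to the arbitrary cluster
order different seeds produce. Clustering is volume-pooled, never per slice:
a tumor is not expected to extend through the whole biopsy, and per-slice
clustering would invent a tumor in every slice.

The margin: every healthy pixel whose in-plane Euclidean distance (computed
by an anisotropy-aware distance transform, axial × lateral pitch) to the
nearest non-healthy pixel is ≤ 0.5 mm becomes *unlabeled*. Non-healthy
pixels are never eroded. A depth-only margin mode exists
(`in_plane=False`); in-plane is the default because the boundary
uncertainty around a lesion is a 2D halo, not a purely vertical band.
Training data is an exactly class-balanced uniform draw without replacement
(default capped at 1000 spectra per class — ample for a ~3 k-parameter
network while keeping single-CPU training in seconds); every spectrum keeps
its flat voxel index as provenance.

## Per-pixel classifier

One model per sample, trained only on that sample's spectra: inter-patient
spectral variability never enters. The network is deliberately small —
conv(16 filters, kernel 9) → ReLU → maxpool(2) → conv(32, kernel 5) → ReLU →
global average pooling → dense(16, ReLU) → dense(1, sigmoid) — roughly 3 300
parameters for a 59-sample spectrum. Kernel widths are constrained to odd
values in [3, 15]: wide enough not to latch onto single-wavelength noise,
narrow enough to keep the melanin slope visible. Training: Adam (lr 1e-3),
batch 32, binary cross-entropy, ≤ 200 epochs with early stopping on a 20 %
validation split (patience 20, min-delta 1e-4 — the min-delta matters on
separable data, where validation loss otherwise creeps down indefinitely);
best-epoch weights are restored. Inputs are standardized per wavelength with
statistics fit on the training set only and stored in the model, which
conditions optimization while preserving the inter-class amplitude contrast
in the learned weights. All randomness (init, split, shuffling) flows from
one seed; identical seeds reproduce the training history bit-exactly. The
implementation is plain numpy (forward and backward passes hand-written);
it is exercised by a permutation-null control: training on shuffled labels
must yield chance-level validation accuracy.

Classification: `p ≤ 0.5` → healthy, `p > 0.5` → non-healthy (the tie goes
to healthy, matching the inclusive 0–0.5 healthy interval). Pixels already
labeled by clustering keep their cluster label; the network decides only the
withheld margin band. Probabilities are still computed everywhere so the
cluster map and the network map can be compared.

## Thickness

Per slice and per lateral column, the longest contiguous vertical run of
non-healthy pixels; slice extent = max over columns, overall thickness =
max over slices × axial pitch. Contiguity (rather than a bounding box) is
the default because a detached misclassified speck deep in the sample must
not inflate the depth; a `bounding_box=True` flag provides the alternative
reading. Thickness is reported both from the classifier map and from the
rasterized contours (the two can differ by a pixel or two at the rim); the
classifier-map value is the primary depth estimate. Cohort agreement is
summarized by the Pearson product-moment correlation and the residual span;
zero-variance inputs yield an explicitly undefined correlation.

## Sandpile energy landscape

The normative toppling rules of this package (the literature description is
qualitative, so these rules are declared, not derived):

* Pour `γ·p` sand on every tumor-classified pixel (γ = 10).
* A non-sink pixel with height `H > h_crit` (h_crit = 1) topples its
  **entire** height in equal quarters to its 4 direct neighbours.
* Healthy-classified pixels are sinks of capacity c = 2: they absorb
  arriving sand up to remaining capacity and hold none — overflow topples
  onward (threshold 0).
* Background pixels and the ring just outside the grid absorb without
  limit; their intake is booked in the absorbed ledger, so conservation
  `Σpour = ΣH + Σabsorbed` holds exactly on every run (checked to 1e-9).
* Sweeps are parallel (all supercritical pixels topple simultaneously);
  iteration stops when the total moved mass falls below 1e-12 of the pour
  or at `max_sweeps` (10 000), in which case `converged=False` is returned
  rather than raising. Sub-tolerance dust wandering between exhausted sinks
  is booked as absorbed at the end so the footprint stays clean.

Toppling the entire height (not just the excess over `h_crit`) is what makes
an isolated speck vanish *identically to zero* when its neighbours' combined
capacity covers its mass; an excess-only rule would always leave `h_crit`
behind. A consequence worth knowing: inside a large coherent region the
final heights are uneven and edge pixels adjacent to exhausted sinks can
retain slightly more sand than interior ones. Downstream stages consume only
the *significant footprint*: connected components of positive sand whose
total mass reaches at least one `h_crit` unit (sub-critical residues of
almost-erased specks are noise on the landscape's own scale).

With the defaults, a speck at p = 0.9 pours 9 units against 4 × 2 = 8 units
of direct-neighbour capacity, leaving a 0.25-unit sub-critical residue at
the fixed point; full erasure to exactly zero needs the immediate
surround's capacity to cover the mass (e.g. c = 3). Both regimes are tested
against an independent hand-written scalar simulator of the same rules.

## Active contour

One closed snake per slice (single connected tumor assumed; multi-component
footprints are flagged and bridged by one hull). Initialisation: convex hull
of the significant footprint, dilated by 1.5 px, resampled uniformly by arc
length at ~1.5 px spacing (8 ≤ n ≤ 200). Energy:

    E = Σᵢ [ α (|vᵢ₊₁ − vᵢ| − d̄)² + β |vᵢ₊₁ − 2vᵢ + vᵢ₋₁|²
            + λ_g |vᵢ − c|² ] − κ Σᵢ R̃(vᵢ)

with d̄ the initial mean vertex spacing, c the centre of mass of the
landscape, and R̃ the bilinear interpolation of the external field.
Defaults: α = β = 0.01, λ_g = 1e-3, κ = 4.

Two deliberate choices differ from the most obvious formulation:

* The homogeneity term penalizes deviation from the mean spacing rather
  than raw segment length. Raw `|Δv|²` rewards vertices bunching up, which
  produces near-degenerate segments and self-touching polygons.
* The external field is, by default, the **rim** of the landscape: the
  Gaussian gradient magnitude (σ = 1 px) of the binary significant
  footprint, normalized to max 1. A pure height attraction (`external=
  "height"`, also implemented) exerts no force on the flat interior of a
  stabilized pile, so any positive gravity weight collapses the contour to
  the centre of mass; the rim field instead creates a potential well along
  the tumor boundary that holds the contour there against the weak inward
  pull. The binary footprint (not the raw heights) is used because the
  uneven residual heights inside the pile would drag the ridge off the rim.

Evolution is greedy and discrete: each pass visits every vertex, evaluates
the 8 one-step moves of a 3×3 neighbourhood (step 1 px, halved twice after
stalls for sub-pixel refinement), and accepts the best strictly
energy-decreasing move that keeps the polygon simple. Simplicity is
enforced twice: a fast vectorized proper-crossing test, then an exact
validity check on the winning candidate (the fast test cannot see
measure-zero self-touches, which arise naturally on a half-pixel lattice).
A minimum vertex spacing of 0.5 px prevents degenerate segments. Because
only improving moves are accepted, the energy trace is non-increasing by
construction; the run stops when a full pass moves nothing at the finest
step (or at 300 passes).

## 3D reconstruction

Between consecutive non-empty slices, each contour is converted to an exact
signed distance field (point-to-polygon distance, negative inside — computed
geometrically rather than from a rasterized mask, which would bias radii by
half a pixel), the fields are blended linearly at
`round(slice_spacing/target) − 1` intermediate positions (default target
0.1 mm), and each intermediate contour is the blend's zero level set.
Contours at measured positions are carried through verbatim. The stack is
extruded by half a slice spacing beyond the terminal slices so the dense
model covers the same scan-axis extent as a voxel model of the coarse grid
(N slices at spacing Δ ↦ length N·Δ). Volume is voxel count × voxel volume
after per-slice polygon fill; the surface mesh comes from marching cubes
over the zero-padded voxel mask and is watertight whenever ≥ 2 dense slices
are non-empty. Gaps where intermediate slices have no contour are not
bridged. This interpolation is deterministic, geometric, and intended for
visualization and volume estimates; it has no learned component.

## Phantoms

The generator emulates exactly the structure the method assumes:

* tissue slab below a flat surface (surface at 0.2 mm), saline elsewhere;
  US contrast tissue 100 : background 2 with 8 % multiplicative noise;
* a superellipsoid tumor (exponent 3) touching the surface; default
  half-axes 1.1 mm (scan) × 0.6 mm (depth) × 1.4 mm (lateral);
* tumor spectrum `A_t (λ/694)^{-k}` with k = 3 (melanin-like power law,
  referenced to the conventional 694 nm point), healthy spectrum a gentle
  linear slope (−0.2 across the sweep) around amplitude `A_h`; contrast
  `A_t/A_h` defaults to 3;
* an amelanotic rim: over the outer 0.2 mm of the tumor the melanin
  fraction ramps linearly from 0 at the boundary to 1 inside, measured to
  the lateral/deep boundary only — a melanoma is pigmented where it meets
  the surface, and an all-faces ramp would make lesions shallower than the
  rim invisible by construction, contradicting the generator's own premise
  that tumor pixels are brighter;
* multiplicative Gaussian noise `(1+ε)`, ε ~ N(0, 0.1), plus a small
  half-normal additive floor (0.01), clipped at zero; optional exponential
  depth attenuation (default off).

Ground truth (tumor mask, tissue mask, maximum contiguous vertical extent,
voxel volume) is exact and recomputable from the masks. Cohorts assign
depths evenly across the configured range (0.2–1.0 mm by default, the span
of clinically typical Breslow depths for thin melanomas) in seed-shuffled
order, so the extremes always equal the bounds; per-sample noise seeds
derive deterministically from the master seed.

What phantoms do **not** emulate: acoustic speckle, fluence inhomogeneity
and spectral coloring with depth, hemoglobin or other chromophore bands,
rough or tilted surfaces, multi-focal lesions. Passing the phantom suite
demonstrates that the pipeline recovers known structure under its own
assumptions; it is not evidence about clinical data.

## Study conditions and problem sizes

Desk-scale defaults used by the test suite and the acceptance script: grid
6 slices × 48 depth × 96 lateral × 59 wavelengths; 10-phantom cohorts,
depths 0.2–1.0 mm, contrast 3, noise 0.1, rim 0.2 mm; classifier capped at
1000 spectra per class. One full pipeline run takes on the order of 15 s on
a single CPU; the acceptance script a few minutes.

## Known limitations

* The sandpile and snake parameters are normative declarations of this
  package, exposed in `SandpileParams`/`ContourParams`; other
  parameterizations of the same qualitative scheme would give different
  (not obviously worse) boundaries.
* The greedy snake finds a local optimum; with the rim field and hull
  initialisation this is reliable for convex-ish single lesions but
  concave pockets narrower than the hull bridge are not recovered.
* Thickness from the classifier map systematically underestimates the
  geometric truth by roughly half the amelanotic rim width on rim
  phantoms — the spectral boundary genuinely sits above the geometric one.
  On clinical data the analogous statement is that the method measures the
  pigmented depth.
* Depth resolution equals the axial pitch; sub-pixel depth is not
  estimated.
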