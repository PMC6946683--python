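# Methods

This note records the models, estimator definitions, numerical choices and
known limitations of `glycomesh`. Coordinates are nm, right-handed, z = 0
at the microvillar tip plane, z increasing toward the gut lumen; bounding
boxes are half-open.

## The structural model the generator emulates

The enteric glycocalyx is modeled as a columnar filament brush:

- **Tip anchors.** Microvillar tips sit on a triangular lattice
  (`microvillus_spacing`, default 100 nm — a brush-border packing scale
  chosen as a convention; the paper-grade measured quantities below do not
  depend on it directly) with 10% lateral jitter and Gaussian height
  variation `layer_thickness_sd` (default 100 nm). Height variation lives
  in the *base* topography so that the terminal plane can stay flat while
  thickness profiles still vary: thickness = (flat terminal plane z) −
  (local anchor z) ~ N(1000, 100) nm, matching the measured 1.0 ± 0.1 µm
  layer.
- **Filaments per tip.** Rounded Gaussian, mean 7, sd 1.5, clipped at
  ≥ 1 — the measured count distribution.
- **Terminal plane.** A single plane at `layer_thickness` with flatness sd
  `terminal_plane_sd` (2 nm). Termini positions come from the regime
  generators below; globular tip diameters are N(10.2, 1.2) nm.
- **Filament paths.** Each filament is a polyline from its anchor to its
  terminus, discretized at `step_nm` (15 nm) in z. Lateral coordinates
  reach the terminus position within the lower 35% of the rise — filaments
  interlace almost immediately after emerging — and carry independent
  per-node lateral excursions of sd `zigzag_amplitude` (12 nm). The rough
  (node-independent) zigzag matters: a smooth wander produces columnar
  side views with elongated void slots, whereas the observed mesh requires
  neighboring filaments to approach each other every few tens of nm.
- **Lateral contacts.** Candidate node pairs of different filaments within
  `contact_capture_radius` (20 nm) are snapped to their midpoints (each
  node at most once, so contacts stay coincident) and subsampled to
  `contact_rate` contacts per µm of filament (default 12/µm, roughly what
  the candidate geometry supplies). Together with the zigzag this yields a
  mean side-view opening of ~32 nm at default parameters, i.e. the
  generator defaults are calibrated to the measured ~29 nm mesh up to the
  final `calibrate_mesh` scaling.
- **Core diameters.** N(5.3, 1.3) nm clipped at ≥ 2 nm; the platinum
  replica coating is a uniform shell (`coating_thickness`, 2.0 nm — a
  package convention, not a measured value).
- **Merging.** A `merge_fraction` of filaments (default 0) merges onto a
  host filament's path in the top 30% of the layer; merging also happens
  naturally when the local termini supply is exhausted. Merged filaments
  share their host's exact upper path, which is why resolution-limited
  counting (`filaments_per_tip` with `dedup_tolerance > 0`) undercounts —
  the same reason replica counts underestimate mucin numbers.

### Terminal-plane packing regimes

- `hexagonal`: triangular lattice + isotropic Gaussian jitter
  (jitter ≤ 0.1 × spacing by convention);
- `liquid_crystal`: the same with larger jitter (default 4 nm at 32 nm
  spacing, which keeps ψ6 in the liquid-crystalline band — the measured NN
  sd of ~8 nm reflects regional regime variation across a tissue, not the
  displacement amplitude of a single quasi-ordered patch);
- `liquid`: Matérn type-II hard-core thinning of a Poisson proposal with
  fixed dimensionless proposal density λ·d² = 2 (≈ 25% disc packing).

**Spacing calibration contract.** `mean_spacing` is the *target mean NN
spacing*, not the lattice constant. The generator maps it through a
dimensionless factor f(regime, jitter ratio) = (mean NN)/(length
parameter), estimated once per regime/ratio from a ~4,000-point
unit-parameter simulation with a fixed internal seed and cached. Jitter is
applied self-similarly (ratio × lattice constant) so the factor is exact
under rescaling; zero-jitter lattices use f = 1 exactly. Empirical
recovery is within ~1% at n ≥ 1,000 (3% contract).

**Mesh calibration.** The pore size of the zigzag network has no closed
form, so `calibrate_mesh(target)` scales all lateral length parameters by
a common factor found by secant iteration on the measured mean opening of
large calibration networks (internal fixed seeds), then records the
ground-truth pore size as the mean over all openings of two further
calibration networks. Recovery experiments compare freshly seeded networks
against that recorded ground truth.

## Estimator definitions and numerics

- **Nearest neighbor.** Reference points within `edge_buffer` of the
  lateral boundary are excluded; all points remain candidate neighbors.
  The buffer always applies to x/y; a z side thinner than four buffers is
  exempt so quasi-planar 3D patterns keep their reference set. Histogram
  binning is Freedman–Diaconis; the Gaussian is fit to the histogram by
  least squares (the histogram-overlay convention), not by MLE.
- **RDF.** Border correction: references lie ≥ r_max from the boundary,
  all points count as neighbors; normalization by global density gives
  g → 1 for CSR (asserted in tests). First peak = first local maximum of
  the 3-bin-smoothed g that (a) exceeds 1 plus half the peak prominence
  and (b) has ≥ 5 supporting pairs, refined by 3-point quadratic
  interpolation with ties broken toward smaller r. The floor and support
  conditions exist because on finite samples the literal "first local
  maximum above 1" is claimed by noise wiggles or by single close pairs
  whose tiny shell areas inflate g.
- **Autocorrelation.** The pattern (projected to 2D if 3D) is rendered at
  `render_px` (default 1 nm/px), smoothed with a 1.2 px Gaussian,
  autocorrelated by FFT with 2× zero padding, radially averaged in 1 px
  annuli; the first off-origin local maximum past the central peak's
  minimum, subject to a 25%-prominence floor, is reported with quadratic
  refinement. A single-point pattern returns NaN with a warning flag.
- **ψ6 and regime call.** Delaunay neighborhoods; convex-hull vertices are
  excluded as references (their neighborhoods are boundary artifacts, and
  excluding them makes a perfect lattice read ψ6 = 1 to machine
  precision). Thresholds 0.35/0.70 separate liquid / liquid-crystalline /
  hexagonal; they are conventions calibrated on the generator and
  overridable. The FFT sixfold ratio is the best sixfold comb of azimuthal
  power at the first-order ring over the azimuthal mean.
- **Pore size.** Side-view projection mode: filaments inside a lateral
  slab (60 nm) are drawn at their core diameters onto a 1 nm/px image over
  the mid-layer z range (0.3 × layer to layer − 50 nm; the near-anchor
  region holds inter-microvillar splay gaps that are not part of the
  mesh). Enclosed openings are watershed basins of the void's distance
  transform (neck depth 2 px, border-touching basins skipped): a compact
  void is one basin, while a long irregular corridor decomposes into the
  locally identifiable pockets an annotator would select. Each opening's
  size is its max caliper (convex-hull diameter of pixel centers) plus one
  pixel (half-pixel surface offset on each side), i.e. the maximal
  surface-to-surface distance between the filaments outlining it. On
  designed grids every cell is a single basin, the size equals the cell
  diagonal, and the estimator agrees with a brute-force all-pairs oracle
  to < 1%. A 3D void mode was considered and not built: the caliper
  definition (not the inscribed sphere) is what reproduces the
  designed-grid diagonal identity, and the projection mode mirrors
  side-view replica-montage measurement practice. The measured sd
  (~16 nm) remains tail-heavier than the reported ±10 nm; only the mean
  is contract-tested.
- **Filament diameter.** For labeled volumes the outer diameter is the
  area-equivalent circle diameter of the central cross-section; a
  max-inscribed-circle reading via the distance transform carries a
  systematic ≈ 1.5-voxel negative bias from center sampling and would
  fail its own 1-voxel round-trip contract. Core = outer − 2 × coating;
  non-physical (≤ 0) values are excluded with a warning, > 10% of them
  raises a coating-model error.
- **Permeation.** Obstacle = filament axis voxels dilated by the mean core
  radius (per-filament spread ~0.6 nm, below one voxel) plus termini
  spheres near the terminal plane (computed on a 150 nm top slab — their
  influence does not reach deeper). One Euclidean distance transform per
  (voxel, domain) gives a clearance field cached across probe radii;
  probe-accessible voxels are clearance ≥ r, connectivity is 6-connected
  components. Probes are seeded at uniform surface positions and enter
  through the nearest accessible surface pore within a lateral capture
  disc of radius (Stokes radius + termini spacing/2) — the slack a
  diffusing probe has above the surface before committing to a pore; this
  makes entry fractions independent of voxel size (a strict one-voxel
  entry column would couple the result to the discretization). Voxel
  default: min(probe radius/2, min core radius, 1 nm). Because probes are
  rigid spheres while dextrans are flexible coils, the simulated exclusion
  curve is sharper than experiment; on the default calibrated network the
  transition sits between ~8 and ~16 nm probe radius, with ~1 nm probes
  fully penetrating and ≥ 35 nm probes fully excluded.

## Seeding and reproducibility

A single master seed drives a run; every stage draws from a named child
stream (CRC-labeled `SeedSequence`), so adding or removing a stage never
perturbs the others, and identical config + seed give byte-identical
serialized outputs. The run manifest hashes the config, seed and stage
list (timestamps excluded). Internal calibration simulations use their own
fixed seeds and are part of the definitions, not of user randomness.

## Problem sizes used in the shipped tests

Tests and the acceptance script use desk-scale versions of the study
conditions: termini patterns of ~600-1,700 points (n ≈ 1,200 analyzed for
the headline spacing recovery), networks of 54-460 tips, 51 rasterized
cross-sections at 0.5 nm voxels, permeation domains of 120-200 nm lateral
extent through the full ~1 µm layer at 0.6-1 nm voxels, and 101-opening
pore samples — the sample sizes at which the original statistics are
quoted, which is what the 2-SEM recovery bands are defined against.

## What passing tests do and do not show

The generator reproduces the *statistics* the estimators consume (spacing
distributions, packing order, mesh scale, count/diameter/thickness
distributions, a percolating void space). It does not model image
formation (platinum shadowing beyond a uniform shell, replica granularity,
missing-wedge artifacts), filament mechanics under flow, charge or binding
effects in permeation, dextran flexibility, or the quasi-periodic filament
substructure. Recovery of ground truth on synthetic data validates the
estimator implementations and their edge handling; it does not by itself
validate segmentation or coordinate extraction from real tomograms, which
are out of scope.
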