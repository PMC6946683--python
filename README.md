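# glycomesh

Quantitative morphometry of the enteric glycocalyx — the micrometre-thick
brush of transmembrane-mucin filaments that covers intestinal microvilli —
driven by a synthetic structural model so that every estimator can be
tested against known ground truth.

Freeze-etch electron tomography shows this layer as a columnar network:
rod-like filaments (core diameter ~5.3 nm) emerge from microvillar tips
(~7 per tip), interlace through zigzagged lateral contacts into a ~30 nm
mesh, and terminate in a single flat plane of ~10 nm globular tips spaced
~32 nm apart with packing between hexagonal-crystalline and liquid. The
architecture behaves as a deformable size-exclusion filter: small solutes
(Stokes radius ~1 nm) reach the absorptive surface while large ones
(~27 nm and above) are excluded. `glycomesh` implements the measurements
behind those numbers — and the generative model needed to validate them —
for researchers quantifying brush-like filament coats in EM data.

## What it computes

**Termini spacing and order** (on 2D/3D point patterns, coordinates in nm):

- nearest-neighbor statistics: per point *i*, `d_i = min_{j != i} ||x_i − x_j||`,
  with border-buffer edge exclusion, histogram and least-squares Gaussian
  overlay;
- radial distribution function `g(r)` with border edge-correction
  (`g(r) = counts(r) / (n_ref · λ · shell(r))`), first-peak spacing by
  3-point quadratic interpolation;
- image-autocorrelation spacing (FFT of the rendered pattern, radially
  averaged, first off-origin maximum);
- sixfold bond-orientational order
  `ψ6 = |⟨ ⟨exp(6iθ_jk)⟩_{k ∈ N(j)} ⟩_j|` over Delaunay neighborhoods,
  an FFT sixfold-spot ratio, and a packing-regime call
  (hexagonal / liquid-crystalline / liquid).

On disordered patterns the NN mean (a per-point *minimum*) sits below the
RDF and autocorrelation peaks (*average* spacings) — the package preserves
and tests that ordering.

**Network morphometry**: mesh/pore size (max caliper of enclosed openings
in side-view renderings), filament diameter with platinum-coating
correction (`core = outer − 2·coating`), layer thickness profiles,
filaments-per-tip counts from cross-sections, globular-tip diameters.

**Size-exclusion permeation**: rigid-sphere probes of given Stokes radius
versus the rasterized network; static void percolation (distance-transform
clearance thresholding + connected components) yields the fraction of
probes reaching the microvillar tip plane and a depth profile, i.e. an
in-silico dextran-exclusion curve.

**Synthetic generator**: a parametric glycocalyx (anchors, filament
polylines, contacts, termini) whose defaults are the measured statistics
above; it provides the calibrated ground truth all tests recover.

## Worked example

```python
import glycomesh as gm

pattern = gm.generate_termini_pattern(
    "liquid_crystal", 32.0, 4.0, extent=((0, 1200), (0, 1200)), seed=7)
nn = gm.nearest_neighbor_stats(pattern, edge_buffer=40.0)
rdf = gm.radial_distribution(pattern, bin_width=1.0, r_max=100.0)
order = gm.hexagonal_order(pattern)
print(f"NN spacing: {nn.mean:.1f} +/- {nn.sd:.1f} nm (n = {nn.n})")
print(f"RDF first peak: {rdf.first_peak_r:.1f} nm")
print(f"psi6 = {order.psi6:.2f} -> {order.regime_call}")

net = gm.generate_network(gm.GeneratorParams(), seed=3, n_tips=54)
pores = gm.pore_sizes(net, n_openings=101, seed=0)
thick = gm.layer_thickness(net, n_profiles=53, seed=0)
sec = gm.cross_section(net, float(net.anchors[:, 2].max()) + 30.0)
counts = gm.filaments_per_tip(sec)
print(f"pore size: {pores.mean:.0f} +/- {pores.sd:.0f} nm (n = {pores.n})")
print(f"layer thickness: {thick.mean/1000:.2f} +/- {thick.sd/1000:.2f} um (n = {thick.n})")
print(f"filaments per tip: {counts.mean:.1f} +/- {counts.sd:.1f} (n = {counts.n})")
```

prints

```
NN spacing: 31.9 +/- 4.5 nm (n = 873)
RDF first peak: 39.9 nm
psi6 = 0.53 -> liquid_crystal
pore size: 30 +/- 19 nm (n = 101)
layer thickness: 0.98 +/- 0.09 um (n = 53)
filaments per tip: 7.1 +/- 1.3 (n = 54)
```

The termini pattern was generated with a ground-truth mean NN spacing of
32 nm and the estimator recovers 31.9 nm; the RDF peak lands higher
(39.9 nm) because it measures the average characteristic spacing rather
than the per-point minimum. The 54-tip network recovers its generative
parameters: ~7 filaments per tip, ~1 µm layer, pore mean in the ~30 nm
range (the pore sd carries the long upper tail of projected openings).

A command-line interface mirrors the library
(`glycomesh simulate-network`, `simulate-termini`, `analyze-termini`,
`analyze-network`, `permeate`, and config-driven `run` with a
reproducibility manifest); point tables are CSV (`x_nm,y_nm[,z_nm][,tip_id]`),
networks are JSON, volumes are MRC2014.

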