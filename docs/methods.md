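# Methods

## Units and data model

Canonical internal units are Å, kcal/mol and kcal/(mol·Å); unit converters
exist only at the I/O boundary (`read_npz_bundle` factors). A
`ConfigurationSet` assumes constant topology — a fixed atom count and order
across frames — because every analysis (per-atom projection, per-element
decomposition, descriptors) indexes atoms consistently across frames;
trajectories violating this are rejected at load. Frame indexing is
0-based with half-open ranges.

The extended-XYZ dialect accepted is the dominant community one: a
`Properties=species:S:1:pos:R:3[:forces:R:3]` column declaration, a
case-insensitive `energy=` comment key, and unknown comment keys preserved
as opaque metadata. Plain 4-column XYZ (optionally with three trailing
force columns) is accepted as a fallback. A `Lattice` key, if present, is
carried verbatim but never interpreted; periodic systems are otherwise out
of scope, as are MD-engine binary formats.

## Error conventions

Per atom and frame, two scalars are defined from ΔF = F_pred − F_ref:

- `component_mae` (default): mean over the three Cartesian components of
  |ΔF|. Chosen as default because the atom-count-weighted mean of
  per-element MAEs then equals the all-atom MAE *identically* (partition
  identity), keeping per-element tables consistent with overall numbers.
- `vector_norm`: |ΔF|₂; used for per-atom visualization exports and the
  dummy (reference-magnitude) mode, where the displayed quantity is the
  reference force norm itself.

RMSE always uses the squared quantity matching the convention (mean
squared component, or squared norm), so `rmse ≥ mae` holds for every
selection by Jensen's inequality and mean-squared errors recombine across
disjoint partitions. Energy errors are per molecule (kcal/mol), stored
signed; summaries take absolute values.

Whether plotted per-element densities should use component errors or norms
is a genuinely open convention choice; both are exposed, with
`component_mae` as the default for the reasons above. Force distributions
are sampled per atom, energy distributions per frame.

## Densities, timelines, outliers, distribution comparison

- KDE: Gaussian kernels; default bandwidth Scott's rule h = σ·n^(−1/5)
  (no convention is forced by the analyses themselves); grid spans
  [min − 3h, max + 3h] so curves integrate to 1 within 1%. Degenerate
  (all-equal) samples are rejected with a pointer to histograms.
- Timelines: centered moving average whose window truncates at the series
  edges — length-preserving, no padding artifacts. The window is a free
  parameter (default 25 frames in the audit pipeline; long MD datasets
  warrant windows of a few thousand frames).
- Outlier flags on correlation scatter: |residual − median| >
  k·(1.4826·MAD), default k = 4. The MAD rule is deliberately simple
  plumbing — outlier inspection is ultimately visual/structural — but it
  is translation-invariant and exact under a single gross corruption.
  Note that under strongly heterogeneous error scales (a mixture of
  Gaussians) the flag count is naturally large; k controls this.
- Training-set representativeness: histogram intersection of
  probability-mass histograms on a shared 50-bin grid over the pooled
  range, plus the two-sample Kolmogorov–Smirnov statistic, computed for
  force-norm, energy and gyradius samples.

## Two-stage clustering

Stage 1 (structure): Ward-linkage agglomerative clustering, Euclidean
metric, on the upper-triangle pairwise interatomic-distance vector of each
frame (rotation/translation invariant; atoms labeled, no sorting).
Inverse-distance descriptors are available but off by default. Stage 2
(energetics): within each structural group, KMeans on the group's
*reference* energies (not energy errors — the split is about which energy
regimes a structure group spans). The final budget, 40 clusters by
default, is apportioned to structural groups proportionally to their size
by largest-remainder rounding with a floor of one cluster per group and a
cap at the group's number of distinct energies; the structural default is
10 groups. The 40-total/10-structural split is a package choice — the
source tooling this emulates reports totals of both 40 and 50 in
different places and never specifies the stage split — and both knobs are
exposed.

Seeds fix KMeans initialization. For > 5000 frames, stage 1 runs on a
seeded uniform 5000-frame subsample and the remainder is assigned to the
nearest structural centroid (agglomerative clustering is quadratic in
frames). Requests exceeding the number of distinct frames are reduced with
a warning. Per-cluster summaries (size, mean force error, mean |energy
error|) come from whatever error table is supplied; when several models
audit one dataset the assignment is computed once and re-summarized per
model, so cluster profiles are directly comparable across models.

Representative frames of a cluster are the k nearest to its descriptor
centroid, ties broken by frame index — fully deterministic.

## Geometry

Gyradius is mass-weighted by default (standard atomic weights from the
element symbols); the unweighted variant is exposed since either
convention appears in practice. Angles are reported in [0°, 180°];
dihedrals follow the IUPAC sign convention in (−180°, 180°], with
collinear triples rejected as undefined.

## Synthetic data

The generator plants known statistical structure so that every analysis
stage has a ground truth:

- Geometry: `n_basins` reference structures separated by ≥ `basin_scale`
  (RMS per-atom displacement along mutually orthogonal random directions),
  visited in contiguous blocks, with isotropic Gaussian jitter of
  `thermal_scale` per frame. Defaults (basin_scale 2.0 Å, thermal_scale
  0.1–0.12 Å) keep basins well separated (> 3× jitter) at roughly
  thermal-fluctuation amplitudes.
- Energetics: harmonic wells, E = k/2 Σ|r − ref|² + offset·basin with
  k = 50 kcal/(mol·Å²) (typical bonded-interaction stiffness order),
  forces the exact analytic gradient. Harmonic energetics are chosen
  because the analyses under test audit error bookkeeping, not dynamics
  realism: energies and forces stay analytic and cheap, no integrator
  needed.
- Folding: an optional global compactness factor oscillating with period
  `fold_cycle` scales the reference geometry, so the gyradius oscillates
  like a folding/unfolding fatty-acid chain.
- Errors: predicted force components are reference + bias +
  N(0, σ_element × basin factor × atom factor); energies get N(0,
  energy_noise). The half-normal expectation E|N(0, σ)| = σ√(2/π) links
  planted σ to expected MAE; per-element contrasts are recovered within
  5% at ≥ 200 frames.

Two named suites mirror common audit scenarios: `stachyose_like`
(C₂₄H₄₂O₂₁, 87 atoms, 500 frames, three basins, a designated 9-atom
"linkage" subset with 1.5× error scale) and `dha_like` (C₂₂H₃₂O₂, 56
atoms, 600 frames, six basins phase-locked to a fold cycle so the
odd/folded basins carry 3× errors). These sizes keep full audits in the
seconds range on one CPU while leaving per-element samples in the
10⁴–10⁵ range, tight enough for 5–10% recovery tolerances.

What the generator does *not* emulate: anharmonicity, realistic
vibrational spectra, conformational kinetics, correlated (non-isotropic)
model errors, and systematic energy drifts. Passing tests therefore
demonstrate that the bookkeeping — decompositions, identities, planted
contrast recovery — is correct, not that any real force field behaves
like the fixtures.

## Numerical choices and degenerate inputs

- Empty frame/atom selections raise rather than returning silent zeros.
- Cluster profile ordering is stable: ascending error, ties by cluster id.
- Writing an empty subset produces a zero-frame file with a warning.
- extXYZ floats are written at full precision (`%.17g`), so write→read
  round trips are exact to floating-point.
- PDB B-factors are clamped to the fixed field width (two decimals,
  ≤ 999.99).
- The prediction cache refuses fingerprint mismatches (dataset name,
  frame/atom counts, predictor id) instead of silently reusing stale
  arrays.

## Repository shape

The pipeline is presented statsmodels-style: `ForceFieldAudit` (model,
constructed from data, with a `from_files` constructor) → `fit()` →
`AuditResults` (estimates, `summary()`, exporters). The underlying
operations remain available as plain functions in `trajio`, `predictors`,
`metrics`, `clustering`, `geometry` and `synthetic`; the CLI is a thin
shell over `run_audit`.

## Known limitations

- No periodic-boundary awareness: distance descriptors and gyradius use
  raw Cartesian coordinates.
- The distance descriptor is O(n_atoms²) per frame; fine for molecules of
  hundreds of atoms, not for condensed-phase cells.
- Outlier flags are univariate and scale-global; heteroscedastic errors
  inflate counts (tune k or inspect per element).
- Training subsets are accepted as input, never generated; no
  training-point selection method is included.
- Model wrappers for specific MLFF packages are out of scope; anything
  satisfying the two-member predictor contract plugs in.
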