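# Methods

This note documents the engine's data model, algorithms, numerical choices
and defaults, and what the synthetic fixture data does and does not emulate.

## Data model

An `OmicsContainer` holds named *features × samples* assay matrices (dense
`numpy` arrays or any `scipy.sparse` matrix), a per-feature table
(`row_data`) and per-sample table (`col_data`) whose indexes supply the
ordered, unique feature and sample identifiers, and named *samples × dims*
embeddings (≥ 2 columns). Validation is structural: every assay must be
(n_features, n_samples), tables must match, identifiers must be unique.

On disk, assays and embeddings are headerless delimited numeric files (or
MatrixMarket for sparse assays) and metadata tables are delimited with a
header row and identifier first column; a JSON manifest maps slots to
relative paths. Identifiers always come from the metadata tables; matrix
files are assumed row/column aligned with them (dimension checks still
apply, misalignment within matching dimensions is the caller's
responsibility). Dense values are written at 17 significant digits and read
with round-trip float parsing, so a write/load cycle preserves values
exactly; the container's content hash is computed dtype-insensitively
(numeric columns as float64) so it survives text round trips.

## Variable kinds

A plotted variable is *continuous* if its values are numeric (booleans
excluded), otherwise *categorical*. Numeric variables are never silently
reinterpreted as factors regardless of how few distinct values they have; an
explicit declaration (`declared="categorical"`, or `categorical_cols` in the
manifest) forces factor treatment. Categorical levels follow first
appearance in the data, except explicit `pandas.Categorical` columns, which
keep their declared category order. Ordinal variables are treated as
categorical; their ordering information is not otherwise used. Missing
values never contribute levels; points with missing plotted values are
dropped from that plot with a logged count.

## Geometry dispatch and layouts

With axis kinds (x, y):

| x           | y           | geometry                                    |
|-------------|-------------|---------------------------------------------|
| continuous  | continuous  | scatter                                     |
| categorical | continuous  | vertical violin                             |
| continuous  | categorical | horizontal violin                           |
| categorical | categorical | rectangle; mirrored bar if either has 1 level |

**Violins.** Each level occupies integer lattice position 0, 1, …; points
get uniform jitter with half-width 0.4 level widths on the categorical
axis. Outlines are Gaussian kernel density estimates (Silverman bandwidth)
evaluated at 64 grid points between the level's min and max, scaled to
maximum half-width 0.4; levels with fewer than two distinct values get no
outline. Jitter is constant-width rather than scaled to the outline — a
deliberate simplification, since selection semantics depend only on jitter
bounds, not outline shape.

**Rectangle plots.** The plane is an L×M lattice of unit cells indexed by
level order. The combination with count n_ij gets a square centred in its
cell with side √(f_ij / f_max) cell widths, where f_ij = n_ij/n; relative
areas are then exactly proportional to frequencies and the modal
combination fills its cell. With a single-level variable the plot collapses
to bars along the multi-level axis (width 0.8 cells), extending
symmetrically about the single level's cell centre with full length
proportional to count. Points are scattered uniformly strictly inside their
combination's rectangle/bar.

**Per-point determinism.** All placement randomness comes from a stream
seeded by `blake2b(seed, point_id)`, so placement is reproducible,
independent of point insertion order, and adding or removing points never
moves the others.

## Downsampling

`downsample_points` partitions the bounding box into resolution² equal bins
(points on the maximum edge fall in the last bin) and keeps the first `cap`
points per bin in index order — bounding visible points by roughly
resolution²·cap while every occupied region stays represented. The first
point attaining each bounding-box extreme is additionally always retained:
this pins the box, hence the grid, and makes the operation exactly
idempotent (without it, dropping an extreme point re-bins the survivors and
a second pass would thin further). Defaults: resolution 200, cap 1.
Downsampling removes non-retained points from the rendered spec, so a brush
on a downsampled panel can only capture retained points — matching what is
on screen.

## Colormaps

A colormap is either a *count form* (asked for n colours, returns n) or a
*named form* (a fixed level → colour map). The registry resolves
per-variable entries first, then a shared (slot, kind) default, then the
global kind default, which always exists. Defaults are frozen literals: a
12-colour qualitative cycle (recycled with a warning beyond 12 levels) and
the 256-step viridis ramp. Categorical assignment colours levels in level
order; a named map missing a level present in the data is an error.
Continuous assignment calls the map at resolution 256 and maps each value
linearly between the *observed* min and max of the plotted vector (per-plot
contrast; the index is ⌊frac·255 + 0.5⌋, a constant vector maps to the
first ramp colour). Missing values are `#AAAAAA` and excluded from legends.
Duplicate colours from count-form maps are accepted (routine for 256-step
ramps after 8-bit rounding). Session configs declare colormaps as data
(palette literals, named maps, or builtin names) — never executable code.

## Selections and linking

Brushes are axis-aligned rectangles, inclusive on all four bounds (so a
degenerate brush can still select a coincident point). Lassos are closed
polygons; membership uses the even–odd ray-casting rule with boundary
points counted inside (an explicit on-segment test precedes the ray cast).
Selections are stored as shapes in display coordinates and re-captured
whenever upstream specs change, so replays and re-seeded jitter recompute
membership exactly; only *included* (not restricted-out, not downsampled)
points are capturable.

Links form a directed acyclic graph over live panels, checked at insertion:
plot→plot links require matching point domains (sample-based: metadata,
feature-assay, embedding, heatmap; feature-based: feature-metadata plots and
row tables) and carry restrict or highlight semantics; row tables transmit
semantically (colour variable, feature-assay y-axis, heatmap feature set);
feature-metadata plots can subset row tables; heatmaps receive only.

Propagation walks panels in lexicographic topological order. A receiver's
effective restriction is the **intersection** of all restrict-transmitters'
captured sets — the natural gating semantics when several selections feed
one panel; the equally defensible union was rejected to keep chained
restriction monotone. A transmitter with no active selection imposes no
constraint, but an *empty capture restricts to zero points* (faithful set
semantics, with a logged warning) rather than being ignored. Restricted-out
points remain in the spec flagged `included=false` with finite placeholder
coordinates, while geometry statistics (violin outlines, rectangle areas,
bar lengths) are computed over included points only; highlight edges leave
inclusion alone and re-colour non-selected points grey at opacity 0.3.
Because evaluation order is fixed by panel ids, results are independent of
the order links were added.

## Session state and code tracking

An `AppState` captures panels (with layout sizes), links, selections at full
float precision, the declarative colormap specification, the container
manifest reference, and the master seed. Serialization is canonical JSON —
sorted keys, compact separators, explicit version — so equal states are
byte-identical documents and `serialize ∘ restore` is the identity.
Restoration validates every reference (panel variables, link endpoints,
selection sources) and rejects unsupported versions.

`emit_plot_code` writes a self-contained Python script: a preamble loading
the container and registry, one delimited block per panel rebuilding its
configuration and selection, the link list, and a `replay(out_dir)` entry
point that re-propagates with the stored seed. Replay equality — the script
reproducing every live spec byte-for-byte — is enforced by tests over
randomized sessions.

## Synthetic fixture data

`make_example_container(n_features, n_samples, n_clusters, seed)` emulates a
small clustered expression study: samples get balanced cluster labels
(round-robin, shuffled); each feature draws a base log-mean from N(2, 1);
per cluster, 10% of features are markers whose log-mean shifts by N(2,
0.5); counts are log-normal (σ = 0.5) rounded to integers, with
`logcounts = log2(counts+1)` alongside; `col_data` carries the true cluster
label (explicit factor) and the continuous library size; `row_data` carries
mean log-expression and detection counts; a 2-D embedding places samples at
cluster centres drawn from N(0, 5²) plus N(0, 0.6²) noise, giving clearly
separated clusters (mean within-cluster distance ≪ between-cluster).
Everything derives from one `numpy` generator, so equal seeds give equal
containers.

What it does **not** emulate: batch effects, doublets/outliers, mean–
variance relationships of real counts, dropout structure, or unbalanced
cluster sizes. Tests passing on this fixture therefore demonstrate the
engine's *mechanics* (dispatch, linking, reproducibility), not robustness to
real-data pathologies.

## Problem sizes and runtime choices

The test fixture is 60 features × 40 samples × 3 clusters; the demo and the
acceptance script use 200 × 120 × 4. Randomized contracts run at: 1,000
random categorical pairings (rectangle layout), 500 polygons × 100 points
(lasso vs an independent computational-geometry oracle), 200 random panel
graphs (≤ 8 panels, ≤ 12 edges) against a naive fixpoint re-evaluator, 10⁵
points for downsampling invariants, and 100 randomized sessions for the
serialize/replay contract. These sizes make the whole suite run in well
under five minutes on a single CPU while leaving each property's failure
modes (off-by-one binning, boundary exclusion, order dependence) plenty of
room to surface.

## Known limitations

* No HDF5/disk-backed assays; containers live in memory.
* The optional rendering of specs to images is plumbing, not a tested
  contract; the canonical artifact is the JSON spec.
* Violin jitter ignores outline width (see above).
* Multiple-transmitter semantics (intersection) and boundary-inclusive
  selection are design choices a particular interactive tool might make
  differently; both are documented and property-tested as specified here.
* Cross-version state migration is limited to an explicit version check.
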