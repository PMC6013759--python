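# omicspanels

A headless, fully testable engine for linked multi-panel exploration of
rectangular omics data sets — the computational core of an interactive
explorer, without the browser.

High-throughput experiments (bulk and single-cell RNA-seq, proteomics, mass
cytometry) are naturally described by a *features × samples* container: one
or more assay matrices plus per-feature (`rowData`) and per-sample
(`colData`) metadata tables and optional low-dimensional embeddings (PCA,
t-SNE). Exploring such data means looking at several views at once —
an embedding, a metadata plot, expression of a chosen gene, a heatmap — and
*linking* them: brushing a region of the t-SNE and asking what those cells
look like everywhere else. `omicspanels` implements exactly that machinery
as a deterministic library: every view resolves to a JSON plot
specification, every selection is an explicit geometric object, and every
session can be replayed bit-for-bit.

## What the engine does

* **Data model** — an `OmicsContainer` holding named assay matrices (dense
  or sparse), metadata tables, and embeddings, dimension-validated against
  ordered unique feature/sample identifiers; plain-text file I/O
  (CSV/TSV/MatrixMarket + a JSON manifest); a seeded generator of clustered
  count-like fixture data.
* **Geometry dispatch** — for axis variables *x*, *y* with kinds
  continuous/categorical: (cont, cont) → scatter; exactly one categorical →
  vertical/horizontal violin with jittered points (|jitter| ≤ 0.4 level
  widths); (cat, cat) → rectangle plot where the rectangle for level
  combination (i, j) has area ∝ n<sub>ij</sub>/n, collapsing to a mirrored
  bar plot when a variable has one level.
* **Colormaps** — a registry of colour-map functions resolved by precedence
  (per-variable > per-slot-and-kind default > global kind default), with a
  frozen 12-colour qualitative cycle and a 256-step viridis ramp as
  defaults; continuous values map linearly between the observed min and max.
* **Linked selections** — rectangular brushes and closed lassos in display
  coordinates (even–odd rule, boundary-inclusive); a directed acyclic
  transmitter → receiver graph; receivers restrict to (or merely highlight)
  the intersection of their transmitters' captured points, so chains of
  links reproduce flow-cytometry-style sequential gating. Row tables
  transmit semantically: the selected row drives a receiver's colour
  variable, a feature-assay plot's y-axis, or a heatmap's feature set.
* **Density-dependent downsampling** — grid thinning that bounds the number
  of rendered points while keeping every occupied bin (and the bounding
  box) represented; idempotent by construction.
* **Code tracking** — sessions serialize to canonical, versioned JSON, and
  the engine emits a runnable Python script (one block per panel) whose
  execution regenerates every panel's spec byte-identically.

## Worked example

```python
from omicspanels import make_example_container, write_container, default_registry
from omicspanels import PanelConfig, build_plot_spec
from omicspanels.demo import demo_state
from omicspanels.tracking import evaluate_state

container = make_example_container(n_features=200, n_samples=120, n_clusters=4, seed=1)
manifest = write_container(container, "demo_container")

panel = PanelConfig("qc", "column_data", x_var="cluster", y_var="total_count")
spec = build_plot_spec(panel, container, default_registry(), seed=1)
print("geometry:", spec.geometry)
print("violins:", [(s["level"], s["n"]) for s in spec.shapes])

state = demo_state(container, str(manifest), seed=1)
specs = evaluate_state(state, container)
print("selected feature:", state.selections["table"].shape.feature)
print("embedding gate ->", len(specs["metadata"].included_ids()), "samples")
print("metadata gate  ->", len(specs["heatmap"].data["samples"]), "samples in heatmap")
```

prints

```
geometry: violin_vertical
violins: [('C1', 30), ('C2', 30), ('C3', 30), ('C4', 30)]
selected feature: G0007
embedding gate -> 30 samples
metadata gate  -> 3 samples in heatmap
```

The categorical `cluster` against the continuous library size dispatched a
vertical violin plot with one violin (of 30 samples each) per cluster. The
demo session then selects feature `G0007` in the row table (driving the
feature-assay y-axis and the embedding's colouring), brushes the first
cluster's region of the t-SNE (30 samples pass the gate into the metadata
plot), and brushes low library sizes there — only the 3 samples surviving
both gates reach the heatmap.

The same workflow is available from the shell:

```sh
omicspanels simulate --n-features 200 --n-samples 120 --n-clusters 4 --seed 1 --out sim/
omicspanels validate sim/manifest.json
omicspanels render session.json --out out/   # writes specs + state + reproduce.py
```

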