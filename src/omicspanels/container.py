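"""Rectangular omics data container and its file-backed I/O.

The central object is :class:`OmicsContainer`, the in-memory analogue of a
SummarizedExperiment: one or more features x samples assay matrices, a
per-feature metadata table (``row_data``), a per-sample metadata table
(``col_data``) and zero or more samples x dims embeddings (``reduced_dims``).
Feature and sample identifiers are carried by the metadata table indexes and
every slot is dimension-validated against them.

Also here: variable-kind classification (continuous vs categorical, driving
plot-geometry dispatch downstream), feature annotation URLs, and the seeded
synthetic fixture generator used throughout the test-suite and demos.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._canonical import canonical_dumps

logger = logging.getLogger(__name__)

__all__ = [
    "VariableKind",
    "CONTINUOUS",
    "OmicsContainer",
    "ContainerValidationError",
    "LookupError_",
    "classify_variable",
    "get_feature_values",
    "annotation_url",
    "make_example_container",
    "load_container",
    "write_container",
    "DEFAULT_URL_TEMPLATES",
]


class ContainerValidationError(ValueError):
    """A slot violates the container's dimensional or uniqueness invariants."""


class LookupError_(KeyError):
    """A named assay, variable, feature or sample does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


# ---------------------------------------------------------------------------
# Variable kinds
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class VariableKind:
    """Classification of a plotted variable.

    ``kind`` is ``"continuous"`` or ``"categorical"``; categorical kinds carry
    their ordered ``levels`` (first-appearance order, or declared category
    order for explicit factors).
    """

    kind: str
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.levels) == 0:
                raise ValueError("categorical kind requires non-empty levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError("categorical levels must be unique")
        elif self.levels:
            raise ValueError("continuous kind carries no levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"

    @property
    def n_levels(self) -> int:
        return len(self.levels)


CONTINUOUS = VariableKind("continuous")


def classify_variable(values, declared: str | None = None) -> VariableKind:
    """Classify a vector of values as continuous or categorical.

    Numeric vectors are always continuous, irrespective of how few distinct
    values they contain; pass ``declared="categorical"`` to force factor
    treatment (levels then follow first-appearance order of the distinct
    values). Text, boolean and explicit pandas-Categorical vectors are
    categorical; Categorical dtype keeps its declared category order, all
    other inputs derive levels in first-appearance order. Missing values are
    ignored for level derivation.
    """
    series = values if isinstance(values, pd.Series) else pd.Series(values)
    if len(series) == 0:
        raise ValueError("cannot classify an empty vector")
    non_missing = series.dropna()
    if len(non_missing) == 0:
        raise ValueError("cannot classify an all-missing vector")

    if declared not in (None, "continuous", "categorical"):
        raise ValueError(f"unknown declared kind {declared!r}")

    if isinstance(series.dtype, pd.CategoricalDtype):
        present = [lvl for lvl in series.cat.categories]
        return VariableKind("categorical", tuple(present))

    is_numeric = pd.api.types.is_numeric_dtype(non_missing) and not pd.api.types.is_bool_dtype(non_missing)
    if declared == "continuous":
        if not is_numeric:
            raise ValueError("non-numeric vector cannot be declared continuous")
        return CONTINUOUS
    if is_numeric and declared != "categorical":
        return CONTINUOUS

    if pd.api.types.is_bool_dtype(non_missing):
        vals = [str(bool(v)) for v in non_missing]
    else:
        vals = list(non_missing)
    levels: list = []
    seen = set()
    for v in vals:
        if v not in seen:
            seen.add(v)
            levels.append(v)
    return VariableKind("categorical", tuple(levels))


# ---------------------------------------------------------------------------
# The container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OmicsContainer:
    """Assays plus feature/sample metadata tables and embeddings.

    Parameters
    ----------
    assays
        Named features x samples numeric matrices (dense ndarray or any
        scipy.sparse matrix). At least one assay is required.
    row_data
        Per-feature table; its index supplies the feature identifiers.
    col_data
        Per-sample table; its index supplies the sample identifiers.
    reduced_dims
        Named samples x dims embeddings (>= 2 columns each).
    """

    assays: dict
    row_data: pd.DataFrame
    col_data: pd.DataFrame
    reduced_dims: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- identifiers --------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.row_data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.col_data.index]

    @property
    def n_features(self) -> int:
        return len(self.row_data)

    @property
    def n_samples(self) -> int:
        return len(self.col_data)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.assays:
            raise ContainerValidationError("container must hold at least one assay")
        nf, ns = self.n_features, self.n_samples
        for ids, what in ((self.feature_ids, "feature_ids"), (self.sample_ids, "sample_ids")):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ContainerValidationError(f"duplicate {what}: {dupes}")
        for name, mat in self.assays.items():
            if mat.shape != (nf, ns):
                raise ContainerValidationError(
                    f"assay {name!r} has shape {mat.shape}, expected ({nf}, {ns}) "
                    f"from row_data/col_data"
                )
        for name, emb in self.reduced_dims.items():
            emb = np.asarray(emb)
            if emb.ndim != 2 or emb.shape[0] != ns:
                raise ContainerValidationError(
                    f"reduced_dims {name!r} has shape {emb.shape}, expected ({ns}, >=2)"
                )
            if emb.shape[1] < 2:
                raise ContainerValidationError(
                    f"reduced_dims {name!r} needs >= 2 columns, has {emb.shape[1]}"
                )

    # -- accessors ----------------------------------------------------------
    def assay(self, name: str):
        if name not in self.assays:
            raise LookupError_(f"unknown assay {name!r}; available: {sorted(self.assays)}")
        return self.assays[name]

    def reduced_dim(self, name: str) -> np.ndarray:
        if name not in self.reduced_dims:
            raise LookupError_(
                f"unknown reduced_dims entry {name!r}; available: {sorted(self.reduced_dims)}"
            )
        return np.asarray(self.reduced_dims[name])

    def content_hash(self) -> str:
        """Stable hex digest of identifiers, table contents and assay values."""
        h = hashlib.sha256()
        h.update(canonical_dumps(self.feature_ids).encode())
        h.update(canonical_dumps(self.sample_ids).encode())
        for name in sorted(self.assays):
            mat = self.assays[name]
            dense = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
            h.update(name.encode())
            h.update(np.ascontiguousarray(dense, dtype=np.float64).tobytes())
        for name in sorted(self.reduced_dims):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.reduced_dims[name], dtype=np.float64).tobytes())
        for df in (self.row_data, self.col_data):
            for col in df.columns:
                h.update(str(col).encode())
                series = df[col]
                # hash numeric columns by value (dtype-insensitive: an
                # integer-valued float column survives a text round trip)
                if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
                    h.update(np.ascontiguousarray(series, dtype=np.float64).tobytes())
                else:
                    h.update("\x1f".join(str(v) for v in series).encode())
        return h.hexdigest()


def get_feature_values(container: OmicsContainer, assay: str, feature: str) -> np.ndarray:
    """Per-sample values of one feature from one assay, in sample order."""
    mat = container.assay(assay)
    try:
        row = container.feature_ids.index(str(feature))
    except ValueError:
        raise LookupError_(f"unknown feature {feature!r} in container") from None
    values = mat[row]
    if sp.issparse(mat):
        values = np.asarray(mat[[row], :].todense()).ravel()
    else:
        values = np.asarray(values, dtype=float).ravel()
    return values.astype(float)


# ---------------------------------------------------------------------------
# Annotation URLs
# ---------------------------------------------------------------------------

DEFAULT_URL_TEMPLATES: dict[str, str] = {
    "ensembl": "https://www.ensembl.org/id/{id}",
    "entrez": "https://www.ncbi.nlm.nih.gov/gene/{id}",
}


def annotation_url(
    feature_id: str,
    source: str,
    template_overrides: Mapping[str, str] | None = None,
) -> str:
    """Deterministic annotation URL for a feature at an online resource.

    ``source`` names a template (built-in: ``ensembl``, ``entrez``); overrides
    replace or extend the defaults. Templates use ``{id}`` as placeholder.
    """
    if not feature_id:
        raise ValueError("feature_id must be non-empty")
    templates = dict(DEFAULT_URL_TEMPLATES)
    if template_overrides:
        templates.update(template_overrides)
    if source not in templates:
        raise LookupError_(
            f"unknown annotation source {source!r}; known: {sorted(templates)}"
        )
    return templates[source].format(id=feature_id)


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

def make_example_container(
    n_features: int,
    n_samples: int,
    n_clusters: int,
    seed: int,
    sparse_counts: bool = False,
) -> OmicsContainer:
    """Generate a clustered single-cell-like container, reproducible from seed.

    Emulates a small expression study: a ``counts`` assay of cluster-shifted
    log-normal values rounded to integers, a ``logcounts`` assay
    (log2(counts+1)), sample metadata with the true ``cluster`` label
    (categorical) and ``total_count`` (continuous), per-feature
    ``mean_log_expression`` in row_data, and a 2-D ``tsne`` embedding whose
    samples scatter tightly around well-separated cluster centres.

    Per cluster, 10% of features are "markers" whose log-mean is shifted up by
    ~2 units, giving the clusters an expression signature as well as spatial
    separation in the embedding.
    """
    if n_features < 1 or n_samples < 1 or n_clusters < 1:
        raise ValueError("n_features, n_samples and n_clusters must all be >= 1")
    if n_clusters > n_samples:
        raise ValueError(
            f"n_clusters ({n_clusters}) cannot exceed n_samples ({n_samples})"
        )
    rng = np.random.default_rng(seed)

    # round-robin labels then shuffle: every cluster non-empty
    labels = np.array([i % n_clusters for i in range(n_samples)])
    rng.shuffle(labels)

    base_logmean = rng.normal(2.0, 1.0, size=n_features)
    n_markers = max(1, n_features // 10)
    shifts = np.zeros((n_features, n_clusters))
    for k in range(n_clusters):
        markers = rng.choice(n_features, size=n_markers, replace=False)
        shifts[markers, k] = rng.normal(2.0, 0.5, size=n_markers)

    logmeans = base_logmean[:, None] + shifts[:, labels]
    counts = np.round(np.exp(rng.normal(logmeans, 0.5))).astype(float)
    logcounts = np.log2(counts + 1.0)

    centres = rng.normal(0.0, 5.0, size=(n_clusters, 2))
    embedding = centres[labels] + rng.normal(0.0, 0.6, size=(n_samples, 2))

    feature_ids = [f"G{i + 1:04d}" for i in range(n_features)]
    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]

    col_data = pd.DataFrame(
        {
            "cluster": pd.Categorical(
                [f"C{k + 1}" for k in labels],
                categories=[f"C{k + 1}" for k in range(n_clusters)],
            ),
            "total_count": counts.sum(axis=0),
        },
        index=sample_ids,
    )
    row_data = pd.DataFrame(
        {
            "mean_log_expression": logcounts.mean(axis=1),
            "n_detected": (counts > 0).sum(axis=1).astype(float),
        },
        index=feature_ids,
    )

    counts_mat = sp.csr_matrix(counts) if sparse_counts else counts
    return OmicsContainer(
        assays={"counts": counts_mat, "logcounts": logcounts},
        row_data=row_data,
        col_data=col_data,
        reduced_dims={"tsne": embedding},
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------
#
# On-disk layout (all plain text):
#   * assays: headerless delimited numeric tables (.csv/.tsv) or MatrixMarket
#     (.mtx); identifiers come from the metadata tables, and assay files are
#     assumed row/column aligned with them (dimension checks still apply).
#   * row_data/col_data: delimited with header row, first column = identifiers.
#   * reduced_dims: headerless delimited numeric, one row per sample.
#   * manifest: a JSON file mapping slots to relative paths.

def _delim_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","


def _read_matrix(path: Path):
    if not path.exists():
        raise IOError(f"cannot read matrix file: {path}")
    if path.suffix.lower() == ".mtx":
        return sp.csr_matrix(scipy.io.mmread(path))
    arr = np.loadtxt(path, delimiter=_delim_for(path), ndmin=2, dtype=float)
    return arr


def _read_table(path: Path, categorical: Sequence[str] = ()) -> pd.DataFrame:
    if not path.exists():
        raise IOError(f"cannot read metadata table: {path}")
    df = pd.read_csv(path, sep=_delim_for(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    for col in categorical:
        if col in df.columns:
            df[col] = pd.Categorical(df[col].astype("object"))
    return df


def load_container(
    assay_paths: Mapping[str, str | Path],
    col_data_path: str | Path,
    row_data_path: str | Path,
    reduced_dim_paths: Mapping[str, str | Path] | None = None,
    categorical_cols: Sequence[str] = (),
) -> OmicsContainer:
    """Assemble and validate an :class:`OmicsContainer` from files.

    Identifiers are taken from the metadata tables (first column); assay and
    embedding matrices are assumed aligned to them. ``categorical_cols``
    forces the named col_data/row_data columns to factor treatment.
    """
    row_data = _read_table(Path(row_data_path), categorical_cols)
    col_data = _read_table(Path(col_data_path), categorical_cols)
    assays = {name: _read_matrix(Path(p)) for name, p in assay_paths.items()}
    reduced = {
        name: np.asarray(_read_matrix(Path(p)), dtype=float)
        for name, p in (reduced_dim_paths or {}).items()
    }
    for name, emb in reduced.items():
        if sp.issparse(emb):
            reduced[name] = emb.toarray()
    return OmicsContainer(
        assays=assays, row_data=row_data, col_data=col_data, reduced_dims=reduced
    )


def load_container_manifest(manifest_path: str | Path) -> OmicsContainer:
    """Load a container from a JSON manifest of slot -> relative path."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise IOError(f"cannot read manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    return load_container(
        assay_paths={k: base / v for k, v in manifest["assays"].items()},
        col_data_path=base / manifest["col_data"],
        row_data_path=base / manifest["row_data"],
        reduced_dim_paths={k: base / v for k, v in manifest.get("reduced_dims", {}).items()},
        categorical_cols=manifest.get("categorical_cols", ()),
    )


def write_container(container: OmicsContainer, out_dir: str | Path) -> Path:
    """Write a container to plain-text files plus a JSON manifest.

    Returns the manifest path. Dense assays/embeddings go to headerless CSV at
    full float precision; sparse assays to MatrixMarket. Categorical col/row
    columns are recorded in the manifest so factor declarations survive the
    round trip.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"assays": {}, "reduced_dims": {}, "categorical_cols": []}
    for name, mat in container.assays.items():
        if sp.issparse(mat):
            fname = f"assay_{name}.mtx"
            scipy.io.mmwrite(out / fname, sp.coo_matrix(mat))
        else:
            fname = f"assay_{name}.csv"
            np.savetxt(out / fname, np.asarray(mat), delimiter=",", fmt="%.17g")
        manifest["assays"][name] = fname
    for name, emb in container.reduced_dims.items():
        fname = f"reduceddim_{name}.csv"
        np.savetxt(out / fname, np.asarray(emb), delimiter=",", fmt="%.17g")
        manifest["reduced_dims"][name] = fname
    container.col_data.to_csv(out / "col_data.csv", float_format="%.17g")
    container.row_data.to_csv(out / "row_data.csv", float_format="%.17g")
    manifest["col_data"] = "col_data.csv"
    manifest["row_data"] = "row_data.csv"
    cats = set()
    for df in (container.col_data, container.row_data):
        for col in df.columns:
            if isinstance(df[col].dtype, pd.CategoricalDtype) or df[col].dtype == object:
                cats.add(col)
    manifest["categorical_cols"] = sorted(cats)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path
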