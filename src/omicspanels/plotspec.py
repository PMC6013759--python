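"""Panel configurations resolved into renderable plot specifications.

A :class:`PanelConfig` says *what* a panel shows (which variables, assay,
embedding, colouring, selection effect); :func:`build_plot_spec` resolves it
against a container, a colormap registry and an optional incoming selection
into a :class:`PlotSpec` — a fully materialized, JSON-serializable description
of the plot: geometry, placed points, outline/rectangle shapes, axis and
legend metadata.

Geometry follows the variable kinds: two continuous variables give a scatter
plot; one categorical variable gives a (vertical or horizontal) violin plot
with points jittered within each violin; two categorical variables give a
rectangle plot whose rectangles have area proportional to the frequency of
each level combination, collapsing to a mirrored bar plot when one of the
variables has a single level. Density-dependent grid downsampling
(:func:`downsample_points`) thins crowded regions while keeping every
occupied bin represented.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._canonical import canonical_dumps
from .colormaps import (
    ColorMapRegistry,
    MISSING_COLOR,
    assign_colors,
    resolve_colormap,
)
from .container import (
    CONTINUOUS,
    LookupError_,
    OmicsContainer,
    VariableKind,
    classify_variable,
    get_feature_values,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PanelConfig",
    "PlotSpec",
    "PANEL_TYPES",
    "panel_domain",
    "dispatch_geometry",
    "rectangle_layout",
    "mirrored_bar_layout",
    "place_points",
    "order_samples_by_fields",
    "build_plot_spec",
    "heatmap_spec",
    "downsample_points",
    "DEFAULT_POINT_COLOR",
    "JITTER_HALF_WIDTH",
    "DOWNSAMPLE_RESOLUTION",
    "DOWNSAMPLE_CAP",
]

PANEL_TYPES = (
    "column_data",
    "feature_assay",
    "row_data",
    "reduced_dim",
    "heatmap",
    "row_table",
)

#: panels whose points are samples vs features
_SAMPLE_PANELS = ("column_data", "feature_assay", "reduced_dim", "heatmap")
_FEATURE_PANELS = ("row_data", "row_table")

DEFAULT_POINT_COLOR = "#000000"
JITTER_HALF_WIDTH = 0.4
HIGHLIGHT_EXCLUDED_OPACITY = 0.3
DOWNSAMPLE_RESOLUTION = 200
DOWNSAMPLE_CAP = 1
_VIOLIN_GRID = 64


def panel_domain(panel_type: str) -> str:
    """``"sample"`` or ``"feature"``: which identifiers a panel's points carry."""
    if panel_type in _SAMPLE_PANELS:
        return "sample"
    if panel_type in _FEATURE_PANELS:
        return "feature"
    raise ValueError(f"unknown panel type {panel_type!r}")


# ---------------------------------------------------------------------------
# Panel configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PanelConfig:
    """Declarative parameters of one panel.

    Which fields apply depends on ``panel_type``: ``x_var``/``y_var`` name
    col_data (or row_data) columns; ``assay`` + ``feature`` select the y-axis
    of a feature-assay plot; ``reduced_dim`` + ``dims`` pick two embedding
    columns; ``features`` + ``order_by`` configure a heatmap. ``colour_by``
    is ``None`` or a dict: ``{"slot": "coldata"|"rowdata", "name": var}`` or
    ``{"slot": "feature", "feature": id, "assay": name}``.
    """

    panel_id: str
    panel_type: str
    x_var: str | None = None
    y_var: str | None = None
    assay: str | None = None
    feature: str | None = None
    reduced_dim: str | None = None
    dims: tuple[int, int] = (0, 1)
    features: list[str] | None = None
    order_by: list[str] | None = None
    colour_by: dict | None = None
    selection_effect: str = "restrict"
    downsample: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.panel_type not in PANEL_TYPES:
            raise ValueError(
                f"unknown panel type {self.panel_type!r}; expected one of {PANEL_TYPES}"
            )
        if self.selection_effect not in ("restrict", "highlight"):
            raise ValueError(f"unknown selection effect {self.selection_effect!r}")
        self.dims = tuple(self.dims)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dims"] = list(self.dims)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        d = dict(d)
        if "dims" in d and d["dims"] is not None:
            d["dims"] = tuple(d["dims"])
        if d.get("downsample") is not None:
            d["downsample"] = tuple(d["downsample"])
        return cls(**d)


def validate_panel(panel: PanelConfig, container: OmicsContainer) -> None:
    """Check that every name the panel references exists in the container."""
    pt = panel.panel_type
    if pt == "column_data":
        if panel.y_var is None:
            raise LookupError_(f"panel {panel.panel_id}: column_data needs y_var")
        for var in (panel.x_var, panel.y_var):
            if var is not None and var not in container.col_data.columns:
                raise LookupError_(
                    f"panel {panel.panel_id}: unknown col_data variable {var!r}"
                )
    elif pt == "feature_assay":
        container.assay(panel.assay)
        if str(panel.feature) not in container.feature_ids:
            raise LookupError_(
                f"panel {panel.panel_id}: unknown feature {panel.feature!r}"
            )
        if panel.x_var is not None and panel.x_var not in container.col_data.columns:
            raise LookupError_(
                f"panel {panel.panel_id}: unknown col_data variable {panel.x_var!r}"
            )
    elif pt == "row_data":
        if panel.y_var is None:
            raise LookupError_(f"panel {panel.panel_id}: row_data needs y_var")
        for var in (panel.x_var, panel.y_var):
            if var is not None and var not in container.row_data.columns:
                raise LookupError_(
                    f"panel {panel.panel_id}: unknown row_data variable {var!r}"
                )
    elif pt == "reduced_dim":
        emb = container.reduced_dim(panel.reduced_dim)
        for d in panel.dims:
            if not 0 <= d < emb.shape[1]:
                raise LookupError_(
                    f"panel {panel.panel_id}: dimension {d} out of range for "
                    f"{panel.reduced_dim!r} with {emb.shape[1]} columns"
                )
    elif pt == "heatmap":
        container.assay(panel.assay)
        if not panel.features:
            raise LookupError_(f"panel {panel.panel_id}: heatmap needs features")
        missing = [f for f in panel.features if str(f) not in container.feature_ids]
        if missing:
            raise LookupError_(f"panel {panel.panel_id}: unknown features {missing}")
        for field in panel.order_by or []:
            if field not in container.col_data.columns:
                raise LookupError_(
                    f"panel {panel.panel_id}: unknown ordering field {field!r}"
                )
    cb = panel.colour_by
    if cb is not None:
        slot = cb.get("slot")
        if slot == "coldata" and cb.get("name") not in container.col_data.columns:
            raise LookupError_(
                f"panel {panel.panel_id}: unknown colour variable {cb.get('name')!r}"
            )
        if slot == "rowdata" and cb.get("name") not in container.row_data.columns:
            raise LookupError_(
                f"panel {panel.panel_id}: unknown colour variable {cb.get('name')!r}"
            )
        if slot == "feature":
            container.assay(cb.get("assay"))
            if str(cb.get("feature")) not in container.feature_ids:
                raise LookupError_(
                    f"panel {panel.panel_id}: unknown colour feature {cb.get('feature')!r}"
                )


# ---------------------------------------------------------------------------
# Plot specification
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlotSpec:
    """A fully-resolved, renderable plot description."""

    panel_id: str
    geometry: str
    points: list = dataclasses.field(default_factory=list)
    axes: dict = dataclasses.field(default_factory=dict)
    shapes: list = dataclasses.field(default_factory=list)
    legend: dict | None = None
    data: dict | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    def included_ids(self) -> set[str]:
        if self.geometry == "heatmap":
            return set((self.data or {}).get("samples", []))
        if self.geometry == "table":
            return set((self.data or {}).get("rows", []))
        return {p["id"] for p in self.points if p["included"]}

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "panel_id": self.panel_id,
            "geometry": self.geometry,
            "points": self.points,
            "axes": self.axes,
            "shapes": self.shapes,
            "legend": self.legend,
            "data": self.data,
            "provenance": self.provenance,
        }

    def to_document(self) -> str:
        """Canonical JSON text; equal specs serialize byte-identically."""
        return canonical_dumps(self.to_dict())


# ---------------------------------------------------------------------------
# Geometry dispatch
# ---------------------------------------------------------------------------

def dispatch_geometry(x_kind: VariableKind, y_kind: VariableKind) -> str:
    """Pick the plot geometry from the two axis variable kinds.

    continuous x continuous -> scatter; exactly one categorical -> violin
    (vertical when the categorical variable is on x); categorical x
    categorical -> rectangle, collapsing to a mirrored bar plot when either
    categorical variable has exactly one level.
    """
    if not x_kind.is_categorical and not y_kind.is_categorical:
        return "scatter"
    if x_kind.is_categorical and not y_kind.is_categorical:
        return "violin_vertical"
    if not x_kind.is_categorical and y_kind.is_categorical:
        return "violin_horizontal"
    if x_kind.n_levels == 1 or y_kind.n_levels == 1:
        return "mirrored_bar"
    return "rectangle"


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def rectangle_layout(
    counts: Mapping[tuple, int],
    total: int,
    x_levels: Sequence | None = None,
    y_levels: Sequence | None = None,
) -> list[dict]:
    """Rectangles for a categorical x categorical plot.

    The plane is a lattice of unit cells indexed by level order (x level i
    spans [i, i+1], y level j spans [j, j+1]). Each combination with a
    positive count gets one rectangle centred in its cell with side
    sqrt(fraction / max_fraction) cell widths, so relative *areas* are exactly
    proportional to combination frequencies and the most frequent combination
    fills its cell. ``fraction`` on each rectangle is exactly count/total.
    """
    if total <= 0 or total != sum(counts.values()):
        raise ValueError("total must be positive and equal the sum of counts")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    if x_levels is None:
        x_levels = list(dict.fromkeys(k[0] for k in counts))
    if y_levels is None:
        y_levels = list(dict.fromkeys(k[1] for k in counts))
    xi = {lvl: i for i, lvl in enumerate(x_levels)}
    yi = {lvl: j for j, lvl in enumerate(y_levels)}
    max_fraction = max(c / total for c in counts.values() if c > 0)
    rects = []
    for (xl, yl), count in counts.items():
        if count == 0:
            continue
        fraction = count / total
        side = math.sqrt(fraction / max_fraction)
        cx, cy = xi[xl] + 0.5, yi[yl] + 0.5
        rects.append(
            {
                "x_level": str(xl),
                "y_level": str(yl),
                "x0": cx - side / 2,
                "x1": cx + side / 2,
                "y0": cy - side / 2,
                "y1": cy + side / 2,
                "fraction": fraction,
                "count": int(count),
            }
        )
    return rects


def mirrored_bar_layout(
    counts: Mapping[tuple, int],
    total: int,
    x_levels: Sequence,
    y_levels: Sequence,
) -> list[dict]:
    """Bars for the one-level collapse of the rectangle plot.

    The multi-level variable keeps its lattice axis (one bar per level, width
    0.8); bars extend symmetrically about the single-level variable's axis
    position with full length proportional to count (the most frequent level
    spans one cell width).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    single_is_x = len(x_levels) == 1
    multi_levels = list(y_levels if single_is_x else x_levels)
    max_count = max(counts.values())
    bars = []
    for (xl, yl), count in counts.items():
        if count == 0:
            continue
        lvl = yl if single_is_x else xl
        pos = multi_levels.index(lvl)
        half = 0.5 * (count / max_count)
        lo, hi = 0.5 - half, 0.5 + half
        if single_is_x:
            rect = {"x0": lo, "x1": hi, "y0": pos + 0.1, "y1": pos + 0.9}
        else:
            rect = {"x0": pos + 0.1, "x1": pos + 0.9, "y0": lo, "y1": hi}
        rect.update(
            {
                "x_level": str(xl),
                "y_level": str(yl),
                "fraction": count / total,
                "count": int(count),
            }
        )
        bars.append(rect)
    return bars


# ---------------------------------------------------------------------------
# Point placement
# ---------------------------------------------------------------------------

def _point_rng(seed: int, point_id: str) -> np.random.Generator:
    # stable per-point stream: adding/removing other points never shifts this one
    digest = hashlib.blake2b(
        f"{seed}\x1f{point_id}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


def _level_index(kind: VariableKind) -> dict:
    return {lvl: i for i, lvl in enumerate(kind.levels)}


def place_points(
    geometry: str,
    x_values: Sequence,
    y_values: Sequence,
    point_ids: Sequence[str],
    seed: int,
    x_kind: VariableKind = CONTINUOUS,
    y_kind: VariableKind = CONTINUOUS,
    rects: list[dict] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Display coordinates for each point under the given geometry.

    Scatter passes values through unchanged. Violins put each point at its
    level's lattice position plus uniform jitter bounded by 0.4 level widths
    on the categorical axis. Rectangle and mirrored-bar geometries scatter
    points uniformly strictly inside their combination's rectangle (``rects``
    from :func:`rectangle_layout`/:func:`mirrored_bar_layout`; recomputed from
    the values when omitted). All randomness is drawn from a deterministic
    per-point stream seeded by (seed, point_id), so placement is reproducible
    and independent of point insertion order.
    """
    n = len(point_ids)
    xs = np.empty(n)
    ys = np.empty(n)
    if geometry == "scatter":
        return np.asarray(x_values, float), np.asarray(y_values, float)

    if geometry in ("violin_vertical", "violin_horizontal"):
        cat_on_x = geometry == "violin_vertical"
        kind = x_kind if cat_on_x else y_kind
        idx = _level_index(kind)
        cat_vals = x_values if cat_on_x else y_values
        cont_vals = np.asarray(y_values if cat_on_x else x_values, float)
        for i, pid in enumerate(point_ids):
            rng = _point_rng(seed, str(pid))
            pos = idx[cat_vals[i]] + rng.uniform(-JITTER_HALF_WIDTH, JITTER_HALF_WIDTH)
            if cat_on_x:
                xs[i], ys[i] = pos, cont_vals[i]
            else:
                xs[i], ys[i] = cont_vals[i], pos
        return xs, ys

    if geometry in ("rectangle", "mirrored_bar"):
        if rects is None:
            combos = list(zip(x_values, y_values))
            counts: dict[tuple, int] = {}
            for c in combos:
                counts[c] = counts.get(c, 0) + 1
            x_lv = list(x_kind.levels)
            y_lv = list(y_kind.levels)
            keyed = {(str(x), str(y)): v for (x, y), v in counts.items()}
            if geometry == "rectangle":
                rects = rectangle_layout(keyed, n, [str(l) for l in x_lv], [str(l) for l in y_lv])
            else:
                rects = mirrored_bar_layout(keyed, n, [str(l) for l in x_lv], [str(l) for l in y_lv])
        by_combo = {(r["x_level"], r["y_level"]): r for r in rects}
        xi = _level_index(x_kind)
        yi = _level_index(y_kind)
        eps = 1e-9
        for i, pid in enumerate(point_ids):
            rng = _point_rng(seed, str(pid))
            u, v = rng.random(2)
            u = min(max(u, eps), 1 - eps)
            v = min(max(v, eps), 1 - eps)
            r = by_combo.get((str(x_values[i]), str(y_values[i])))
            if r is None:
                # combination absent from the layout (e.g. restricted out):
                # park the point at its lattice cell centre
                xs[i] = xi[x_values[i]] + 0.5
                ys[i] = yi[y_values[i]] + 0.5
            else:
                xs[i] = r["x0"] + (r["x1"] - r["x0"]) * u
                ys[i] = r["y0"] + (r["y1"] - r["y0"]) * v
        return xs, ys

    raise ValueError(f"cannot place points for geometry {geometry!r}")


# ---------------------------------------------------------------------------
# Sample ordering (heatmap columns)
# ---------------------------------------------------------------------------

def order_samples_by_fields(col_data: pd.DataFrame, fields: Sequence[str]) -> np.ndarray:
    """Stable lexicographic sample permutation by the given fields in order.

    Categorical fields sort by level order — declared category order for
    explicit factors, lexical (alphabetical) order for plain text fields —
    continuous fields ascending; ties keep the original order. An empty
    field list is the identity permutation.
    """
    n = len(col_data)
    if not fields or n == 0:
        return np.arange(n)
    # np.lexsort sorts by its *last* key as primary; build keys least
    # significant first, starting from the original index as tiebreak
    keys: list[np.ndarray] = [np.arange(n, dtype=float)]
    for field in reversed(list(fields)):
        if field not in col_data.columns:
            raise LookupError_(f"unknown ordering field {field!r}")
        series = col_data[field]
        kind = classify_variable(series)
        if isinstance(series.dtype, pd.CategoricalDtype):
            codes = np.asarray(series.cat.codes, dtype=float)
            codes[codes < 0] = len(series.cat.categories)  # missing sorts last
            keys.append(codes)
        elif kind.is_categorical:
            vals = np.array([str(v) for v in series.astype("object")], dtype=object)
            order = {v: i for i, v in enumerate(sorted(set(vals)))}
            keys.append(np.array([order[v] for v in vals], dtype=float))
        else:
            keys.append(np.asarray(series, dtype=float))
    return np.lexsort(tuple(keys))


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_points(
    coords: Sequence[tuple[float, float]],
    resolution: int = DOWNSAMPLE_RESOLUTION,
    cap: int = DOWNSAMPLE_CAP,
) -> list[int]:
    """Density-dependent grid thinning of display coordinates.

    The bounding box is partitioned into resolution x resolution equal bins
    (points on the maximum edge fall in the last bin); within each bin the
    first ``cap`` points in original index order are retained. The first
    point attaining each bounding-box extreme is always retained as well,
    which pins the box — and therefore the grid — under repeated application,
    making the operation idempotent. Returns the retained indices sorted
    ascending — a subset that keeps every occupied bin represented, bounding
    the visible point count by about resolution^2 * cap.
    """
    if resolution < 1 or cap < 1:
        raise ValueError("resolution and cap must both be >= 1")
    pts = np.asarray(coords, dtype=float)
    if pts.size == 0:
        return []
    pts = pts.reshape(len(pts), 2)
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    bins = np.minimum((pts - lo) / span * resolution, resolution - 1).astype(int)
    anchors = {
        int(pts[:, 0].argmin()), int(pts[:, 0].argmax()),
        int(pts[:, 1].argmin()), int(pts[:, 1].argmax()),
    }
    kept: set[int] = set(anchors)
    fill: dict[tuple[int, int], int] = {}
    for i, (bx, by) in enumerate(bins):
        key = (int(bx), int(by))
        if fill.get(key, 0) < cap:
            fill[key] = fill.get(key, 0) + 1
            kept.add(i)
    return sorted(kept)


# ---------------------------------------------------------------------------
# Variable resolution helpers
# ---------------------------------------------------------------------------

_CONSTANT_LEVEL = "all"


def _resolve_axis(panel: PanelConfig, container: OmicsContainer, axis: str):
    """Raw values + kind + label for one axis of a point-based panel."""
    pt = panel.panel_type
    var = panel.x_var if axis == "x" else panel.y_var
    if pt == "reduced_dim":
        emb = container.reduced_dim(panel.reduced_dim)
        dim = panel.dims[0] if axis == "x" else panel.dims[1]
        return emb[:, dim].astype(float), CONTINUOUS, f"{panel.reduced_dim}[{dim + 1}]"
    if pt == "feature_assay" and axis == "y":
        vals = get_feature_values(container, panel.assay, panel.feature)
        return vals, CONTINUOUS, f"{panel.feature} ({panel.assay})"
    table = container.row_data if pt == "row_data" else container.col_data
    if var is None:
        # no variable selected: a single-level constant, giving one violin/bar
        n = len(table)
        kind = VariableKind("categorical", (_CONSTANT_LEVEL,))
        return np.array([_CONSTANT_LEVEL] * n, dtype=object), kind, ""
    if var not in table.columns:
        raise LookupError_(f"panel {panel.panel_id}: unknown variable {var!r}")
    series = table[var]
    kind = classify_variable(series)
    if kind.is_categorical:
        # keep values aligned with the level representation (bools become str)
        vals = np.array(
            [
                str(bool(v)) if isinstance(v, (bool, np.bool_)) else v
                for v in series.astype("object")
            ],
            dtype=object,
        )
    else:
        vals = np.asarray(series, dtype=float)
    return vals, kind, var


def _colour_values(panel: PanelConfig, container: OmicsContainer):
    """(slot, name, values, kind) for the colour variable, or None."""
    cb = panel.colour_by
    if cb is None:
        return None
    slot = cb["slot"]
    if slot == "coldata":
        series = container.col_data[cb["name"]]
        kind = classify_variable(series)
        vals = series.astype("object") if kind.is_categorical else np.asarray(series, float)
        return "coldata", cb["name"], np.asarray(vals), kind
    if slot == "rowdata":
        series = container.row_data[cb["name"]]
        kind = classify_variable(series)
        vals = series.astype("object") if kind.is_categorical else np.asarray(series, float)
        return "rowdata", cb["name"], np.asarray(vals), kind
    if slot == "feature":
        # colour by a feature's assay values: always continuous
        vals = get_feature_values(container, cb["assay"], cb["feature"])
        return "assay", cb["assay"], vals, CONTINUOUS
    raise ValueError(f"unknown colour_by slot {slot!r}")


# ---------------------------------------------------------------------------
# Spec building
# ---------------------------------------------------------------------------

def build_plot_spec(
    panel: PanelConfig,
    container: OmicsContainer,
    registry: ColorMapRegistry,
    incoming: set | None = None,
    seed: int = 0,
    *,
    restrict_ids: set | None = None,
    highlight_ids: set | None = None,
    container_hash: str | None = None,
) -> PlotSpec:
    """Resolve a panel into a renderable spec.

    ``incoming`` is the effective selection transmitted to this panel; it is
    applied according to the panel's ``selection_effect``: *restrict* marks
    excluded points ``included=false`` and recomputes geometry statistics
    (violin outlines, rectangle areas, bar lengths) over the surviving points
    only, while *highlight* keeps all points included but re-colours
    non-selected points grey at reduced opacity. ``highlight_ids`` lets a
    caller apply an additional highlight set on top of a restricting panel
    (used during propagation when both edge kinds feed one receiver).
    """
    validate_panel(panel, container)
    if restrict_ids is not None:
        restrict_ids = {str(i) for i in restrict_ids}
    if incoming is not None:
        if panel.selection_effect == "restrict":
            restrict_ids = {str(i) for i in incoming}
        else:
            highlight_ids = {str(i) for i in incoming}
    if highlight_ids is not None:
        highlight_ids = {str(i) for i in highlight_ids}

    if container_hash is None:
        container_hash = container.content_hash()
    provenance = {
        "panel_id": panel.panel_id,
        "container_hash": container_hash,
        "seed": int(seed),
    }

    if panel.panel_type == "heatmap":
        return heatmap_spec(
            container,
            panel.features,
            panel.order_by or [],
            panel.assay,
            registry,
            panel_id=panel.panel_id,
            incoming=restrict_ids,
            provenance=provenance,
        )
    if panel.panel_type == "row_table":
        return _table_spec(panel, container, restrict_ids, provenance)

    domain = panel_domain(panel.panel_type)
    ids = container.sample_ids if domain == "sample" else container.feature_ids
    x_vals, x_kind, x_label = _resolve_axis(panel, container, "x")
    y_vals, y_kind, y_label = _resolve_axis(panel, container, "y")

    # drop points with missing plotted values before dispatch
    keep = np.ones(len(ids), dtype=bool)
    for vals, kind in ((x_vals, x_kind), (y_vals, y_kind)):
        if kind.is_categorical:
            keep &= np.array([not pd.isna(v) for v in vals], dtype=bool)
        else:
            keep &= np.isfinite(np.asarray(vals, float))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "panel %s: dropped %d point(s) with missing plotted values",
            panel.panel_id,
            n_dropped,
        )
    ids = [i for i, k in zip(ids, keep) if k]
    x_vals = np.asarray(x_vals, dtype=object)[keep]
    y_vals = np.asarray(y_vals, dtype=object)[keep]

    geometry = dispatch_geometry(x_kind, y_kind)

    included = np.ones(len(ids), dtype=bool)
    if restrict_ids is not None:
        included = np.array([i in restrict_ids for i in ids], dtype=bool)

    # geometry statistics over included points only
    inc_x = x_vals[included]
    inc_y = y_vals[included]
    shapes = _geometry_shapes(geometry, inc_x, inc_y, x_kind, y_kind)
    rects = shapes if geometry in ("rectangle", "mirrored_bar") else None

    xs, ys = place_points(
        geometry, x_vals, y_vals, ids, seed, x_kind, y_kind, rects=rects
    )

    colour_info = _colour_values(panel, container)
    legend = None
    if colour_info is None:
        colors = [DEFAULT_POINT_COLOR] * len(ids)
    else:
        slot, name, cvals, ckind = colour_info
        cvals = np.asarray(cvals, dtype=object)[keep]
        fn = resolve_colormap(registry, slot, name, ckind)
        colors, legend = assign_colors(fn, ckind, cvals)
        if legend is not None:
            legend = dict(legend, variable=name)

    opacity = np.ones(len(ids))
    if highlight_ids is not None:
        for i, pid in enumerate(ids):
            if pid not in highlight_ids:
                colors[i] = MISSING_COLOR
                opacity[i] = HIGHLIGHT_EXCLUDED_OPACITY

    points = [
        {
            "id": pid,
            "x": float(xs[i]),
            "y": float(ys[i]),
            "color": colors[i],
            "included": bool(included[i]),
            "opacity": float(opacity[i]),
        }
        for i, pid in enumerate(ids)
    ]

    if panel.downsample is not None:
        resolution, cap = panel.downsample
        shown = [p for p in points if p["included"]]
        kept = set(
            downsample_points([(p["x"], p["y"]) for p in shown], resolution, cap)
        )
        kept_ids = {shown[i]["id"] for i in kept}
        before = len(shown)
        points = [p for p in points if not p["included"] or p["id"] in kept_ids]
        logger.info(
            "panel %s: downsampled %d -> %d points", panel.panel_id, before, len(kept_ids)
        )

    axes = {
        "x": _axis_meta(x_label, x_kind),
        "y": _axis_meta(y_label, y_kind),
    }
    return PlotSpec(
        panel_id=panel.panel_id,
        geometry=geometry,
        points=points,
        axes=axes,
        shapes=shapes,
        legend=legend,
        data=None,
        provenance=provenance,
    )


def _axis_meta(label: str, kind: VariableKind) -> dict:
    meta: dict = {"label": label, "kind": kind.kind}
    if kind.is_categorical:
        meta["levels"] = [str(l) for l in kind.levels]
        meta["tick_positions"] = list(range(len(kind.levels)))
    return meta


def _geometry_shapes(geometry, x_vals, y_vals, x_kind, y_kind) -> list:
    if geometry in ("rectangle", "mirrored_bar"):
        counts: dict[tuple, int] = {}
        for xv, yv in zip(x_vals, y_vals):
            key = (str(xv), str(yv))
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        if total == 0:
            return []
        x_lv = [str(l) for l in x_kind.levels]
        y_lv = [str(l) for l in y_kind.levels]
        if geometry == "rectangle":
            return rectangle_layout(counts, total, x_lv, y_lv)
        return mirrored_bar_layout(counts, total, x_lv, y_lv)
    if geometry in ("violin_vertical", "violin_horizontal"):
        cat_on_x = geometry == "violin_vertical"
        kind = x_kind if cat_on_x else y_kind
        cat_vals = x_vals if cat_on_x else y_vals
        cont_vals = np.asarray(y_vals if cat_on_x else x_vals, dtype=float)
        return _violin_outlines(kind, cat_vals, cont_vals)
    return []


def _violin_outlines(kind: VariableKind, cat_vals, cont_vals) -> list:
    """Gaussian-KDE outlines (Silverman bandwidth, 64 grid points) per level."""
    shapes = []
    for pos, level in enumerate(kind.levels):
        mask = np.array([str(v) == str(level) for v in cat_vals], dtype=bool)
        vals = cont_vals[mask]
        outline = None
        if len(vals) >= 2 and np.unique(vals).size >= 2:
            try:
                kde = gaussian_kde(vals, bw_method="silverman")
                grid = np.linspace(float(vals.min()), float(vals.max()), _VIOLIN_GRID)
                dens = kde(grid)
                if dens.max() > 0:
                    half = 0.4 * dens / dens.max()
                    outline = {
                        "values": [float(g) for g in grid],
                        "half_width": [float(h) for h in half],
                    }
            except np.linalg.LinAlgError:  # singular covariance
                outline = None
        shapes.append(
            {
                "level": str(level),
                "position": pos,
                "n": int(mask.sum()),
                "outline": outline,
            }
        )
    return shapes


def _table_spec(panel, container, restrict_ids, provenance) -> PlotSpec:
    rows = container.feature_ids
    warning = None
    if restrict_ids is not None:
        rows = [f for f in rows if f in restrict_ids]
        if not rows:
            warning = "selection restricted the table to zero rows"
            logger.warning("panel %s: %s", panel.panel_id, warning)
    data = {
        "rows": rows,
        "columns": [str(c) for c in container.row_data.columns],
    }
    if warning:
        data["warning"] = warning
    return PlotSpec(
        panel_id=panel.panel_id,
        geometry="table",
        points=[],
        axes={},
        shapes=[],
        legend=None,
        data=data,
        provenance=provenance,
    )


def heatmap_spec(
    container: OmicsContainer,
    features: Sequence[str],
    order_fields: Sequence[str],
    assay: str,
    registry: ColorMapRegistry,
    panel_id: str = "heatmap",
    incoming: set | None = None,
    provenance: dict | None = None,
) -> PlotSpec:
    """Assay-value heatmap with metadata-ordered, annotated sample columns.

    Columns are the (optionally selection-restricted) samples ordered by the
    given col_data fields — categorical fields by level order, continuous
    ascending, ties broken by sample identifier so the column order is
    invariant to the container's input sample order. One annotation colour
    track is emitted per ordering field; cell colouring metadata comes from
    the assay's resolved continuous colormap.
    """
    features = [str(f) for f in features]
    if not features:
        raise ValueError("heatmap needs a non-empty feature list")
    missing = [f for f in features if f not in container.feature_ids]
    if missing:
        raise LookupError_(f"unknown heatmap features {missing}")
    sample_ids = container.sample_ids
    mask = np.ones(len(sample_ids), dtype=bool)
    if incoming is not None:
        incoming = {str(i) for i in incoming}
        mask = np.array([s in incoming for s in sample_ids], dtype=bool)
    sub_cd = container.col_data.loc[mask]
    sub_ids = [s for s, m in zip(sample_ids, mask) if m]

    # id-lexical pre-sort, then stable field sort => order invariant to input
    pre = np.argsort(np.array(sub_ids, dtype=object), kind="stable")
    sub_cd = sub_cd.iloc[pre]
    sub_ids = [sub_ids[i] for i in pre]
    perm = order_samples_by_fields(sub_cd, list(order_fields))
    ordered_ids = [sub_ids[i] for i in perm]
    ordered_cd = sub_cd.iloc[perm]

    mat = container.assay(assay)
    fidx = [container.feature_ids.index(f) for f in features]
    sidx = [container.sample_ids.index(s) for s in ordered_ids]
    import scipy.sparse as sp

    dense = mat.toarray() if sp.issparse(mat) else np.asarray(mat, dtype=float)
    values = dense[np.ix_(fidx, sidx)]

    cell_kind = CONTINUOUS
    cell_fn = resolve_colormap(registry, "assay", assay, cell_kind)
    if values.size:
        _, cell_legend = assign_colors(cell_fn, cell_kind, values.ravel())
    else:
        cell_legend = None

    annotations = []
    for field in order_fields:
        series = ordered_cd[field]
        kind = classify_variable(container.col_data[field])
        fn = resolve_colormap(registry, "coldata", field, kind)
        if len(ordered_ids) == 0:
            colors, legend = [], None
        else:
            vals = series.astype("object") if kind.is_categorical else np.asarray(series, float)
            colors, legend = assign_colors(fn, kind, np.asarray(vals, dtype=object))
        annotations.append(
            {"field": field, "kind": kind.kind, "colors": colors, "legend": legend}
        )

    data = {
        "features": features,
        "samples": ordered_ids,
        "values": [[float(v) for v in row] for row in values],
        "assay": assay,
        "order_by": [str(f) for f in order_fields],
        "annotations": annotations,
    }
    return PlotSpec(
        panel_id=panel_id,
        geometry="heatmap",
        points=[],
        axes={
            "x": {"label": "samples", "kind": "categorical", "levels": ordered_ids},
            "y": {"label": "features", "kind": "categorical", "levels": features},
        },
        shapes=[],
        legend=cell_legend,
        data=data,
        provenance=provenance or {"panel_id": panel_id},
    )
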