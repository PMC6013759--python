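"""Selections, the directed panel-link graph, and propagation semantics.

Panels *transmit* point selections — an axis-aligned rectangular brush or a
free-form closed lasso, both in display coordinates — to *receiving* panels
along directed edges. Receivers either restrict themselves to the transmitted
points or merely highlight them. Chains of restrict links reproduce the
sequential gating strategies familiar from flow cytometry: a selection made
downstream operates on the already-restricted population.

Row statistics tables participate through semantic links (the selected table
row drives a receiver's colour variable, a feature-assay plot's y-axis
feature, or a heatmap's feature set), and feature-metadata plots can subset a
table's rows.

The graph is kept acyclic; evaluation walks panels in (lexicographic)
topological order, so results are deterministic and independent of the order
in which links were added. Multiple transmitters into one receiver combine by
intersection.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from typing import Mapping

import networkx as nx

from .colormaps import ColorMapRegistry
from .container import LookupError_, OmicsContainer
from .plotspec import PanelConfig, PlotSpec, build_plot_spec, panel_domain

logger = logging.getLogger(__name__)

__all__ = [
    "RectBrush",
    "Lasso",
    "TableRow",
    "Selection",
    "LinkGraph",
    "LinkError",
    "point_in_selection",
    "capture_selection",
    "add_link",
    "propagate",
    "table_transmit",
    "rowplot_to_table",
    "shape_from_dict",
    "shape_to_dict",
]


class LinkError(ValueError):
    """An illegal link: cycle, dead endpoint or domain mismatch."""


# ---------------------------------------------------------------------------
# Selection shapes
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RectBrush:
    """Axis-aligned rectangular brush; all four bounds inclusive."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError("brush bounds must satisfy xmin <= xmax and ymin <= ymax")


@dataclasses.dataclass(frozen=True)
class Lasso:
    """Free-form polygon selection; membership requires a closed polygon."""

    vertices: tuple
    closed: bool = True

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("a lasso needs at least 3 vertices")


@dataclasses.dataclass(frozen=True)
class TableRow:
    """Selection of a single feature row in a row statistics table."""

    feature: str


@dataclasses.dataclass
class Selection:
    """A selection made in a source panel, with its cached captured ids."""

    source_panel: str
    shape: RectBrush | Lasso | TableRow | None = None
    captured_ids: set | None = None


def shape_to_dict(shape) -> dict | None:
    if shape is None:
        return None
    if isinstance(shape, RectBrush):
        return {
            "type": "brush",
            "xmin": shape.xmin,
            "xmax": shape.xmax,
            "ymin": shape.ymin,
            "ymax": shape.ymax,
        }
    if isinstance(shape, Lasso):
        return {
            "type": "lasso",
            "vertices": [[x, y] for x, y in shape.vertices],
            "closed": bool(shape.closed),
        }
    if isinstance(shape, TableRow):
        return {"type": "table_row", "feature": shape.feature}
    raise TypeError(f"unknown shape {shape!r}")


def shape_from_dict(d: Mapping | None):
    if d is None:
        return None
    t = d.get("type")
    if t == "brush":
        return RectBrush(d["xmin"], d["xmax"], d["ymin"], d["ymax"])
    if t == "lasso":
        return Lasso(tuple((v[0], v[1]) for v in d["vertices"]), d.get("closed", True))
    if t == "table_row":
        return TableRow(str(d["feature"]))
    raise ValueError(f"unknown shape type {t!r}")


# ---------------------------------------------------------------------------
# Point membership
# ---------------------------------------------------------------------------

def _on_segment(px, py, ax, ay, bx, by, eps=1e-12) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > eps * max(1.0, abs(bx - ax), abs(by - ay)):
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    length2 = (bx - ax) ** 2 + (by - ay) ** 2
    return -eps <= dot <= length2 + eps


def point_in_selection(shape, point) -> bool:
    """Boundary-inclusive membership of a display point in a brush or lasso.

    Brushes compare inclusively on all four bounds. Lassos use the even–odd
    (ray-casting) rule with points on the polygon boundary counting as
    inside; an open lasso has no interior and raises.
    """
    x, y = float(point[0]), float(point[1])
    if isinstance(shape, RectBrush):
        return shape.xmin <= x <= shape.xmax and shape.ymin <= y <= shape.ymax
    if isinstance(shape, Lasso):
        if not shape.closed:
            raise ValueError("membership is undefined for an open lasso")
        verts = shape.vertices
        n = len(verts)
        for i in range(n):
            ax, ay = verts[i]
            bx, by = verts[(i + 1) % n]
            if _on_segment(x, y, ax, ay, bx, by):
                return True
        inside = False
        j = n - 1
        for i in range(n):
            xi, yi = verts[i]
            xj, yj = verts[j]
            if (yi > y) != (yj > y):
                x_cross = (xj - xi) * (y - yi) / (yj - yi) + xi
                if x < x_cross:
                    inside = not inside
            j = i
        return inside
    raise TypeError(f"cannot test membership against {type(shape).__name__}")


def capture_selection(spec: PlotSpec, shape) -> set[str]:
    """Ids of the spec's *included* points whose display coordinates fall in
    the shape. Restricted-out points are never capturable. A table-row shape
    captures the selected feature (if still present among the table's rows).
    """
    if isinstance(shape, TableRow):
        rows = set((spec.data or {}).get("rows", []))
        return {shape.feature} & rows if rows else {shape.feature}
    return {
        p["id"]
        for p in spec.points
        if p["included"] and point_in_selection(shape, (p["x"], p["y"]))
    }


# ---------------------------------------------------------------------------
# The link graph
# ---------------------------------------------------------------------------

#: effects carried by plot-to-plot edges vs semantic table edges
_POINT_EFFECTS = ("restrict", "highlight")
_TABLE_EFFECTS = ("colour_by", "y_feature", "features")

_POINT_PLOTS = ("column_data", "feature_assay", "reduced_dim", "row_data")
_SAMPLE_PLOTS = ("column_data", "feature_assay", "reduced_dim")


class LinkGraph:
    """Directed acyclic transmitter -> receiver graph over live panels."""

    def __init__(self, panel_types: Mapping[str, str]):
        self.panel_types = dict(panel_types)
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self.panel_types)

    def copy(self) -> "LinkGraph":
        new = LinkGraph(self.panel_types)
        new._g = self._g.copy()
        return new

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, v, d["effect"]) for u, v, d in self._g.edges(data=True)]

    def transmitters_of(self, panel_id: str) -> list[tuple[str, str]]:
        return [(u, self._g.edges[u, panel_id]["effect"]) for u in self._g.predecessors(panel_id)]

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self._g)


def _check_effect(graph: LinkGraph, transmitter: str, receiver: str, effect: str) -> None:
    t_type = graph.panel_types[transmitter]
    r_type = graph.panel_types[receiver]
    if t_type == "row_table":
        if effect not in _TABLE_EFFECTS:
            raise LinkError(
                f"row_table links carry a semantic effect {_TABLE_EFFECTS}, got {effect!r}"
            )
        if effect == "colour_by" and r_type not in _SAMPLE_PLOTS:
            raise LinkError("a table colour link needs a sample-based plot receiver")
        if effect == "y_feature" and r_type != "feature_assay":
            raise LinkError("a table y-axis link needs a feature_assay receiver")
        if effect == "features" and r_type != "heatmap":
            raise LinkError("a table feature-set link needs a heatmap receiver")
        return
    if t_type == "heatmap":
        raise LinkError("heatmaps cannot transmit selections")
    if effect not in _POINT_EFFECTS:
        raise LinkError(f"plot links carry effect in {_POINT_EFFECTS}, got {effect!r}")
    if r_type == "row_table":
        if t_type != "row_data":
            raise LinkError(
                "only feature-metadata (row_data) plots can subset a row table"
            )
        return
    t_dom, r_dom = panel_domain(t_type), panel_domain(r_type)
    if t_dom != r_dom:
        raise LinkError(
            f"domain mismatch: {transmitter} transmits {t_dom} ids but "
            f"{receiver} displays {r_dom}-based points"
        )
    if r_type == "heatmap" and effect != "restrict":
        raise LinkError("heatmap receivers only support restrict links")


def add_link(graph: LinkGraph, transmitter: str, receiver: str, effect: str) -> LinkGraph:
    """Return a new graph with the edge added, iff the result stays acyclic
    and the receiver accepts the transmitter's selection type.
    """
    for pid in (transmitter, receiver):
        if pid not in graph.panel_types:
            raise LinkError(f"unknown panel {pid!r}")
    if transmitter == receiver:
        raise LinkError(f"self-link rejected: cycle [{transmitter!r}]")
    _check_effect(graph, transmitter, receiver, effect)
    new = graph.copy()
    new._g.add_edge(transmitter, receiver, effect=effect)
    if not new.is_acyclic():
        cycle = nx.find_cycle(new._g)
        raise LinkError(f"link {transmitter}->{receiver} rejected: cycle {cycle}")
    return new


# ---------------------------------------------------------------------------
# Table links
# ---------------------------------------------------------------------------

def table_transmit(
    selection: Selection,
    receiver: PanelConfig,
    effect: str | None = None,
    features: list[str] | None = None,
    default_assay: str | None = None,
) -> PanelConfig:
    """Apply a row-table transmission to a receiving panel's configuration.

    A colour link points the receiver's ``colour_by`` at the selected
    feature's assay values; a y-axis link swaps a feature-assay plot's
    feature; a feature-set link replaces a heatmap's feature list with the
    table's current (possibly filtered) rows, given as ``features``.
    """
    if effect is None:
        effect = {
            "heatmap": "features",
            "feature_assay": "y_feature",
        }.get(receiver.panel_type, "colour_by")
    updated = copy.deepcopy(receiver)
    if effect == "features":
        if features is None:
            raise ValueError("a feature-set link needs the table's current rows")
        if not features:
            logger.warning(
                "panel %s: table transmitted an empty feature set", receiver.panel_id
            )
        updated.features = [str(f) for f in features]
        return updated

    if not isinstance(selection.shape, TableRow):
        raise ValueError("table transmission needs a table_row selection")
    feature = selection.shape.feature
    if effect == "y_feature":
        updated.feature = feature
    elif effect == "colour_by":
        assay = None
        if receiver.colour_by and receiver.colour_by.get("slot") == "feature":
            assay = receiver.colour_by.get("assay")
        assay = assay or receiver.assay or default_assay
        if assay is None:
            raise ValueError(
                f"panel {receiver.panel_id}: no assay available for a colour link"
            )
        updated.colour_by = {"slot": "feature", "feature": feature, "assay": assay}
    else:
        raise ValueError(f"unknown table link effect {effect!r}")
    return updated


def rowplot_to_table(selection: Selection, table_spec: PlotSpec) -> PlotSpec:
    """Subset a row table's rows to a feature-plot selection.

    A cleared selection (no captured ids) restores the full table; an empty
    capture yields a zero-row table carrying a warning flag.
    """
    data = dict(table_spec.data or {})
    if selection.captured_ids is None:
        data.pop("warning", None)
        return dataclasses.replace(table_spec, data=data)
    rows = [r for r in data.get("rows", []) if r in selection.captured_ids]
    data["rows"] = rows
    if not rows:
        data["warning"] = "selection restricted the table to zero rows"
        logger.warning("panel %s: %s", table_spec.panel_id, data["warning"])
    return dataclasses.replace(table_spec, data=data)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def propagate(
    graph: LinkGraph,
    panels: Mapping[str, PanelConfig],
    selections: Mapping[str, Selection],
    container: OmicsContainer,
    registry: ColorMapRegistry,
    seed: int = 0,
) -> dict[str, PlotSpec]:
    """Evaluate every panel, flowing selections along the link graph.

    Panels are visited in lexicographic topological order. Each receiver's
    effective restriction is the intersection of its restrict-transmitters'
    captured id sets (transmitters with no active selection impose no
    constraint; an *empty* capture restricts to zero points, with a warning).
    Selections are stored as shapes in display coordinates and re-captured
    from each freshly built spec, so a downstream selection operates on the
    already-restricted population — chained gating. The result is independent
    of edge insertion order.
    """
    if not graph.is_acyclic():
        raise LinkError(f"cannot propagate over a cyclic graph: {nx.find_cycle(graph._g)}")
    order = list(nx.lexicographical_topological_sort(graph._g))
    order += [pid for pid in sorted(panels) if pid not in set(order)]

    container_hash = container.content_hash()
    specs: dict[str, PlotSpec] = {}
    captured: dict[str, set | None] = {}

    for pid in order:
        if pid not in panels:
            continue
        cfg = panels[pid]
        restrict_sets: list[set] = []
        highlight_sets: list[set] = []
        for t, effect in sorted(graph.transmitters_of(pid)):
            t_type = graph.panel_types[t]
            if t_type == "row_table":
                sel = selections.get(t)
                if effect == "features":
                    rows = (specs[t].data or {}).get("rows", []) if t in specs else None
                    if rows:
                        cfg = table_transmit(sel or Selection(t), cfg, effect, features=rows)
                elif sel is not None and isinstance(sel.shape, TableRow):
                    default_assay = next(iter(container.assays))
                    cfg = table_transmit(sel, cfg, effect, default_assay=default_assay)
                continue
            got = captured.get(t)
            if got is None:
                continue
            if effect == "restrict":
                restrict_sets.append(got)
            else:
                highlight_sets.append(got)

        restrict: set | None = None
        if restrict_sets:
            restrict = set.intersection(*restrict_sets)
            if not restrict:
                logger.warning("panel %s: incoming selection restricts to zero points", pid)
        highlight: set | None = None
        if highlight_sets:
            highlight = set.intersection(*highlight_sets)

        spec = build_plot_spec(
            cfg,
            container,
            registry,
            seed=seed,
            restrict_ids=restrict,
            highlight_ids=highlight,
            container_hash=container_hash,
        )
        specs[pid] = spec

        sel = selections.get(pid)
        if sel is not None and sel.shape is not None:
            ids = capture_selection(spec, sel.shape)
            captured[pid] = ids
            sel.captured_ids = ids
        else:
            captured[pid] = None
    return specs
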