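"""Shared fixtures and independent oracles for the test suite.

The fixture container is the seeded synthetic data set from
``make_example_container`` (60 features x 40 samples, 3 clusters). The
oracles here — naive fixpoint propagation and random session/graph
generators — deliberately avoid the code paths they are used to check.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from omicspanels.colormaps import default_registry
from omicspanels.container import make_example_container, write_container
from omicspanels.linking import (
    Lasso,
    LinkError,
    LinkGraph,
    RectBrush,
    Selection,
    TableRow,
    add_link,
    capture_selection,
    table_transmit,
)
from omicspanels.plotspec import PanelConfig, build_plot_spec
from omicspanels.tracking import AppState, PanelSlot


@pytest.fixture(scope="session")
def container():
    return make_example_container(60, 40, 3, seed=2)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def manifest_path(container, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_container")
    return write_container(container, out)


# ---------------------------------------------------------------------------
# Naive fixpoint propagation oracle
# ---------------------------------------------------------------------------

def fixpoint_propagate(graph, panels, selections, container, registry, seed=0):
    """Re-evaluate every panel repeatedly until captures stabilize.

    Independent of the topological-order evaluator: no ordering logic at all,
    just repeated passes until nothing changes.
    """
    captured = {pid: None for pid in panels}
    specs: dict = {}
    specs_prev: dict = {}
    for iteration in range(len(panels) + 3):
        new_captured = {}
        specs = {}
        for pid, cfg in panels.items():
            cfg = copy.deepcopy(cfg)
            restrict_sets, highlight_sets = [], []
            for t, effect in graph.transmitters_of(pid):
                t_type = graph.panel_types[t]
                if t_type == "row_table":
                    sel = selections.get(t)
                    if effect == "features":
                        prev = specs_prev.get(t)
                        rows = (prev.data or {}).get("rows", []) if prev else None
                        if rows:
                            cfg = table_transmit(sel or Selection(t), cfg, effect, features=rows)
                    elif sel is not None and isinstance(sel.shape, TableRow):
                        cfg = table_transmit(
                            sel, cfg, effect, default_assay=next(iter(container.assays))
                        )
                    continue
                got = captured.get(t)
                if got is None:
                    continue
                (restrict_sets if effect == "restrict" else highlight_sets).append(got)
            restrict = set.intersection(*restrict_sets) if restrict_sets else None
            highlight = set.intersection(*highlight_sets) if highlight_sets else None
            spec = build_plot_spec(
                cfg, container, registry, seed=seed,
                restrict_ids=restrict, highlight_ids=highlight,
            )
            specs[pid] = spec
            sel = selections.get(pid)
            if sel is not None and sel.shape is not None:
                new_captured[pid] = capture_selection(spec, sel.shape)
            else:
                new_captured[pid] = None
        stable = new_captured == captured
        specs_prev = specs
        captured = new_captured
        # tables feed receivers their row sets one pass late, so require a
        # second stable pass before accepting the fixpoint
        if stable and iteration >= 1:
            break
    return specs


# ---------------------------------------------------------------------------
# Random sessions
# ---------------------------------------------------------------------------

def random_panels(rng: np.random.Generator, container, max_panels=8):
    """A random panel set referencing only names present in the container."""
    n = int(rng.integers(2, max_panels + 1))
    makers = [
        lambda pid: PanelConfig(pid, "reduced_dim", reduced_dim="tsne"),
        lambda pid: PanelConfig(
            pid, "column_data", x_var="cluster", y_var="total_count"
        ),
        lambda pid: PanelConfig(
            pid,
            "feature_assay",
            assay="logcounts",
            feature=container.feature_ids[int(rng.integers(len(container.feature_ids)))],
            x_var="cluster",
        ),
        lambda pid: PanelConfig(
            pid, "row_data", x_var="mean_log_expression", y_var="n_detected"
        ),
        lambda pid: PanelConfig(pid, "row_table"),
        lambda pid: PanelConfig(
            pid,
            "heatmap",
            assay="logcounts",
            features=list(container.feature_ids[:4]),
            order_by=["cluster"],
        ),
    ]
    panels = {}
    for i in range(n):
        pid = f"P{i + 1}"
        maker = makers[int(rng.integers(len(makers)))]
        panels[pid] = maker(pid)
    return panels


def random_selection(rng: np.random.Generator, cfg: PanelConfig, container):
    """A random shape plausible for the panel's display coordinate ranges."""
    if cfg.panel_type == "row_table":
        fid = container.feature_ids[int(rng.integers(len(container.feature_ids)))]
        return Selection(cfg.panel_id, TableRow(fid))
    if cfg.panel_type == "heatmap":
        return None
    if cfg.panel_type == "reduced_dim":
        emb = container.reduced_dims["tsne"]
        lo, hi = emb.min(0) - 1, emb.max(0) + 1
    elif cfg.panel_type == "row_data":
        lo = np.array([0.0, 0.0])
        hi = np.array([8.0, 45.0])
    else:
        lo = np.array([-0.6, 0.0])
        hi = np.array([3.0, 4000.0])
    a = rng.uniform(lo, hi)
    b = rng.uniform(lo, hi)
    if rng.random() < 0.5:
        return Selection(
            cfg.panel_id,
            RectBrush(min(a[0], b[0]), max(a[0], b[0]), min(a[1], b[1]), max(a[1], b[1])),
        )
    cx, cy = (a + b) / 2
    r = rng.uniform(0.1, 1.0) * (hi - lo).max() / 2
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=int(rng.integers(3, 8))))
    verts = tuple((cx + r * np.cos(t), cy + r * np.sin(t)) for t in angles)
    if len(verts) < 3:
        return None
    return Selection(cfg.panel_id, Lasso(verts))


def random_link_graph(rng: np.random.Generator, panels, max_edges=12):
    """Random legal DAG: attempts random edges, keeping those add_link accepts."""
    graph = LinkGraph({pid: p.panel_type for pid, p in panels.items()})
    links = []
    ids = list(panels)
    effects = ["restrict", "restrict", "highlight", "colour_by", "y_feature", "features"]
    for _ in range(3 * max_edges):
        if len(links) >= max_edges:
            break
        t, r = (ids[int(i)] for i in rng.integers(len(ids), size=2))
        effect = effects[int(rng.integers(len(effects)))]
        try:
            graph = add_link(graph, t, r, effect)
        except LinkError:
            continue
        links.append({"from": t, "to": r, "effect": effect})
    return graph, links


def random_app_state(rng: np.random.Generator, container, manifest: str):
    panels = random_panels(rng, container, max_panels=6)
    graph, links = random_link_graph(rng, panels, max_edges=8)
    selections = {}
    for pid, cfg in panels.items():
        if rng.random() < 0.7:
            sel = random_selection(rng, cfg, container)
            if sel is not None:
                selections[pid] = sel
    return AppState(
        panels=[PanelSlot(cfg) for cfg in panels.values()],
        links=links,
        selections=selections,
        colormap_decl={},
        manifest=str(manifest),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
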