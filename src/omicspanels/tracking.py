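"""Session state: canonical serialization, restoration, code emission, tours.

An :class:`AppState` captures everything needed to rebuild an exploration
session bit-for-bit: the panel configurations and their layout sizes, the
link graph, every brush/lasso/table-row selection at full float precision,
the declarative colormap specification, a reference to the container
manifest, and the master seed driving jittered point placement.

States serialize to canonical JSON (sorted keys, compact, versioned), so
equal states produce byte-identical documents. :func:`emit_plot_code` goes a
step further and writes a runnable, self-contained Python script — one
clearly delimited block per panel — whose execution regenerates every
panel's plot specification exactly as the live session would.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping

from ._canonical import canonical_dumps
from .colormaps import registry_from_declaration
from .container import LookupError_, OmicsContainer
from .linking import (
    LinkGraph,
    Selection,
    add_link,
    propagate,
    shape_from_dict,
    shape_to_dict,
)
from .plotspec import PanelConfig, PlotSpec, validate_panel

logger = logging.getLogger(__name__)

SUPPORTED_VERSION = 1

__all__ = [
    "AppState",
    "PanelSlot",
    "TourSpec",
    "StateError",
    "serialize_state",
    "restore_state",
    "evaluate_state",
    "emit_plot_code",
    "validate_tour",
]


class StateError(ValueError):
    """The state document is malformed, unsupported or references dead names."""


@dataclasses.dataclass
class PanelSlot:
    """A panel plus its layout footprint in grid units."""

    config: PanelConfig
    width: int = 4
    height: int = 4


@dataclasses.dataclass
class TourSpec:
    """Ordered (target, text) steps guiding a viewer through a session."""

    steps: list  # list of (target, text) tuples


@dataclasses.dataclass
class AppState:
    """Complete serializable session state."""

    panels: list  # list[PanelSlot]
    links: list = dataclasses.field(default_factory=list)  # [{from,to,effect}]
    selections: dict = dataclasses.field(default_factory=dict)  # pid -> Selection
    colormap_decl: dict = dataclasses.field(default_factory=dict)
    manifest: str = ""
    seed: int = 0
    version: int = SUPPORTED_VERSION

    def panel_ids(self) -> list[str]:
        return [slot.config.panel_id for slot in self.panels]

    def panel_map(self) -> dict[str, PanelConfig]:
        return {slot.config.panel_id: slot.config for slot in self.panels}

    def link_graph(self) -> LinkGraph:
        graph = LinkGraph({pid: cfg.panel_type for pid, cfg in self.panel_map().items()})
        for link in self.links:
            graph = add_link(graph, link["from"], link["to"], link["effect"])
        return graph


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _state_to_dict(state: AppState) -> dict:
    return {
        "version": state.version,
        "seed": int(state.seed),
        "manifest": state.manifest,
        "colormaps": state.colormap_decl,
        "panels": [
            {"config": slot.config.to_dict(), "width": slot.width, "height": slot.height}
            for slot in state.panels
        ],
        "links": [
            {"from": l["from"], "to": l["to"], "effect": l["effect"]} for l in state.links
        ],
        "selections": {
            pid: shape_to_dict(sel.shape)
            for pid, sel in state.selections.items()
            if sel.shape is not None
        },
    }


def serialize_state(state: AppState) -> str:
    """Canonical, versioned state document; byte-identical for equal states."""
    if state.version != SUPPORTED_VERSION:
        raise StateError(
            f"unsupported state version {state.version} (supported: {SUPPORTED_VERSION})"
        )
    ids = state.panel_ids()
    if len(set(ids)) != len(ids):
        raise StateError(f"duplicate panel ids in state: {ids}")
    return canonical_dumps(_state_to_dict(state))


def restore_state(document: str, container: OmicsContainer | None = None) -> AppState:
    """Rebuild an AppState from a document, validating every reference.

    With a container given, panel variable/assay/feature references are
    checked against it and dangling names raise a :class:`StateError` listing
    them. Restoring then serializing is the identity on documents.
    """
    try:
        raw = json.loads(document)
    except json.JSONDecodeError as exc:
        raise StateError(f"malformed state document: {exc}") from exc
    version = raw.get("version")
    if version != SUPPORTED_VERSION:
        raise StateError(
            f"unsupported state version {version} (supported: {SUPPORTED_VERSION})"
        )
    panels = [
        PanelSlot(
            config=PanelConfig.from_dict(p["config"]),
            width=int(p.get("width", 4)),
            height=int(p.get("height", 4)),
        )
        for p in raw.get("panels", [])
    ]
    state = AppState(
        panels=panels,
        links=[dict(l) for l in raw.get("links", [])],
        selections={
            pid: Selection(source_panel=pid, shape=shape_from_dict(sd))
            for pid, sd in raw.get("selections", {}).items()
        },
        colormap_decl=raw.get("colormaps", {}),
        manifest=raw.get("manifest", ""),
        seed=int(raw.get("seed", 0)),
        version=version,
    )

    problems: list[str] = []
    ids = set(state.panel_ids())
    for link in state.links:
        for end in ("from", "to"):
            if link.get(end) not in ids:
                problems.append(f"link references unknown panel {link.get(end)!r}")
    for pid in state.selections:
        if pid not in ids:
            problems.append(f"selection references unknown panel {pid!r}")
    if container is not None:
        for slot in state.panels:
            try:
                validate_panel(slot.config, container)
            except (LookupError_, KeyError, ValueError) as exc:
                problems.append(str(exc))
    if problems:
        raise StateError("invalid state document: " + "; ".join(problems))
    state.link_graph()  # raises on cycles / illegal effects
    return state


def evaluate_state(state: AppState, container: OmicsContainer) -> dict[str, PlotSpec]:
    """Build every panel's PlotSpec by propagating over the state's links."""
    registry = registry_from_declaration(state.colormap_decl)
    return propagate(
        state.link_graph(),
        state.panel_map(),
        state.selections,
        container,
        registry,
        seed=state.seed,
    )


# ---------------------------------------------------------------------------
# Code emission
# ---------------------------------------------------------------------------

_SCRIPT_HEADER = '''\
#!/usr/bin/env python
"""Session reproduction script (auto-generated).

Running this script rebuilds the exact plot specification of every panel in
the session it was emitted from: same container, same panel parameters, same
links, same selections, same seed. Pass an output directory to write one
canonical PlotSpec JSON per panel.
"""
import sys
from pathlib import Path

from omicspanels.colormaps import registry_from_declaration
from omicspanels.container import load_container_manifest
from omicspanels.linking import LinkGraph, Selection, add_link, propagate, shape_from_dict
from omicspanels.plotspec import PanelConfig
'''


def emit_plot_code(state: AppState) -> str:
    """A runnable, self-contained script regenerating every panel's spec.

    The script loads the container from the session's manifest, rebuilds the
    colormap registry, panel configurations (one block per panel), links and
    selections, and re-propagates with the stored master seed. Its
    ``replay(out_dir)`` function returns {panel_id: canonical spec document}
    and equals direct evaluation of the live state byte-for-byte.
    """
    serialize_state(state)  # validates
    lines = [_SCRIPT_HEADER]
    lines.append(f"SEED = {int(state.seed)}")
    lines.append(f"MANIFEST = {state.manifest!r}")
    lines.append("container = load_container_manifest(MANIFEST)")
    lines.append(
        f"registry = registry_from_declaration({json.loads(canonical_dumps(state.colormap_decl))!r})"
    )
    lines.append("")
    lines.append("panels = {}")
    lines.append("selections = {}")
    for slot in state.panels:
        cfg = slot.config
        lines.append("")
        lines.append(f"# === panel {cfg.panel_id} ({cfg.panel_type}) ===")
        cfg_dict = json.loads(canonical_dumps(cfg.to_dict()))
        lines.append(f"panels[{cfg.panel_id!r}] = PanelConfig.from_dict({cfg_dict!r})")
        sel = state.selections.get(cfg.panel_id)
        if sel is not None and sel.shape is not None:
            sd = json.loads(canonical_dumps(shape_to_dict(sel.shape)))
            lines.append(
                f"selections[{cfg.panel_id!r}] = Selection("
                f"source_panel={cfg.panel_id!r}, shape=shape_from_dict({sd!r}))"
            )
    lines.append("")
    lines.append("# === links ===")
    lines.append("graph = LinkGraph({pid: p.panel_type for pid, p in panels.items()})")
    for link in state.links:
        lines.append(
            f"graph = add_link(graph, {link['from']!r}, {link['to']!r}, {link['effect']!r})"
        )
    lines.append("")
    lines.append(
        "\n".join(
            [
                "def replay(out_dir=None):",
                "    specs = propagate(graph, panels, selections, container, registry, seed=SEED)",
                "    docs = {pid: spec.to_document() for pid, spec in specs.items()}",
                "    if out_dir is not None:",
                "        out = Path(out_dir)",
                "        out.mkdir(parents=True, exist_ok=True)",
                "        for pid, doc in docs.items():",
                "            (out / f'{pid}.json').write_text(doc)",
                "    return docs",
                "",
                "",
                "if __name__ == '__main__':",
                "    replay(sys.argv[1] if len(sys.argv) > 1 else '.')",
            ]
        )
    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Tours
# ---------------------------------------------------------------------------

#: interface element keys a tour may target besides live panel ids
_ELEMENT_KEYS = {"session", "layout", "colormaps", "links"}


def validate_tour(tour: TourSpec, state: AppState) -> list[str]:
    """Issues preventing a tour from running against a session; [] if clean."""
    issues: list[str] = []
    if not tour.steps:
        return ["tour has no steps"]
    live = set(state.panel_ids()) | _ELEMENT_KEYS
    for i, step in enumerate(tour.steps):
        target, _text = step[0], step[1]
        if target not in live:
            issues.append(f"step {i + 1} targets unknown panel/element {target!r}")
    return issues
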