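"""Hierarchical colormap registry and colour assignment.

A colormap is a small function object: either a *count form* that, asked for
``n`` colours, returns an ordered list of ``n`` colour strings, or a *named
form* that fixes a level -> colour mapping for a known factor. A registry
resolves which colormap applies to a given variable by precedence:

    per-variable  >  shared (slot, kind) default  >  global kind default

so resolution is total — the global defaults always exist.

Defaults: a fixed 12-colour qualitative cycle for categorical variables and a
256-step perceptually-uniform (viridis) ramp for continuous ones; both are
frozen at import so colour output is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping, Sequence

import numpy as np
from matplotlib import colormaps as _mpl_colormaps
from matplotlib.colors import to_hex

from .container import VariableKind

logger = logging.getLogger(__name__)

__all__ = [
    "ColorMapFn",
    "palette_colormap",
    "named_colormap",
    "ColorMapRegistry",
    "resolve_colormap",
    "assign_colors",
    "default_registry",
    "registry_from_declaration",
    "QUALITATIVE_12",
    "VIRIDIS_256",
    "MISSING_COLOR",
    "INTERPOLATION_RESOLUTION",
]

MISSING_COLOR = "#AAAAAA"
INTERPOLATION_RESOLUTION = 256

# 12-colour qualitative cycle (tab10 plus two light companions), stored as a
# literal so categorical colours never depend on plotting-library internals.
QUALITATIVE_12: tuple[str, ...] = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD", "#8C564B",
    "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF", "#AEC7E8", "#FFBB78",
)

# 256-step viridis ramp, materialized once from matplotlib's literal LUT.
VIRIDIS_256: tuple[str, ...] = tuple(
    to_hex(c).upper() for c in _mpl_colormaps["viridis"](np.linspace(0.0, 1.0, 256))
)


def _interp_hex(colors: Sequence[str], n: int) -> list[str]:
    """Linear RGB interpolation of a colour list to exactly n colours."""
    rgb = np.array(
        [[int(c.lstrip("#")[i : i + 2], 16) for i in (0, 2, 4)] for c in colors],
        dtype=float,
    )
    if len(colors) == 1:
        rgb = np.vstack([rgb, rgb])
    xs = np.linspace(0.0, len(rgb) - 1.0, n)
    out = []
    for x in xs:
        lo = int(np.floor(x))
        hi = min(lo + 1, len(rgb) - 1)
        frac = x - lo
        mixed = np.round(rgb[lo] * (1 - frac) + rgb[hi] * frac).astype(int)
        out.append("#{:02X}{:02X}{:02X}".format(*mixed))
    return out


@dataclasses.dataclass(frozen=True)
class ColorMapFn:
    """A resolvable colormap: count-form callable or fixed named mapping.

    Exactly one of ``count_fn`` / ``named`` is set. Count-form maps are called
    with the number of colours wanted; named maps are used directly for level
    lookup (and only make sense for categorical variables).
    """

    count_fn: Callable[[int], list[str]] | None = None
    named: Mapping[str, str] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if (self.count_fn is None) == (self.named is None):
            raise ValueError("exactly one of count_fn or named must be given")

    @property
    def is_named(self) -> bool:
        return self.named is not None

    def colors(self, n: int) -> list[str]:
        if self.is_named:
            raise TypeError("named colormaps are not callable with a count")
        out = list(self.count_fn(n))
        if len(out) != n:
            raise ValueError(
                f"colormap {self.label or '<anon>'} returned {len(out)} colours, wanted {n}"
            )
        if len(set(out)) != len(out):
            # accepted, but noted (8-bit hex rounding collapses neighbouring
            # ramp entries, so this is routine for 256-step ramps)
            logger.debug(
                "colormap %s returned duplicate colours for n=%d", self.label or "<anon>", n
            )
        return out


def palette_colormap(
    colors: Sequence[str], mode: str = "cycle", label: str = ""
) -> ColorMapFn:
    """Count-form colormap backed by a fixed colour list.

    ``mode="cycle"`` (categorical use) returns the first n colours, recycling
    with a warning past the palette's capacity; ``mode="interpolate"``
    (continuous use) linearly interpolates the list to n colours.
    """
    colors = [str(c) for c in colors]
    if not colors:
        raise ValueError("palette must contain at least one colour")
    if mode not in ("cycle", "interpolate"):
        raise ValueError(f"unknown palette mode {mode!r}")

    if mode == "cycle":
        def fn(n: int) -> list[str]:
            if n > len(colors):
                logger.warning(
                    "palette %s recycled: %d levels > %d colours",
                    label or "<anon>", n, len(colors),
                )
            return [colors[i % len(colors)] for i in range(n)]
    else:
        def fn(n: int) -> list[str]:
            return _interp_hex(colors, n)

    return ColorMapFn(count_fn=fn, label=label or f"palette[{len(colors)},{mode}]")


def named_colormap(mapping: Mapping[str, str], label: str = "") -> ColorMapFn:
    """Named-form colormap fixing the colour of each known factor level."""
    return ColorMapFn(named=dict(mapping), label=label or "named")


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_SLOTS = ("assay", "coldata", "rowdata")
_KINDS = ("categorical", "continuous")


@dataclasses.dataclass
class ColorMapRegistry:
    """Precedence hierarchy of colormaps.

    ``per_assay`` / ``per_coldata_var`` / ``per_rowdata_var`` hold
    per-variable entries; ``shared_defaults`` is keyed by (slot, kind);
    ``global_defaults`` by kind and must cover both kinds so resolution never
    fails.
    """

    per_assay: dict = dataclasses.field(default_factory=dict)
    per_coldata_var: dict = dataclasses.field(default_factory=dict)
    per_rowdata_var: dict = dataclasses.field(default_factory=dict)
    shared_defaults: dict = dataclasses.field(default_factory=dict)
    global_defaults: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind in _KINDS:
            if kind not in self.global_defaults:
                raise ValueError(f"global_defaults must define kind {kind!r}")

    def _per_variable(self, slot: str) -> dict:
        return {
            "assay": self.per_assay,
            "coldata": self.per_coldata_var,
            "rowdata": self.per_rowdata_var,
        }[slot]


def default_registry() -> ColorMapRegistry:
    """Registry holding only the two frozen global defaults."""
    return ColorMapRegistry(
        global_defaults={
            "categorical": palette_colormap(QUALITATIVE_12, "cycle", "qualitative12"),
            "continuous": palette_colormap(VIRIDIS_256, "interpolate", "viridis256"),
        }
    )


def resolve_colormap(
    registry: ColorMapRegistry, slot: str, name: str, kind: VariableKind
) -> ColorMapFn:
    """Most specific applicable colormap for a variable.

    Precedence: per-variable entry for (slot, name), then the shared
    (slot, kind) default, then the global kind default. Total by construction.
    """
    if slot not in _SLOTS:
        raise ValueError(f"unknown slot {slot!r}; expected one of {_SLOTS}")
    per_var = registry._per_variable(slot)
    if name in per_var:
        return per_var[name]
    shared = registry.shared_defaults.get((slot, kind.kind))
    if shared is not None:
        return shared
    return registry.global_defaults[kind.kind]


def assign_colors(
    fn: ColorMapFn, kind: VariableKind, values
) -> tuple[list[str], dict]:
    """Evaluate a colormap into per-point colours plus a legend.

    Categorical: one colour per level (named form looked up directly — a level
    present in the data but absent from the map is an error; count form called
    with n = number of levels, assigned in level order). Continuous: the count
    form is called at the interpolation resolution (256) and each value maps
    linearly between the observed min and max; a degenerate (constant) vector
    maps everything to the ramp's first colour. Missing values are coloured
    grey and excluded from the legend.
    """
    values = np.asarray(values, dtype=object)
    if kind.is_categorical:
        levels = list(kind.levels)
        if fn.is_named:
            present = {v for v in values if not _is_missing(v)}
            missing_levels = sorted(str(v) for v in present if _lookup(fn.named, v) is None)
            if missing_levels:
                raise KeyError(
                    f"named colormap lacks colours for levels: {missing_levels}"
                )
            level_colors = {
                lvl: _lookup(fn.named, lvl) for lvl in levels if _lookup(fn.named, lvl) is not None
            }
        else:
            palette = fn.colors(len(levels))
            level_colors = dict(zip(levels, palette))
        colors = [
            MISSING_COLOR if _is_missing(v) else level_colors[_match_level(levels, v)]
            for v in values
        ]
        legend = {"kind": "categorical", "entries": {str(k): v for k, v in level_colors.items()}}
        return colors, legend

    ramp = fn.colors(INTERPOLATION_RESOLUTION)
    numeric = np.array([np.nan if _is_missing(v) else float(v) for v in values])
    finite = numeric[np.isfinite(numeric)]
    if finite.size == 0:
        raise ValueError("cannot colour an all-missing continuous vector")
    vmin, vmax = float(finite.min()), float(finite.max())
    colors = []
    for v in numeric:
        if not np.isfinite(v):
            colors.append(MISSING_COLOR)
        elif vmax == vmin:
            colors.append(ramp[0])
        else:
            frac = (v - vmin) / (vmax - vmin)
            idx = int(np.floor(frac * (len(ramp) - 1) + 0.5))
            colors.append(ramp[idx])
    legend = {
        "kind": "continuous",
        "vmin": vmin,
        "vmax": vmax,
        "low": ramp[0],
        "high": ramp[-1],
    }
    return colors, legend


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(np.isnan(v))
    except (TypeError, ValueError):
        return False


def _lookup(mapping: Mapping, level):
    if level in mapping:
        return mapping[level]
    return mapping.get(str(level))


def _match_level(levels: list, v):
    if v in levels:
        return v
    sv = str(v)
    for lvl in levels:
        if str(lvl) == sv:
            return lvl
    raise KeyError(f"value {v!r} not among levels {levels}")


# ---------------------------------------------------------------------------
# Declarative registry specification (for session configs / state documents)
# ---------------------------------------------------------------------------
#
# Declarations are pure data (JSON-able), e.g.:
#   {"per_coldata_var": {"cluster": {"named": {"C1": "#FF0000", ...}}},
#    "shared": {"coldata": {"categorical": {"palette": ["#111111", ...]}}},
#    "global": {"continuous": {"builtin": "viridis256"}}}

_BUILTIN_PALETTES = {
    "qualitative12": (QUALITATIVE_12, "cycle"),
    "viridis256": (VIRIDIS_256, "interpolate"),
}


def _fn_from_entry(entry: Mapping, kind_hint: str) -> ColorMapFn:
    if "named" in entry:
        return named_colormap(entry["named"])
    if "palette" in entry:
        mode = entry.get("mode", "interpolate" if kind_hint == "continuous" else "cycle")
        return palette_colormap(entry["palette"], mode)
    if "builtin" in entry:
        name = entry["builtin"]
        if name not in _BUILTIN_PALETTES:
            raise ValueError(f"unknown builtin palette {name!r}")
        colors, mode = _BUILTIN_PALETTES[name]
        return palette_colormap(colors, mode, name)
    raise ValueError(f"colormap entry needs 'named', 'palette' or 'builtin': {entry}")


def registry_from_declaration(decl: Mapping | None) -> ColorMapRegistry:
    """Build a registry from a declarative (JSON) specification.

    Unspecified pieces fall back to the frozen defaults; only declarative
    palettes are supported (no executable code in configs).
    """
    reg = default_registry()
    if not decl:
        return reg
    for key, target in (
        ("per_assay", reg.per_assay),
        ("per_coldata_var", reg.per_coldata_var),
        ("per_rowdata_var", reg.per_rowdata_var),
    ):
        for name, entry in decl.get(key, {}).items():
            # per-assay colormaps colour continuous assay values
            hint = "continuous" if key == "per_assay" else "categorical"
            target[name] = _fn_from_entry(entry, hint)
    for slot, kinds in decl.get("shared", {}).items():
        for kind, entry in kinds.items():
            reg.shared_defaults[(slot, kind)] = _fn_from_entry(entry, kind)
    for kind, entry in decl.get("global", {}).items():
        reg.global_defaults[kind] = _fn_from_entry(entry, kind)
    return reg
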