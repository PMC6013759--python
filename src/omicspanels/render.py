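"""Optional rasterization of plot specs to SVG/PNG.

The canonical artifact of the engine is the JSON PlotSpec; this module is a
convenience for eyeballing specs. Fidelity is intentionally untested beyond
producing a file.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .plotspec import PlotSpec  # noqa: E402


def render_spec(spec: PlotSpec, path: str | Path) -> Path:
    """Draw a spec to an image file (format from the suffix)."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    try:
        if spec.geometry == "heatmap" and spec.data:
            values = np.asarray(spec.data["values"], dtype=float)
            if values.size:
                ax.imshow(values, aspect="auto", cmap="viridis")
            ax.set_yticks(range(len(spec.data["features"])), spec.data["features"])
            ax.set_xticks([])
        elif spec.geometry == "table" and spec.data:
            ax.axis("off")
            ax.text(0.05, 0.95, "\n".join(spec.data["rows"][:20]), va="top", family="monospace")
        else:
            shown = [p for p in spec.points if p["included"]]
            ax.scatter(
                [p["x"] for p in shown],
                [p["y"] for p in shown],
                c=[p["color"] for p in shown],
                alpha=0.8,
                s=12,
            )
            for shape in spec.shapes:
                if "x0" in shape:  # rectangle / bar
                    ax.add_patch(
                        plt.Rectangle(
                            (shape["x0"], shape["y0"]),
                            shape["x1"] - shape["x0"],
                            shape["y1"] - shape["y0"],
                            fill=False,
                            edgecolor="grey",
                        )
                    )
            ax.set_xlabel(spec.axes.get("x", {}).get("label", ""))
            ax.set_ylabel(spec.axes.get("y", {}).get("label", ""))
        ax.set_title(spec.panel_id)
        fig.savefig(path)
    finally:
        plt.close(fig)
    return path
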