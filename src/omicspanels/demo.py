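"""A canonical linked-session demonstrating chained selection propagation.

The session wires five panels the way a typical exploration looks: a row
statistics table drives the y-axis of a feature-assay plot and the colouring
of a reduced-dimension plot; a brush on the embedding gates the sample
metadata plot; a further brush there gates the heatmap. The brushes are
derived deterministically from the container (the first cluster's bounding
box in the embedding; the lower half of library sizes), so the demo is fully
reproducible from the container alone.
"""

from __future__ import annotations

import numpy as np

from .container import OmicsContainer
from .linking import RectBrush, Selection, TableRow
from .plotspec import PanelConfig
from .tracking import AppState, PanelSlot


def demo_state(container: OmicsContainer, manifest: str, seed: int = 0) -> AppState:
    """Build the five-panel gated session for a clustered container.

    Requires the slots the synthetic fixture provides: a ``tsne`` embedding,
    a categorical ``cluster`` and continuous ``total_count`` column, and a
    ``logcounts`` assay.
    """
    emb = np.asarray(container.reduced_dims["tsne"])
    clusters = np.asarray(container.col_data["cluster"], dtype=object)
    first_cluster = clusters[0]
    mask = clusters == first_cluster
    pad = 0.5
    embed_brush = RectBrush(
        float(emb[mask, 0].min() - pad),
        float(emb[mask, 0].max() + pad),
        float(emb[mask, 1].min() - pad),
        float(emb[mask, 1].max() + pad),
    )
    total = np.asarray(container.col_data["total_count"], dtype=float)
    n_levels = len(set(clusters))
    count_brush = RectBrush(
        -0.5, n_levels - 0.5, float(total.min()), float(np.median(total))
    )
    chosen_feature = container.feature_ids[min(6, container.n_features - 1)]

    panels = [
        PanelSlot(PanelConfig("table", "row_table"), width=4),
        PanelSlot(
            PanelConfig(
                "expression", "feature_assay", assay="logcounts",
                feature=container.feature_ids[0], x_var="cluster",
            )
        ),
        PanelSlot(
            PanelConfig(
                "embedding", "reduced_dim", reduced_dim="tsne",
                colour_by={
                    "slot": "feature",
                    "feature": container.feature_ids[0],
                    "assay": "logcounts",
                },
            )
        ),
        PanelSlot(PanelConfig("metadata", "column_data", x_var="cluster", y_var="total_count")),
        PanelSlot(
            PanelConfig(
                "heatmap", "heatmap", assay="logcounts",
                features=list(container.feature_ids[:8]), order_by=["cluster"],
            )
        ),
    ]
    links = [
        {"from": "table", "to": "expression", "effect": "y_feature"},
        {"from": "table", "to": "embedding", "effect": "colour_by"},
        {"from": "embedding", "to": "metadata", "effect": "restrict"},
        {"from": "metadata", "to": "heatmap", "effect": "restrict"},
    ]
    selections = {
        "table": Selection("table", TableRow(chosen_feature)),
        "embedding": Selection("embedding", embed_brush),
        "metadata": Selection("metadata", count_brush),
    }
    return AppState(
        panels=panels, links=links, selections=selections,
        manifest=str(manifest), seed=seed,
    )
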