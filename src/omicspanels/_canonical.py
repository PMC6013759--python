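"""Canonical JSON serialization: sorted keys, compact, NaN-free.

Equal Python structures always serialize to byte-identical documents, which is
what the state-tracking and replay-equality contracts compare.
"""

from __future__ import annotations

import json

import numpy as np


def _plain(obj):
    """Recursively convert numpy scalars/arrays to builtin types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def canonical_dumps(obj) -> str:
    """Serialize to canonical JSON text (sorted keys, compact separators)."""
    return json.dumps(_plain(obj), sort_keys=True, separators=(",", ":"), allow_nan=False)
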