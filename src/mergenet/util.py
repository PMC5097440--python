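"""Small shared helpers."""

from __future__ import annotations

from typing import Collection

__all__ = ["jaccard_index"]


def jaccard_index(x: Collection, y: Collection) -> float:
    """Jaccard overlap |X intersect Y| / |X union Y|; 0 when both are empty."""
    xs, ys = set(x), set(y)
    union = xs | ys
    if not union:
        return 0.0
    return len(xs & ys) / len(union)
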