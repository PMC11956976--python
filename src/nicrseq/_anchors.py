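"""Approximate anchor search shared by the long-read and short-read parsers."""

from __future__ import annotations

import numpy as np

__all__ = ["find_anchor"]


def find_anchor(seq: str, anchor: str, max_mismatch: int, start: int = 0) -> int:
    """Leftmost position >= ``start`` where ``anchor`` matches ``seq`` with at
    most ``max_mismatch`` substitutions, or -1.

    Substitution-only (no indels): matches how the fixed priming sequences are
    located in reads.
    """
    m = len(anchor)
    if m == 0:
        raise ValueError("anchor must be non-empty")
    if len(seq) - start < m:
        return -1
    # exact match at `start` is always the leftmost acceptable hit
    if seq.startswith(anchor, start):
        return start
    a = np.frombuffer(seq[start:].encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(a, m)
    mism = (windows != p).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    if hits.size == 0:
        return -1
    return start + int(hits[0])
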