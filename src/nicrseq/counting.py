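"""Nested-barcode extraction and counting from merged short reads.

Each pooled-screen sample is a file of merged reads carrying the 54-nt
nested barcode between fixed priming sites.  Extraction finds both anchors
(allowing a few substitutions), requires the intervening 54 nt to parse with
exact junctions, and counts exact barcode strings — no error correction;
the long-read whitelist membership filter is the error control.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._anchors import find_anchor
from .barcode import (
    BarcodeError,
    BarcodeLayout,
    Codebook,
    LengthError,
    StructureError,
    UndecodableError,
    parse_nicr,
    reverse_complement,
)

__all__ = [
    "SampleMeta",
    "extract_nicr_barcodes",
    "whitelist_filter",
    "build_count_matrix",
    "merge_read_pair",
]


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample of the screen: a (time, MMS dose) condition."""

    sample_id: str
    time_h: float
    mms_pct: float


def extract_nicr_barcodes(
    reads: Iterable,
    layout: BarcodeLayout | None = None,
    anchor_mismatch: int = 2,
) -> tuple[Counter, Counter]:
    """Count valid 54-nt nested barcodes in merged reads.

    Returns (barcode counts, drop reasons).  A read contributes iff the
    upstream and downstream anchors are found (at most ``anchor_mismatch``
    substitutions each, either strand) and the sequence between them is a
    structurally valid 54-nt barcode (exact junctions).  Drop reasons:
    no_upstream_anchor, no_downstream_anchor, wrong_length,
    junction_mismatch.
    """
    layout = layout or BarcodeLayout()
    up, down = layout.upstream_anchor, layout.downstream_anchor
    counts: Counter = Counter()
    drops: Counter = Counter()
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        seq = seq.upper()
        reason = None
        for candidate in (seq, reverse_complement(seq)):
            i = find_anchor(candidate, up, anchor_mismatch)
            if i < 0:
                reason = reason or "no_upstream_anchor"
                continue
            start = i + len(up)
            j = find_anchor(candidate, down, anchor_mismatch, start=start)
            if j < 0:
                reason = "no_downstream_anchor"
                continue
            barcode = candidate[start:j]
            try:
                parse_nicr(barcode, layout)
            except LengthError:
                reason = "wrong_length"
                continue
            except StructureError:
                reason = "junction_mismatch"
                continue
            counts[barcode] += 1
            reason = None
            break
        if reason is not None:
            drops[reason] += 1
    return counts, drops


def whitelist_filter(
    counts: Mapping[str, int],
    whitelists: Mapping[int, set],
    layout: BarcodeLayout | None = None,
) -> Counter:
    """Keep a nested barcode iff all three unit barcodes are whitelisted.

    ``whitelists`` maps set_id (1..3) to the set of verified 14-nt barcode
    strings from long-read QC.  Idempotent and monotone: counts are never
    altered, only kept or removed.
    """
    layout = layout or BarcodeLayout()
    for s in (1, 2, 3):
        if s not in whitelists:
            raise BarcodeError(f"missing whitelist for set {s}")
    kept: Counter = Counter()
    for barcode, n in counts.items():
        icrs = parse_nicr(barcode, layout)
        if all(icr.sequence in whitelists[s] for s, icr in zip((1, 2, 3), icrs)):
            kept[barcode] = n
    return kept


def build_count_matrix(
    sample_counts: Mapping[str, Mapping[str, int]],
    meta: Iterable[SampleMeta],
    codebook: Codebook,
    layout: BarcodeLayout | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the barcode x sample count matrix.

    ``sample_counts`` maps sample_id to that sample's barcode counts; rows
    are the union of barcodes, zero where absent, each annotated with its
    decoded genotype label.  Returns (counts, meta_frame); counts has a
    leading ``genotype`` column.
    """
    layout = layout or BarcodeLayout()
    meta = list(meta)
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise BarcodeError("duplicate sample_id in sample sheet")
    missing = set(sample_counts) - set(ids)
    if missing:
        raise BarcodeError(f"samples without metadata: {sorted(missing)}")
    frame = pd.DataFrame(
        {sid: pd.Series(dict(sample_counts.get(sid, {})), dtype="int64") for sid in ids}
    )
    frame = frame.fillna(0).astype("int64")
    frame.index.name = "barcode"
    frame = frame.sort_index()
    genotypes = []
    for barcode in frame.index:
        icrs = parse_nicr(barcode, layout)
        try:
            label = "".join(
                codebook.decode(icr.hardcode).category_code for icr in icrs
            )
        except UndecodableError as e:
            raise BarcodeError(f"barcode {barcode} has an undecodable hardcode") from e
        genotypes.append(label)
    frame.insert(0, "genotype", genotypes)
    meta_frame = pd.DataFrame(
        [{"sample_id": m.sample_id, "time_h": m.time_h, "mms_pct": m.mms_pct} for m in meta]
    )
    return frame, meta_frame


def merge_read_pair(r1: str, r2: str, min_overlap: int = 20) -> str | None:
    """Naive exact-overlap merger for synthetic paired reads.

    ``r2`` is reverse-complemented and merged onto ``r1`` at the longest
    exact overlap of at least ``min_overlap`` nt (no mismatches).  Returns
    None when no such overlap exists.  Real data should be merged with a
    dedicated tool; this exists for fixtures only.
    """
    r2rc = reverse_complement(r2.upper())
    r1 = r1.upper()
    max_ov = min(len(r1), len(r2rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        if r1[-ov:] == r2rc[:ov]:
            return r1 + r2rc[ov:]
    return None
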