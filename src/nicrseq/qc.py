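"""Long-read QC of single-cargo barcode libraries.

Associates each 14-nt unit barcode with its cloned cargo, classifies cloning
errors (wrong insert, primer dimer, SNP/indel variants), and emits the
whitelist of verified barcodes used to filter the pooled-screen counts.

A barcode survives into the whitelist when its reads show the expected
cargo either error-free or with edits confined to the primer-derived ends
(where primer synthesis errors land and gene function is untouched).
Barcodes whose reads support both the expected cargo and a wrong insert are
discarded as conflicting.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import edlib
import numpy as np
import pandas as pd

from ._anchors import find_anchor
from .barcode import (
    BarcodeLayout,
    CargoSpec,
    Codebook,
    ICRBarcode,
    UndecodableError,
    reverse_complement,
)

__all__ = [
    "ClassifyParams",
    "ReadAssociation",
    "ExtractionError",
    "extract_icr",
    "associate_reads",
    "classify_cargo",
    "classify_read_table",
    "aggregate_and_whitelist",
    "whitelists_by_set",
    "library_report",
]

# read-level classes grouped by what they say about the insert
_RIGHT_CARGO = {"correct", "mutant_snp_indel"}
_WRONG_INSERT = {"misassociated", "primer_dimer", "unclassifiable"}
_CLASS_ORDER = [
    "correct",
    "mutant_snp_indel",
    "misassociated",
    "primer_dimer",
    "unclassifiable",
]


@dataclass
class ClassifyParams:
    """Thresholds of the cargo classifier.

    ``primer_dimer_max_len``: inserts shorter than this are primer dimers
    (well below the shortest real reference, 1549 nt).
    ``assign_min_identity``: minimum global alignment identity to assign an
    insert to any reference.
    ``primer_region_len``: width of the primer-derived ends within which
    variants are tolerated for whitelisting.
    """

    primer_dimer_max_len: int = 150
    assign_min_identity: float = 0.9
    primer_region_len: int = 30
    anchor_mismatch: int = 2
    min_reads: int = 10


@dataclass
class ReadAssociation:
    read_id: str
    icr: ICRBarcode
    cargo_seq: str


class ExtractionError(ValueError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def extract_icr(
    seq: str,
    layout: BarcodeLayout,
    anchor_mismatch: int = 2,
    read_id: str = "",
) -> ReadAssociation:
    """Pull the 14-nt barcode and its cargo sequence out of one long read.

    Locates the upstream anchor (at most ``anchor_mismatch`` substitutions)
    on either strand, reverse-complementing as needed; the barcode is the 14
    nt that follow, the cargo everything after the downstream anchor, which
    must sit immediately after the barcode.
    """
    up, down = layout.upstream_anchor, layout.downstream_anchor
    for candidate in (seq, reverse_complement(seq)):
        i = find_anchor(candidate, up, anchor_mismatch)
        if i < 0:
            continue
        bc_start = i + len(up)
        bc_end = bc_start + layout.icr_len
        if len(candidate) < bc_end + len(down):
            raise ExtractionError("truncated")
        observed_down = candidate[bc_end : bc_end + len(down)]
        if sum(a != b for a, b in zip(observed_down, down)) > anchor_mismatch:
            raise ExtractionError("no_downstream_anchor")
        return ReadAssociation(
            read_id=read_id,
            icr=ICRBarcode.from_sequence(candidate[bc_start:bc_end]),
            cargo_seq=candidate[bc_end + len(down) :],
        )
    raise ExtractionError("no_upstream_anchor")


def associate_reads(
    reads: Iterable, layout: BarcodeLayout, anchor_mismatch: int = 2
) -> tuple[list[ReadAssociation], Counter]:
    """Extract barcode/cargo pairs from reads; failures are tallied, not fatal.

    ``reads`` may be Biopython SeqRecords or (id, sequence) pairs.
    """
    out: list[ReadAssociation] = []
    drops: Counter = Counter()
    for read in reads:
        if hasattr(read, "seq"):
            rid, seq = read.id, str(read.seq)
        else:
            rid, seq = read
        try:
            out.append(extract_icr(seq.upper(), layout, anchor_mismatch, read_id=rid))
        except ExtractionError as e:
            drops[e.reason] += 1
    return out, drops


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_variants(cigar: str) -> list[tuple[str, int, int]]:
    """Edit events as (op, ref_pos, length) with positions in reference
    coordinates; op in {X, I, D} (I = extra sequence in the read)."""
    events = []
    ref_pos = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in ("=", "M"):
            ref_pos += n
        elif op == "X":
            events.append(("X", ref_pos, n))
            ref_pos += n
        elif op == "I":
            events.append(("I", ref_pos, n))
        elif op == "D":
            events.append(("D", ref_pos, n))
            ref_pos += n
    return events


def classify_cargo(
    cargo_seq: str,
    expected: CargoSpec,
    codebook: Codebook,
    params: ClassifyParams | None = None,
) -> tuple[str, dict]:
    """Classify one read's insert against the reference cargos.

    Returns (class, detail).  Classes: ``primer_dimer`` (insert below the
    length floor), ``misassociated`` (best global alignment is a different
    reference at sufficient identity), ``correct`` (expected reference,
    zero edits), ``mutant_snp_indel`` (expected reference with edits; detail
    lists them and flags ``primer_region_only``), or ``unclassifiable``
    (no reference reaches the identity floor).
    """
    params = params or ClassifyParams()
    if len(cargo_seq) < params.primer_dimer_max_len:
        return "primer_dimer", {"insert_len": len(cargo_seq)}

    best_name, best_identity, best_dist = None, -1.0, None
    for spec in codebook:
        res = edlib.align(cargo_seq, spec.reference_seq, mode="NW", task="distance")
        d = res["editDistance"]
        identity = 1.0 - d / max(len(cargo_seq), len(spec.reference_seq))
        # prefer the expected cargo on ties
        if identity > best_identity or (
            identity == best_identity and spec.name == expected.name
        ):
            best_name, best_identity, best_dist = spec.name, identity, d
    if best_identity < params.assign_min_identity:
        return "unclassifiable", {"best": best_name, "identity": best_identity}
    if best_name != expected.name:
        return "misassociated", {"best": best_name, "identity": best_identity}
    if best_dist == 0:
        return "correct", {}
    res = edlib.align(cargo_seq, expected.reference_seq, mode="NW", task="path")
    variants = _cigar_variants(res["cigar"])
    L = len(expected.reference_seq)
    w = params.primer_region_len
    primer_only = all(
        (pos + (n if op != "I" else 0)) <= w or pos >= L - w
        for op, pos, n in variants
    )
    return "mutant_snp_indel", {
        "variants": variants,
        "primer_region_only": primer_only,
    }


def classify_read_table(
    associations: Iterable[ReadAssociation],
    codebook: Codebook,
    params: ClassifyParams | None = None,
) -> pd.DataFrame:
    """Classify every extracted read.

    Columns: read_id, barcode, expected_cargo (empty if the hardcode is
    undecodable), read_class, primer_region_only, assigned_cargo.
    """
    params = params or ClassifyParams()
    rows = []
    for assoc in associations:
        try:
            expected = codebook.decode(assoc.icr.hardcode)
        except UndecodableError:
            rows.append(
                {
                    "read_id": assoc.read_id,
                    "barcode": assoc.icr.sequence,
                    "expected_cargo": "",
                    "read_class": "undecodable",
                    "primer_region_only": False,
                    "assigned_cargo": "",
                }
            )
            continue
        cls, detail = classify_cargo(assoc.cargo_seq, expected, codebook, params)
        assigned = detail.get("best", expected.name if cls != "primer_dimer" else "")
        if cls in _RIGHT_CARGO:
            assigned = expected.name
        rows.append(
            {
                "read_id": assoc.read_id,
                "barcode": assoc.icr.sequence,
                "expected_cargo": expected.name,
                "read_class": cls,
                "primer_region_only": bool(detail.get("primer_region_only", False)),
                "assigned_cargo": assigned,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "barcode",
            "expected_cargo",
            "read_class",
            "primer_region_only",
            "assigned_cargo",
        ],
    )


def _majority(classes: pd.Series) -> str:
    counts = classes.value_counts()
    top = counts.max()
    tied = [c for c in _CLASS_ORDER if counts.get(c, 0) == top]
    return tied[0]


def aggregate_and_whitelist(
    read_table: pd.DataFrame, min_reads: int = 10
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Aggregate read classifications per barcode and build the whitelist.

    Barcodes with fewer than ``min_reads`` reads are dropped.  A barcode
    whose reads support both the expected cargo (correct or mutant) and a
    wrong insert (misassociated, primer dimer, unclassifiable) is
    ``conflicting`` and excluded; otherwise the majority read class wins.
    Whitelist = correct barcodes plus mutants whose edits all lie in the
    primer regions, keyed by cargo name.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    rows = []
    whitelist: dict[str, set[str]] = {}
    if len(read_table):
        for barcode, grp in read_table.groupby("barcode", sort=True):
            n = len(grp)
            if n < min_reads:
                continue
            classes = grp["read_class"]
            if (classes == "undecodable").all():
                cls, assigned, primer_only = "undecodable", "", False
            else:
                has_right = classes.isin(_RIGHT_CARGO).any()
                has_wrong = classes.isin(_WRONG_INSERT).any()
                if has_right and has_wrong:
                    cls, primer_only = "conflicting", False
                else:
                    cls = _majority(classes)
                    primer_only = False
                    if cls == "mutant_snp_indel":
                        mut = grp.loc[classes == "mutant_snp_indel", "primer_region_only"]
                        primer_only = bool(mut.all())
                if cls == "misassociated":
                    assigned = grp.loc[
                        classes == "misassociated", "assigned_cargo"
                    ].mode()[0]
                elif cls in _RIGHT_CARGO:
                    assigned = grp["expected_cargo"].iloc[0]
                else:
                    assigned = ""
            expected = grp["expected_cargo"].iloc[0]
            rows.append(
                {
                    "barcode": barcode,
                    "expected_cargo": expected,
                    "n_reads": n,
                    "class": cls,
                    "primer_region_only": primer_only,
                    "assigned_cargo": assigned,
                }
            )
            if cls == "correct" or (cls == "mutant_snp_indel" and primer_only):
                whitelist.setdefault(expected, set()).add(barcode)
    table = pd.DataFrame(
        rows,
        columns=[
            "barcode",
            "expected_cargo",
            "n_reads",
            "class",
            "primer_region_only",
            "assigned_cargo",
        ],
    )
    return table, whitelist


def whitelists_by_set(
    whitelist: dict[str, set[str]], codebook: Codebook
) -> dict[int, set[str]]:
    """Union per-cargo whitelists into per-set whitelists (sets 1..3)."""
    out: dict[int, set[str]] = {1: set(), 2: set(), 3: set()}
    for cargo, barcodes in whitelist.items():
        out[codebook.spec(cargo).set_id] |= barcodes
    return out


def library_report(barcode_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-cargo library summary.

    Returns ``summary`` (unique-barcode count and percentage per class, per
    expected cargo) and ``crosstab`` (expected cargo vs assigned cargo
    counts, the hardcode-vs-best-match layout).
    """
    all_classes = _CLASS_ORDER + ["conflicting", "undecodable"]
    if barcode_table.empty:
        summary = pd.DataFrame(
            columns=["n_barcodes"] + [f"pct_{c}" for c in all_classes]
        )
        summary.index.name = "expected_cargo"
        return {"summary": summary, "crosstab": pd.DataFrame()}
    grp = barcode_table.groupby("expected_cargo")
    rows = {}
    for cargo, sub in grp:
        counts = sub["class"].value_counts()
        total = len(sub)
        row = {"n_barcodes": total}
        for c in all_classes:
            row[f"pct_{c}"] = 100.0 * counts.get(c, 0) / total
        rows[cargo] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "expected_cargo"
    assigned = barcode_table[barcode_table["assigned_cargo"] != ""]
    crosstab = pd.crosstab(assigned["expected_cargo"], assigned["assigned_cargo"])
    return {"summary": summary, "crosstab": crosstab}
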