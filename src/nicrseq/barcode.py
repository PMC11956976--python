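"""Data model and codec for nested replicate-tracking DNA barcodes.

The unit barcode (here "ICR barcode") is a 14-nt tag built from a 4-nt
hardcoded sequence identifying a gene cargo plus a 10-nt random sequence
marking the independent clonal replicate.  Three unit barcodes — one per
cargo set — are joined by two fixed 6-nt junction sequences into a 54-nt
nested ("3-NICR") barcode that encodes a full three-gene genotype together
with replicate identity.

Coordinates are 0-based, half-open throughout: in the 54-nt barcode the unit
barcodes occupy [0, 14), [20, 34) and [40, 54), the junctions [14, 20) and
[34, 40).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BarcodeError",
    "LengthError",
    "StructureError",
    "UndecodableError",
    "CargoSpec",
    "Codebook",
    "BarcodeLayout",
    "ICRBarcode",
    "NICRBarcode",
    "hamming",
    "reverse_complement",
    "design_codebook",
    "assemble_nicr",
    "parse_nicr",
    "decode_icr",
    "new_icr",
]

DNA_ALPHABET = "ACGT"
CATEGORY_CODES = {"yeast": "Y", "human": "H", "null": "N"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BarcodeError(ValueError):
    """Base class for barcode model violations."""


class LengthError(BarcodeError):
    """A sequence has the wrong length for its role."""


class StructureError(BarcodeError):
    """A sequence has the right length but violates the fixed structure."""


class UndecodableError(BarcodeError):
    """A hardcode matches no codebook entry within tolerance."""


def _check_dna(seq: str, name: str) -> None:
    if not set(seq) <= set(DNA_ALPHABET):
        raise BarcodeError(f"{name} contains non-ACGT characters: {seq!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise LengthError(f"hamming requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class CargoSpec:
    """A gene cargo: a yeast gene, its human ortholog, or a neutral null
    sequence, identified by a 4-nt hardcoded barcode component.

    ``reference_seq`` is the cargo as amplified, including primer-derived
    ends; it may be empty when only the codebook (not alignment) is needed.
    """

    name: str
    set_id: int
    category: str
    hardcode: str
    reference_seq: str = ""

    def __post_init__(self) -> None:
        if self.set_id not in (1, 2, 3):
            raise BarcodeError(f"set_id must be 1, 2 or 3, got {self.set_id}")
        if self.category not in CATEGORY_CODES:
            raise BarcodeError(
                f"category must be one of {sorted(CATEGORY_CODES)}, got {self.category!r}"
            )
        if len(self.hardcode) != 4:
            raise LengthError(f"hardcode must be 4 nt, got {len(self.hardcode)}")
        _check_dna(self.hardcode, "hardcode")
        if self.reference_seq:
            _check_dna(self.reference_seq, "reference_seq")

    @property
    def category_code(self) -> str:
        """One-letter genotype code: Y (yeast), H (human), N (null)."""
        return CATEGORY_CODES[self.category]


@dataclass(frozen=True)
class BarcodeLayout:
    """Fixed sequence context of the barcodes.

    Defaults: junctions are AgeI (ACCGGT) and NheI (GCTAGC) sites — the
    enzymes that nest the Set 2 and Set 3 fragments — and the flanking
    anchors are the M13 forward/reverse priming sequences as stand-ins for
    the construct's amplification primers.
    """

    hardcode_len: int = 4
    random_len: int = 10
    junction1: str = "ACCGGT"
    junction2: str = "GCTAGC"
    upstream_anchor: str = "TGTAAAACGACGGCCAGT"
    downstream_anchor: str = "CAGGAAACAGCTATGACC"

    def __post_init__(self) -> None:
        for name in ("junction1", "junction2"):
            j = getattr(self, name)
            if len(j) != 6:
                raise LengthError(f"{name} must be 6 nt, got {len(j)}")
            _check_dna(j, name)
        for name in ("upstream_anchor", "downstream_anchor"):
            a = getattr(self, name)
            if len(a) < 18:
                raise LengthError(f"{name} must be >= 18 nt, got {len(a)}")
            _check_dna(a, name)
        if self.hardcode_len != 4 or self.random_len != 10:
            raise BarcodeError("layout requires a 4-nt hardcode and 10-nt random part")

    @property
    def icr_len(self) -> int:
        return self.hardcode_len + self.random_len

    @property
    def nicr_len(self) -> int:
        return 3 * self.icr_len + len(self.junction1) + len(self.junction2)


@dataclass(frozen=True)
class ICRBarcode:
    """14-nt unit barcode: 4-nt cargo hardcode + 10-nt random replicate tag."""

    hardcode: str
    random_part: str

    def __post_init__(self) -> None:
        if len(self.hardcode) != 4:
            raise LengthError(f"hardcode must be 4 nt, got {len(self.hardcode)}")
        if len(self.random_part) != 10:
            raise LengthError(f"random_part must be 10 nt, got {len(self.random_part)}")
        _check_dna(self.hardcode, "hardcode")
        _check_dna(self.random_part, "random_part")

    @property
    def sequence(self) -> str:
        return self.hardcode + self.random_part

    @classmethod
    def from_sequence(cls, seq: str) -> "ICRBarcode":
        if len(seq) != 14:
            raise LengthError(f"unit barcode must be 14 nt, got {len(seq)}")
        return cls(hardcode=seq[:4], random_part=seq[4:])


@dataclass(frozen=True)
class NICRBarcode:
    """Nested barcode: three unit barcodes for Sets 1, 2, 3 in order."""

    icr1: ICRBarcode
    icr2: ICRBarcode
    icr3: ICRBarcode

    @property
    def components(self) -> tuple[ICRBarcode, ICRBarcode, ICRBarcode]:
        return (self.icr1, self.icr2, self.icr3)

    def sequence(self, layout: BarcodeLayout) -> str:
        return assemble_nicr(self.icr1, self.icr2, self.icr3, layout)

    def genotype_label(self, codebook: "Codebook", max_mismatch: int = 0) -> str:
        """Three-letter genotype code in {Y,H,N}^3, Set 1 first."""
        return "".join(
            decode_icr(icr, codebook, max_mismatch).category_code
            for icr in self.components
        )


class Codebook:
    """The set of cargo specs with mutually distant 4-nt hardcodes.

    Decoding is unambiguous at mismatch tolerance
    floor((min_pairwise_hamming - 1) / 2).
    """

    def __init__(self, specs: list[CargoSpec]):
        if not specs:
            raise BarcodeError("codebook requires at least one cargo spec")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise BarcodeError("cargo names must be unique within a codebook")
        keys = [(s.set_id, s.category) for s in specs]
        if len(set(keys)) != len(keys):
            raise BarcodeError("each (set_id, category) pair may appear only once")
        hardcodes = [s.hardcode for s in specs]
        if len(set(hardcodes)) != len(hardcodes):
            raise BarcodeError("hardcodes must be unique")
        self.specs = list(specs)
        self._by_hardcode = {s.hardcode: s for s in specs}
        self._by_name = {s.name: s for s in specs}
        if len(specs) > 1:
            self.min_pairwise_hamming = min(
                hamming(a.hardcode, b.hardcode)
                for a, b in itertools.combinations(specs, 2)
            )
        else:
            self.min_pairwise_hamming = len(specs[0].hardcode)

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @property
    def max_safe_mismatch(self) -> int:
        return (self.min_pairwise_hamming - 1) // 2

    def spec(self, name: str) -> CargoSpec:
        return self._by_name[name]

    def spec_for(self, set_id: int, category: str) -> CargoSpec:
        for s in self.specs:
            if s.set_id == set_id and s.category == category:
                return s
        raise KeyError((set_id, category))

    def by_set(self, set_id: int) -> list[CargoSpec]:
        return [s for s in self.specs if s.set_id == set_id]

    def decode(self, hardcode: str, max_mismatch: int = 0) -> CargoSpec:
        """Map a 4-nt hardcode to its cargo, allowing up to ``max_mismatch``
        substitutions.  Raises :class:`UndecodableError` if no code is within
        tolerance."""
        if len(hardcode) != 4:
            raise LengthError(f"hardcode must be 4 nt, got {len(hardcode)}")
        if max_mismatch > self.max_safe_mismatch:
            raise BarcodeError(
                f"max_mismatch={max_mismatch} is ambiguous for a codebook with "
                f"min pairwise Hamming {self.min_pairwise_hamming}"
            )
        exact = self._by_hardcode.get(hardcode)
        if exact is not None:
            return exact
        if max_mismatch > 0:
            for s in self.specs:
                if hamming(hardcode, s.hardcode) <= max_mismatch:
                    return s
        raise UndecodableError(f"no cargo hardcode within {max_mismatch} of {hardcode!r}")


def design_codebook(
    n_codes: int, code_len: int = 4, min_dist: int = 2, seed: int = 0
) -> list[str]:
    """Choose ``n_codes`` distinct DNA codes of length ``code_len`` with all
    pairwise Hamming distances >= ``min_dist``.

    Greedy selection over a seeded random permutation of the full code space;
    deterministic given ``seed``.  Raises :class:`BarcodeError` when no such
    set can be found (in particular when n_codes > 4**code_len).
    """
    if n_codes < 1:
        raise BarcodeError("n_codes must be >= 1")
    if min_dist > code_len:
        raise BarcodeError("min_dist cannot exceed code_len")
    space = 4 ** code_len
    if n_codes > space:
        raise BarcodeError(f"n_codes={n_codes} exceeds 4^{code_len} = {space}")
    all_codes = [
        "".join(c) for c in itertools.product(DNA_ALPHABET, repeat=code_len)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(space)
    chosen: list[str] = []
    for idx in order:
        cand = all_codes[idx]
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
            if len(chosen) == n_codes:
                return chosen
    raise BarcodeError(
        f"could not find {n_codes} codes of length {code_len} at distance "
        f">= {min_dist} (found {len(chosen)})"
    )


def assemble_nicr(
    icr1: ICRBarcode, icr2: ICRBarcode, icr3: ICRBarcode, layout: BarcodeLayout
) -> str:
    """Serialize three unit barcodes into the 54-nt nested barcode."""
    out = (
        icr1.sequence
        + layout.junction1
        + icr2.sequence
        + layout.junction2
        + icr3.sequence
    )
    assert len(out) == layout.nicr_len
    return out


def parse_nicr(
    seq: str, layout: BarcodeLayout
) -> tuple[ICRBarcode, ICRBarcode, ICRBarcode]:
    """Split a 54-nt nested barcode into its three unit barcodes.

    Junctions must match exactly at their fixed offsets.  Raises
    :class:`LengthError` for a wrong-length input and :class:`StructureError`
    for a junction mismatch, so QC can count the two failure modes apart.
    """
    u = layout.icr_len
    j1, j2 = layout.junction1, layout.junction2
    if len(seq) != layout.nicr_len:
        raise LengthError(
            f"nested barcode must be {layout.nicr_len} nt, got {len(seq)}"
        )
    if seq[u : u + len(j1)] != j1:
        raise StructureError("junction 1 mismatch")
    off2 = 2 * u + len(j1)
    if seq[off2 : off2 + len(j2)] != j2:
        raise StructureError("junction 2 mismatch")
    a = ICRBarcode.from_sequence(seq[:u])
    b = ICRBarcode.from_sequence(seq[u + len(j1) : u + len(j1) + u])
    c = ICRBarcode.from_sequence(seq[off2 + len(j2) :])
    return (a, b, c)


def decode_icr(
    icr: ICRBarcode, codebook: Codebook, max_mismatch: int = 0
) -> CargoSpec:
    """Identify the cargo a unit barcode encodes via its 4-nt hardcode."""
    return codebook.decode(icr.hardcode, max_mismatch=max_mismatch)


def new_icr(cargo: CargoSpec, rng: np.random.Generator) -> ICRBarcode:
    """Draw a fresh unit barcode for ``cargo``: its hardcode plus a uniform
    random 10-mer replicate tag."""
    random_part = "".join(rng.choice(list(DNA_ALPHABET), size=10))
    return ICRBarcode(hardcode=cargo.hardcode, random_part=random_part)
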