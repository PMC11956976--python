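"""Ground-truthed synthetic inputs for every pipeline stage.

Emulates the screen's study design: nine single-cargo barcode libraries
(three sets x {yeast, human, null}) with configurable cloning-error classes,
a combinatorial pool of 27 genotypes x hundreds of 54-nt nested barcodes,
and a pooled growth time course (0/12/24/36/48 h at MMS concentrations
0/0.005/0.01/0.015/0.02 %) read out as multinomial sequencing counts.

Truth tables are plain :class:`pandas.DataFrame` objects, reproducible
bit-for-bit under a fixed seed.  Every latent quantity (error class, genotype,
per-barcode growth rate) is recorded so downstream stages can be checked
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .barcode import (
    BarcodeError,
    BarcodeLayout,
    CargoSpec,
    Codebook,
    ICRBarcode,
    assemble_nicr,
    design_codebook,
    new_icr,
    reverse_complement,
)

__all__ = [
    "CLASS_NAMES",
    "IcrLibraryConfig",
    "GrowthConfig",
    "synthetic_codebook",
    "default_growth_rates",
    "genotype_labels",
    "simulate_icr_library",
    "simulate_nicr_pool",
    "simulate_timecourse",
    "simulate_normalized_values",
    "sample_reads",
]

CLASS_NAMES = ("correct", "primer_dimer", "misassociated", "mutant_snp_indel")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Cargo roster of the emulated screen: three sets, each with a yeast gene,
# its human ortholog, and a neutral null sequence.  Reference lengths echo
# the real amplicons (coding/noncoding sequence plus promoter/terminator
# flanks); the sequences themselves are synthetic random DNA.
_CARGO_ROSTER = [
    ("RAD1", 1, "yeast", 3957),
    ("ERCC4", 1, "human", 3495),
    ("RAD1-neg", 1, "null", 3752),
    ("RAD10", 2, "yeast", 1577),
    ("ERCC1", 2, "human", 1620),
    ("RAD10-neg", 2, "null", 1586),
    ("RAD14", 3, "yeast", 1742),
    ("XPA", 3, "human", 1650),
    ("RAD14-neg", 3, "null", 1549),
]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def synthetic_codebook(
    seed: int = 20240917,
    ref_lengths: Mapping[str, int] | None = None,
    min_dist: int = 2,
) -> Codebook:
    """Build the nine-cargo codebook with synthetic reference sequences.

    Hardcodes are designed at pairwise Hamming distance >= ``min_dist``;
    reference sequences are uniform random DNA (synthetic stand-ins for the
    real amplicons, which are not bundled) at realistic lengths, overridable
    per cargo via ``ref_lengths`` for small test fixtures.
    """
    rng = np.random.default_rng(seed)
    codes = design_codebook(len(_CARGO_ROSTER), code_len=4, min_dist=min_dist, seed=seed)
    specs = []
    for (name, set_id, category, default_len), code in zip(_CARGO_ROSTER, codes):
        n = (ref_lengths or {}).get(name, default_len)
        specs.append(
            CargoSpec(
                name=name,
                set_id=set_id,
                category=category,
                hardcode=code,
                reference_seq=_random_dna(rng, n),
            )
        )
    return Codebook(specs)


def genotype_labels() -> list[str]:
    """All 27 genotype labels in {Y,H,N}^3, Set 1 letter first."""
    return [a + b + c for a in "YHN" for b in "YHN" for c in "YHN"]


def default_growth_rates(
    yyy_benefit: Mapping[float, float] | None = None,
) -> dict[tuple[str, float], float]:
    """Per-hour growth rates for every (genotype, MMS concentration).

    Baseline rates fall with MMS dose; the all-yeast genotype (YYY) carries
    repair function and keeps a higher rate at intermediate doses, with no
    benefit at the highest dose where growth is uniformly poor — the
    qualitative pattern the screen is designed to detect.
    """
    baseline = {0.0: 0.35, 0.005: 0.25, 0.01: 0.15, 0.015: 0.08, 0.02: 0.02}
    benefit = {0.0: 0.0, 0.005: 0.05, 0.01: 0.12, 0.015: 0.04, 0.02: 0.0}
    if yyy_benefit is not None:
        benefit = dict(benefit, **dict(yyy_benefit))
    rates: dict[tuple[str, float], float] = {}
    for g in genotype_labels():
        for c, r in baseline.items():
            rates[(g, c)] = r + (benefit[c] if g == "YYY" else 0.0)
    return rates


@dataclass
class IcrLibraryConfig:
    """Parameters of one simulated single-cargo barcode library.

    ``class_rates`` are the per-barcode probabilities of the four cloning
    outcomes and must sum to 1.  ``reads_per_barcode`` is the mean of a
    Poisson read-count distribution (minimum one read).
    """

    n_barcodes_per_cargo: int = 500
    class_rates: dict = field(
        default_factory=lambda: {
            "correct": 0.90,
            "primer_dimer": 0.08,
            "misassociated": 0.005,
            "mutant_snp_indel": 0.015,
        }
    )
    reads_per_barcode: float = 50.0
    per_base_error: float = 0.0005
    primer_dimer_len_range: tuple[int, int] = (40, 120)
    primer_region_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_barcodes_per_cargo < 1:
            raise BarcodeError("n_barcodes_per_cargo must be >= 1")
        if set(self.class_rates) != set(CLASS_NAMES):
            raise BarcodeError(f"class_rates must have keys {CLASS_NAMES}")
        rates = np.array([self.class_rates[c] for c in CLASS_NAMES], dtype=float)
        if (rates < 0).any() or (rates > 1).any() or abs(rates.sum() - 1.0) > 1e-9:
            raise BarcodeError("class_rates must lie in [0,1] and sum to 1")
        if not 0.0 <= self.per_base_error < 1.0:
            raise BarcodeError("per_base_error must be in [0, 1)")
        lo, hi = self.primer_dimer_len_range
        if not (0 < lo <= hi):
            raise BarcodeError("invalid primer_dimer_len_range")


@dataclass
class GrowthConfig:
    """Parameters of the pooled growth time course.

    ``growth_rate`` maps (genotype label, concentration) to a per-hour rate.
    ``barcode_effect_sd`` is the SD of a per-barcode rate perturbation drawn
    once per lineage (clonal replicates deviate persistently, not per
    observation); ``initial_log_sd`` is the SD of log initial abundance.
    """

    time_points_h: tuple = (0, 12, 24, 36, 48)
    concentrations: tuple = (0.0, 0.005, 0.01, 0.015, 0.02)
    growth_rate: dict = field(default_factory=default_growth_rates)
    barcode_effect_sd: float = 0.005
    initial_log_sd: float = 0.25
    depth_per_sample: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        t = tuple(self.time_points_h)
        if t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise BarcodeError("time points must strictly increase from 0")
        if self.depth_per_sample < 1:
            raise BarcodeError("depth_per_sample must be >= 1")
        if self.barcode_effect_sd < 0 or self.initial_log_sd < 0:
            raise BarcodeError("noise SDs must be non-negative")


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitution errors."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _mutate_reference(
    ref: str, rng: np.random.Generator, primer_region_len: int
) -> tuple[str, bool, str]:
    """Introduce cloning-stage mutations into a reference cargo.

    Either 1-3 substitutions or one 1-10 nt indel, placed with probability
    0.7 inside the primer-derived ends (first/last ``primer_region_len`` nt,
    where the real construct's synthesis errors concentrated) and otherwise
    well inside the interior.  Returns (sequence, primer_region_only, detail).
    """
    L = len(ref)
    in_primer = bool(rng.random() < 0.7)
    mode = "sub" if rng.random() < 0.5 else "indel"

    def pick_pos(span_needed: int) -> int:
        if in_primer:
            if rng.random() < 0.5:
                return int(rng.integers(0, primer_region_len - span_needed + 1))
            return int(rng.integers(L - primer_region_len, L - span_needed + 1))
        return int(rng.integers(45, L - 45 - span_needed + 1))

    seq = list(ref)
    if mode == "sub":
        k = int(rng.integers(1, 4))
        positions = sorted({pick_pos(1) for _ in range(k)})
        for p in positions:
            old = seq[p]
            seq[p] = chr(rng.choice(_BASES[_BASES != ord(old)]))
        detail = f"sub@{','.join(map(str, positions))}"
        return "".join(seq), in_primer, detail
    d = int(rng.integers(1, 11))
    p = pick_pos(d)
    if rng.random() < 0.5:
        del seq[p : p + d]
        detail = f"del{d}@{p}"
    else:
        ins = _random_dna(rng, d)
        seq[p:p] = list(ins)
        detail = f"ins{d}@{p}"
    return "".join(seq), in_primer, detail


def simulate_icr_library(
    cargo: CargoSpec,
    codebook: Codebook,
    cfg: IcrLibraryConfig,
    layout: BarcodeLayout | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate long reads of one single-cargo barcode library.

    Each of ``cfg.n_barcodes_per_cargo`` barcodes gets a cloning-outcome
    class at the configured rates; each read is
    ``upstream_anchor + barcode + downstream_anchor + cargo_variant`` with
    i.i.d. per-base substitution errors, emitted on a random strand.

    Returns the reads and a truth table with one row per barcode
    (columns: barcode, cargo, true_class, primer_region_only, detail,
    n_reads).
    """
    layout = layout or BarcodeLayout()
    rng = np.random.default_rng(cfg.seed)
    others = [s for s in codebook if s.name != cargo.name]
    rates = [cfg.class_rates[c] for c in CLASS_NAMES]

    rows = []
    reads: list[SeqRecord] = []
    seen: set[str] = set()
    for i in range(cfg.n_barcodes_per_cargo):
        icr = new_icr(cargo, rng)
        while icr.sequence in seen:  # keep truth keyed by unique barcodes
            icr = new_icr(cargo, rng)
        seen.add(icr.sequence)
        cls = CLASS_NAMES[rng.choice(len(CLASS_NAMES), p=rates)]
        primer_only = False
        detail = ""
        if cls == "correct":
            insert = cargo.reference_seq
        elif cls == "primer_dimer":
            lo, hi = cfg.primer_dimer_len_range
            n = int(rng.integers(lo, hi + 1))
            insert = _random_dna(rng, n)
            detail = f"len={n}"
        elif cls == "misassociated":
            other = others[rng.choice(len(others))]
            insert = other.reference_seq
            detail = other.name
        else:
            insert, primer_only, detail = _mutate_reference(
                cargo.reference_seq, rng, cfg.primer_region_len
            )
        template = (
            layout.upstream_anchor + icr.sequence + layout.downstream_anchor + insert
        )
        n_reads = max(1, int(rng.poisson(cfg.reads_per_barcode)))
        for r in range(n_reads):
            seq = _sequencing_errors(template, cfg.per_base_error, rng)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            rec = SeqRecord(
                Seq(seq),
                id=f"{cargo.name}_bc{i}_r{r}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = [30] * len(seq)
            reads.append(rec)
        rows.append(
            {
                "barcode": icr.sequence,
                "cargo": cargo.name,
                "true_class": cls,
                "primer_region_only": primer_only,
                "detail": detail,
                "n_reads": n_reads,
            }
        )
    return reads, pd.DataFrame(rows)


def simulate_nicr_pool(
    set_truths: Mapping[int, pd.DataFrame],
    codebook: Codebook,
    n_per_genotype: int = 500,
    layout: BarcodeLayout | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[pd.DataFrame, list[SeqRecord]]:
    """Combine per-set library truths into the 27-genotype nested pool.

    ``set_truths`` maps set_id (1..3) to the concatenated truth tables of
    that set's three libraries.  For each genotype, ``n_per_genotype``
    component triples are drawn (with replacement per component; the
    assembled 54-nt barcodes are kept unique) and the component error
    classes are carried into the pool truth.
    """
    layout = layout or BarcodeLayout()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for s in (1, 2, 3):
        if s not in set_truths or len(set_truths[s]) == 0:
            raise BarcodeError(f"set {s} has no component library")

    by_cargo = {}
    for s, df in set_truths.items():
        for name, sub in df.groupby("cargo"):
            by_cargo[name] = sub.reset_index(drop=True)

    rows = []
    seen: set[str] = set()
    for label in genotype_labels():
        cargos = [
            codebook.spec_for(set_id, {"Y": "yeast", "H": "human", "N": "null"}[ch])
            for set_id, ch in zip((1, 2, 3), label)
        ]
        for c in cargos:
            if c.name not in by_cargo:
                raise BarcodeError(f"component library for {c.name} is empty")
        pools = [by_cargo[c.name] for c in cargos]
        made = 0
        while made < n_per_genotype:
            comps = [p.iloc[int(rng.integers(len(p)))] for p in pools]
            icrs = [ICRBarcode.from_sequence(c["barcode"]) for c in comps]
            seq = assemble_nicr(*icrs, layout)
            if seq in seen:
                continue
            seen.add(seq)
            classes = [c["true_class"] for c in comps]
            flags = [bool(c["primer_region_only"]) for c in comps]
            whitelistable = [
                cl == "correct" or (cl == "mutant_snp_indel" and fl)
                for cl, fl in zip(classes, flags)
            ]
            rows.append(
                {
                    "barcode": seq,
                    "genotype": label,
                    "icr1": icrs[0].sequence,
                    "icr2": icrs[1].sequence,
                    "icr3": icrs[2].sequence,
                    "class1": classes[0],
                    "class2": classes[1],
                    "class3": classes[2],
                    "all_correct": all(c == "correct" for c in classes),
                    "all_whitelistable": all(whitelistable),
                }
            )
            made += 1
    truth = pd.DataFrame(rows)
    records = [
        SeqRecord(Seq(r.barcode), id=f"{r.genotype}_{i}", description="")
        for i, r in enumerate(truth.itertuples())
    ]
    return truth, records


def simulate_timecourse(
    pool_truth: pd.DataFrame, cfg: GrowthConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the pooled competition and its sequencing readout.

    Latent abundance of barcode b with genotype g at concentration c:
    ``N_b(t) = N_b(0) * exp((r_g(c) + eps_b) * t)`` with ``eps_b`` drawn once
    per barcode; observed counts in each (time, concentration) sample are
    multinomial at ``depth_per_sample``.  The t=0 samples are draws from the
    common starting pool.

    Returns (counts, meta): counts is barcodes x samples with a leading
    ``genotype`` column; meta has columns sample_id, time_h, mms_pct.
    """
    rng = np.random.default_rng(cfg.seed)
    barcodes = pool_truth["barcode"].to_numpy()
    genotypes = pool_truth["genotype"].to_numpy()
    n = len(barcodes)
    for g in np.unique(genotypes):
        for c in cfg.concentrations:
            if (g, c) not in cfg.growth_rate:
                raise BarcodeError(f"no growth rate for genotype {g} at {c}% MMS")

    log_n0 = rng.normal(0.0, cfg.initial_log_sd, size=n)
    eps = rng.normal(0.0, cfg.barcode_effect_sd, size=n)
    base_rates = {
        c: np.array([cfg.growth_rate[(g, c)] for g in genotypes])
        for c in cfg.concentrations
    }

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for c in cfg.concentrations:
        r = base_rates[c] + eps
        for t in cfg.time_points_h:
            log_abund = log_n0 + r * t
            p = np.exp(log_abund - log_abund.max())
            p /= p.sum()
            sid = f"t{t}_c{c:g}"
            cols[sid] = rng.multinomial(cfg.depth_per_sample, p)
            meta_rows.append({"sample_id": sid, "time_h": t, "mms_pct": c})

    counts = pd.DataFrame(cols, index=pd.Index(barcodes, name="barcode"))
    counts.insert(0, "genotype", genotypes)
    meta = pd.DataFrame(meta_rows)
    return counts, meta


def simulate_normalized_values(
    n_per_genotype: int = 500,
    shift_sd: float = 3.5,
    shifted_genotype: str = "YYY",
    residual_sd: float = 1.0,
    seed: int = 0,
    time_h: float = 48.0,
    mms_pct: float = 0.01,
) -> pd.DataFrame:
    """Directly simulate a normalized-abundance table at one condition.

    All 27 genotypes share a common mean on the log2 scale except
    ``shifted_genotype``, whose mean is raised by ``shift_sd`` residual
    standard deviations; barcode values are i.i.d. normal on the log2
    scale with SD ``residual_sd``.  Returns the long normalized table
    (ratio-scale ``value`` column, so the standard log2 analysis applies),
    ready for :func:`nicrseq.power.downsample_once` — the regime used to
    benchmark detection power without running the full count pipeline.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genotype_labels():
        mu = shift_sd * residual_sd if g == shifted_genotype else 0.0
        log2_vals = rng.normal(mu, residual_sd, size=n_per_genotype)
        rows.append(
            pd.DataFrame(
                {
                    "barcode": [f"{g}_{i}" for i in range(n_per_genotype)],
                    "genotype": g,
                    "time_h": time_h,
                    "mms_pct": mms_pct,
                    "value": np.exp2(log2_vals),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def sample_reads(
    barcode_counts: pd.Series,
    layout: BarcodeLayout | None = None,
    rng: np.random.Generator | int = 0,
    per_base_error: float = 0.0,
    sample_id: str = "s",
) -> Iterable[SeqRecord]:
    """Emit merged short reads (anchor + 54-nt barcode + anchor) realizing a
    barcode count vector, in shuffled order."""
    layout = layout or BarcodeLayout()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    expanded = np.repeat(barcode_counts.index.to_numpy(), barcode_counts.to_numpy())
    rng.shuffle(expanded)
    for i, bc in enumerate(expanded):
        seq = layout.upstream_anchor + bc + layout.downstream_anchor
        seq = _sequencing_errors(seq, per_base_error, rng)
        rec = SeqRecord(Seq(seq), id=f"{sample_id}_{i}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        yield rec
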