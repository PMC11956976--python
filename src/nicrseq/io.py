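"""File formats and run configuration.

Everything tabular is TSV; sequences are FASTA/FASTQ via Biopython; the run
configuration is YAML with full defaulting so a pipeline run needs no flags.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO

from .barcode import BarcodeError, BarcodeLayout, CargoSpec, Codebook
from .counting import SampleMeta
from .simulate import GrowthConfig, IcrLibraryConfig

__all__ = [
    "read_fastx",
    "write_fastq",
    "write_fasta",
    "write_codebook",
    "read_codebook",
    "layout_to_dict",
    "layout_from_dict",
    "write_count_matrix",
    "read_count_matrix",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_whitelist",
    "read_whitelist",
    "Thresholds",
    "RunConfig",
    "write_manifest",
]


def read_fastx(path: str | Path):
    """Iterate SeqRecords from a FASTA or FASTQ file (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return SeqIO.parse(str(path), fmt)


def write_fastq(records: Iterable, path: str | Path) -> int:
    return SeqIO.write(records, str(path), "fastq")


def write_fasta(records: Iterable, path: str | Path) -> int:
    return SeqIO.write(records, str(path), "fasta")


def write_codebook(
    codebook: Codebook, tsv_path: str | Path, fasta_path: str | Path | None = None
) -> None:
    """Write the codebook TSV (name, set_id, category, hardcode,
    reference_fasta_id) and, optionally, the reference cargo FASTA."""
    rows = [
        {
            "name": s.name,
            "set_id": s.set_id,
            "category": s.category,
            "hardcode": s.hardcode,
            "reference_fasta_id": s.name,
        }
        for s in codebook
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        write_fasta(
            [
                SeqRecord(Seq(s.reference_seq), id=s.name, description="")
                for s in codebook
            ],
            fasta_path,
        )


def read_codebook(
    tsv_path: str | Path, fasta_path: str | Path | None = None
) -> Codebook:
    # keep_default_na: the literal category "null" must not become NaN
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    refs = {}
    if fasta_path is not None:
        refs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    specs = []
    for _, row in df.iterrows():
        specs.append(
            CargoSpec(
                name=row["name"],
                set_id=int(row["set_id"]),
                category=row["category"],
                hardcode=row["hardcode"],
                reference_seq=refs.get(row.get("reference_fasta_id", row["name"]), ""),
            )
        )
    return Codebook(specs)


def layout_to_dict(layout: BarcodeLayout) -> dict:
    return dataclasses.asdict(layout)


def layout_from_dict(d: dict | None) -> BarcodeLayout:
    return BarcodeLayout(**(d or {}))


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=True)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    sample_cols = [c for c in df.columns if c != "genotype"]
    df[sample_cols] = df[sample_cols].astype("int64")
    return df


def write_sample_sheet(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_h", "mms_pct"}
    if not required <= set(df.columns):
        raise BarcodeError(f"sample sheet must have columns {sorted(required)}")
    return df


def meta_records(meta: pd.DataFrame) -> list[SampleMeta]:
    return [
        SampleMeta(row["sample_id"], float(row["time_h"]), float(row["mms_pct"]))
        for _, row in meta.iterrows()
    ]


def write_whitelist(whitelist: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"cargo": cargo, "barcode": bc}
        for cargo in sorted(whitelist)
        for bc in sorted(whitelist[cargo])
    ]
    pd.DataFrame(rows, columns=["cargo", "barcode"]).to_csv(path, sep="\t", index=False)


def read_whitelist(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["cargo"], set()).add(row["barcode"])
    return out


@dataclass
class Thresholds:
    """Analysis thresholds with their documented defaults."""

    min_reads: int = 10
    alpha: float = 0.05
    es_min: float = 0.2
    anchor_mismatch: int = 2
    primer_dimer_max_len: int = 150
    primer_region_len: int = 30

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise BarcodeError("min_reads must be >= 1")
        if not 0 < self.alpha < 1:
            raise BarcodeError("alpha must be in (0, 1)")
        if self.es_min < 0 or self.anchor_mismatch < 0:
            raise BarcodeError("es_min and anchor_mismatch must be non-negative")
        if self.primer_dimer_max_len < 1 or self.primer_region_len < 0:
            raise BarcodeError("invalid primer length thresholds")


@dataclass
class RunConfig:
    """Pipeline configuration; every field has a default, so an empty YAML
    file (or none) is a valid config.  Round-trips through to_dict/from_dict
    unchanged."""

    seed: int = 0
    layout: BarcodeLayout = field(default_factory=BarcodeLayout)
    library: IcrLibraryConfig = field(default_factory=IcrLibraryConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_per_genotype: int = 500
    power_n_values: tuple = (4, 8, 16, 32, 64, 100, 150)
    power_replicates: int = 500
    ref_lengths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["growth"]["growth_rate"] = _rates_to_nested(self.growth.growth_rate)
        return d

    @classmethod
    def from_dict(cls, d: dict | None) -> "RunConfig":
        d = dict(d or {})
        try:
            layout = layout_from_dict(d.pop("layout", None))
            lib = IcrLibraryConfig(**_tupled(d.pop("library", {}) or {}, "primer_dimer_len_range"))
            growth_d = dict(d.pop("growth", {}) or {})
            if "growth_rate" in growth_d:
                growth_d["growth_rate"] = _rates_from_nested(growth_d["growth_rate"])
            for key in ("time_points_h", "concentrations"):
                if key in growth_d:
                    growth_d[key] = tuple(growth_d[key])
            growth = GrowthConfig(**growth_d)
            thresholds = Thresholds(**(d.pop("thresholds", {}) or {}))
            if "power_n_values" in d:
                d["power_n_values"] = tuple(d["power_n_values"])
            return cls(
                layout=layout, library=lib, growth=growth, thresholds=thresholds, **d
            )
        except TypeError as e:
            raise BarcodeError(f"invalid config field: {e}") from e

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "RunConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    return d


def _rates_to_nested(rates: dict) -> dict:
    nested: dict = {}
    for (g, c), r in rates.items():
        nested.setdefault(g, {})[float(c)] = float(r)
    return nested


def _rates_from_nested(nested: dict) -> dict:
    return {
        (g, float(c)): float(r)
        for g, by_c in nested.items()
        for c, r in by_c.items()
    }


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    config: RunConfig,
    inputs: Iterable[str | Path] = (),
) -> Path:
    """Record what produced a run directory: config hash, seed, package
    version, and input checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()},
    }
    path = out_dir / f"manifest_{subcommand}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
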