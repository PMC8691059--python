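"""Readers and writers for the pipeline's external formats.

Event tables and line metadata are plain TSV; gene annotations are GFF3 or
BED; sequences are FASTA.  Internally everything is 0-based half-open;
GFF3's 1-based inclusive intervals are converted on read.  Every file the
pipeline writes begins with a provenance header recording the tool version,
a hash of the configuration and the RNG seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .events import Channel, EventTableRow, SVType, ValidationError

EVENT_COLUMNS = [
    "line_id",
    "contig",
    "start",
    "end",
    "sv_type",
    "length",
    "channel",
    "copy_number_change",
]

METADATA_COLUMNS = [
    "line_id",
    "genotype",
    "population",
    "generations",
    "callable_sites",
    "gene_count",
]


class FormatError(ValueError):
    """A file does not conform to its expected format."""


@dataclass
class LineMetadataRow:
    """Per-MA-line metadata: g generations, n callable sites, m genes."""

    line_id: str
    genotype: str
    population: str
    generations: int
    callable_sites: int
    gene_count: int

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValidationError(f"generations must be >= 1, got {self.generations}")
        if self.callable_sites <= 0:
            raise ValidationError(
                f"callable_sites must be > 0, got {self.callable_sites}"
            )
        if self.gene_count < 0:
            raise ValidationError(f"gene_count must be >= 0, got {self.gene_count}")


@dataclass
class Config:
    """Pipeline thresholds and replicate counts.

    All randomized stages take their seed from here unless overridden on
    the command line; the seed is recorded in every output header.
    """

    short_max: int = 49
    long_min: int = 50
    cnv_min: int = 2000
    complete_gene_fraction: float = 0.95
    bootstrap_replicates: int = 10_000
    resampling_replicates: int = 1_000
    breakpoint_tolerance: int = 10
    reciprocal_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("short_max", "long_min", "cnv_min", "bootstrap_replicates",
                     "resampling_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.breakpoint_tolerance < 0:
            raise ValueError("breakpoint_tolerance must be >= 0")
        if not 0 < self.complete_gene_fraction <= 1:
            raise ValueError("complete_gene_fraction must be in (0, 1]")
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must be in (0, 1]")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> Config:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return Config(**data)


def provenance_header(config: Config | None = None, seed: int | None = None) -> str:
    """Comment line recording version, config hash and seed for output files."""
    config = config or Config()
    seed = config.seed if seed is None else seed
    return f"# svcmr v{__version__} config={config.hash()} seed={seed}"


# ---------------------------------------------------------------------------
# event and metadata tables


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_event_table(path: str | Path) -> list[EventTableRow]:
    """Read a candidate-event TSV into validated rows, preserving order."""
    df = _read_tsv(path, [c for c in EVENT_COLUMNS if c != "copy_number_change"])
    rows = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        cnc = getattr(rec, "copy_number_change", None)
        if cnc is not None and (pd.isna(cnc) or cnc == "" or cnc == "."):
            cnc = None
        try:
            rows.append(
                EventTableRow(
                    line_id=rec.line_id,
                    contig=rec.contig,
                    start=int(rec.start),
                    end=int(rec.end),
                    sv_type=SVType(rec.sv_type),
                    length=int(rec.length),
                    channel=Channel(rec.channel),
                    copy_number_change=None if cnc is None else float(cnc),
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path}: row {i}: {err}") from err
    return rows


def write_event_table(
    rows: Iterable[EventTableRow],
    path: str | Path,
    config: Config | None = None,
    seed: int | None = None,
) -> None:
    records = []
    for r in rows:
        rec = {c: getattr(r, c) for c in EVENT_COLUMNS}
        rec["sv_type"] = r.sv_type.value
        rec["channel"] = r.channel.value
        if rec["copy_number_change"] is None:
            rec["copy_number_change"] = "."
        records.append(rec)
    df = pd.DataFrame(records, columns=EVENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[LineMetadataRow]:
    df = _read_tsv(path, METADATA_COLUMNS)
    rows = [
        LineMetadataRow(
            line_id=rec.line_id,
            genotype=rec.genotype,
            population=rec.population,
            generations=int(rec.generations),
            callable_sites=int(rec.callable_sites),
            gene_count=int(rec.gene_count),
        )
        for rec in df.itertuples(index=False)
    ]
    ids = [r.line_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate line_id values")
    return rows


def write_metadata(
    rows: Iterable[LineMetadataRow],
    path: str | Path,
    config: Config | None = None,
    seed: int | None = None,
) -> None:
    df = pd.DataFrame([asdict(r) for r in rows], columns=METADATA_COLUMNS)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# call tables and contig lengths

CALL_COLUMNS = ["contig", "start", "end", "sv_type", "length"]


def read_call_table(path: str | Path):
    """Read an external caller's normalized TSV into CallRecord rows."""
    from .evaluate import CallRecord

    df = _read_tsv(path, CALL_COLUMNS)
    return [
        CallRecord(
            contig=rec.contig,
            start=int(rec.start),
            end=int(rec.end),
            sv_type=rec.sv_type,
            length=int(rec.length),
        )
        for rec in df.itertuples(index=False)
    ]


def write_call_table(calls, path: str | Path, config: Config | None = None,
                     seed: int | None = None) -> None:
    df = pd.DataFrame([asdict(c) for c in calls], columns=CALL_COLUMNS)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Contig lengths from a two-column TSV or a samtools .fai index."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected at least 2 tab-separated columns")
            lengths[parts[0]] = int(parts[1])
    return lengths


# ---------------------------------------------------------------------------
# gene annotations


def read_genes(path: str | Path):
    """Read gene annotations from GFF3 or BED, auto-detected by extension.

    GFF3 intervals (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is already half-open.  Genes are
    returned sorted by (contig, start).
    """
    from .overlap import GeneAnnotation

    path = Path(path)
    suffix = path.suffix.lower()
    genes: list[GeneAnnotation] = []
    if suffix in (".gff", ".gff3"):
        with open(path) as fh:
            n = 0
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
                contig, _, feature, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
                if feature != "gene":
                    continue
                start_i, end_i = int(start), int(end)
                if start_i > end_i:
                    raise FormatError(
                        f"{path}: line {lineno}: start {start_i} > end {end_i}"
                    )
                gene_id = _gff3_attribute(parts[8], "ID") or f"gene{n}"
                n += 1
                genes.append(GeneAnnotation(gene_id, contig, start_i - 1, end_i))
    elif suffix == ".bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
                gene_id = parts[3] if len(parts) > 3 else f"gene{lineno}"
                if start >= end:
                    raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
                genes.append(GeneAnnotation(gene_id, contig, start, end))
    else:
        raise FormatError(f"{path}: unrecognized annotation extension {suffix!r}")
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def _gff3_attribute(column: str, key: str) -> Optional[str]:
    for item in column.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def write_genes_gff3(genes, path: str | Path, config: Config | None = None,
                     seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(provenance_header(config, seed) + "\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tsvcmr\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA

FASTA_WRAP = 60


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered contig -> sequence map."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate contig name {record.id!r}")
        sequences[record.id] = str(record.seq)
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


__all__ = [
    "Config",
    "FormatError",
    "LineMetadataRow",
    "load_config",
    "provenance_header",
    "read_event_table",
    "write_event_table",
    "read_metadata",
    "write_metadata",
    "read_genes",
    "write_genes_gff3",
    "read_fasta",
    "write_fasta",
]
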