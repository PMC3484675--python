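"""Readers and writers for the plain-text formats the pipeline uses:
FASTA (60-column wrapped), FASTQ (qualities ignored), TSV tables, BED-style
interval sidecars, and the YAML pipeline configuration."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_coords import GeneModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_tsv",
    "write_tsv",
    "read_bed",
    "read_gene_model",
    "read_config",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Name -> uppercase sequence, preserving file order."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> dict[str, str]:
    """Reads from FASTQ; qualities are ignored."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader: (chrom, start, end, name), 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            name = fields[3] if len(fields) > 3 else ""
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out


def read_gene_model(fasta_path: str | Path, model_path: str | Path) -> GeneModel:
    """A gene model from a FASTA record plus the sidecar annotation TSV
    (columns: name, exons as ``s-e;s-e``, cds_start, cds_end)."""
    seqs = read_fasta(fasta_path)
    row = read_tsv(model_path).iloc[0]
    name = str(row["name"])
    if name not in seqs:
        raise ValueError(f"record {name!r} not found in {fasta_path}")
    exons = [
        (int(part.split("-")[0]), int(part.split("-")[1]))
        for part in str(row["exons"]).split(";")
    ]
    return GeneModel(name, seqs[name], exons, int(row["cds_start"]), int(row["cds_end"]))


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
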