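"""Readers and writers for the formats the pipeline touches.

FASTA parsing/writing goes through Biopython's SeqIO; this module adds the
pipeline's record types, alphabet normalization, id-uniqueness checks and
the two packaged reference tables (the 58-entry mature-miRNA catalogue and
the 11-row per-miRNA target-count table).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq import FormatError, normalize

__all__ = [
    "ESTRecord",
    "MatureMiRNA",
    "UTRRecord",
    "TargetCountRow",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_utrs",
    "load_catalogue",
    "load_target_counts",
    "table1_path",
    "table2_path",
]

#: loose mature-miRNA name pattern: <species>-(miR|let)-<core>[letters][-copy]
MIRNA_NAME_RE = re.compile(
    r"^[A-Za-z][A-Za-z0-9]*-(?:miR|let)-?\d+[a-z]*(?:-\d+)?$"
)


@dataclass(frozen=True)
class ESTRecord:
    """An un-annotated expressed sequence tag (DNA, may contain N)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence (RNA)."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR in sense (mRNA) orientation, RNA alphabet."""

    gene_id: str
    sequence: str


@dataclass(frozen=True)
class TargetCountRow:
    """Per-miRNA predicted-target bookkeeping (total and Class II counts)."""

    mirna_name: str
    n_targets: int
    n_class2: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 0 or self.n_class2 < 0:
            raise FormatError(
                f"negative target count for {self.mirna_name}"
            )
        if self.n_class2 > self.n_targets:
            raise FormatError(
                f"{self.mirna_name}: Class II count {self.n_class2} exceeds "
                f"total {self.n_targets}"
            )


def read_fasta(path, alphabet: str = "DNA"):
    """Read a multi-record FASTA file.

    Returns :class:`ESTRecord` objects for ``alphabet="DNA"`` (U converted
    to T) and :class:`MatureMiRNA` objects for ``alphabet="RNA"`` (T to U).
    Sequences are upper-cased; duplicate ids and empty sequences raise
    :class:`FormatError` naming the offending record.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        s = normalize(str(rec.seq), alphabet, context=rec.id)
        if not s:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        if alphabet == "DNA":
            records.append(ESTRecord(rec.id, s))
        else:
            records.append(MatureMiRNA(rec.id, s))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write records (anything with an id/name and a sequence) as FASTA."""
    out = []
    for r in records:
        rid = getattr(r, "id", None) or getattr(r, "name", None) \
            or getattr(r, "gene_id", None)
        out.append(SeqRecord(Seq(r.sequence), id=str(rid), description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(out)


def read_utrs(path) -> list[UTRRecord]:
    """Read 3'UTR sequences (FASTA, normalized to RNA)."""
    return [UTRRecord(m.name, m.sequence) for m in read_fasta(path, "RNA")]


def table1_path() -> Path:
    """Path to the packaged 58-entry mature-miRNA catalogue fixture."""
    return Path(resources.files("mirest") / "data" / "table1_catalogue.tsv")


def table2_path() -> Path:
    """Path to the packaged 11-row per-miRNA target-count fixture."""
    return Path(resources.files("mirest") / "data" / "table2_targets.tsv")


def load_catalogue(path=None) -> list[MatureMiRNA]:
    """Load a mature-miRNA catalogue TSV (columns ``name``, ``sequence``).

    With no argument, loads the packaged 58-entry *Spodoptera litura*
    catalogue.  Sequences are validated as RNA with lengths in [15, 30] and
    names against the standard miRNA nomenclature pattern.  Duplicate names
    are permitted (the packaged catalogue itself prints one name twice).
    """
    if path is None:
        path = table1_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "sequence"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'name' and 'sequence'")
    out = []
    for row in df.itertuples(index=False):
        seq = normalize(str(row.sequence), "RNA", context=str(row.name))
        if not 15 <= len(seq) <= 30:
            raise FormatError(
                f"{row.name}: mature length {len(seq)} outside [15, 30]"
            )
        if not MIRNA_NAME_RE.match(str(row.name)):
            raise FormatError(f"unparseable miRNA name {row.name!r}")
        out.append(MatureMiRNA(str(row.name), seq))
    return out


def load_target_counts(path=None) -> list[TargetCountRow]:
    """Load a per-miRNA target-count TSV (``mirna``, ``n_targets``,
    ``n_class2``); ``n_class2`` defaults to 0 when the column is absent."""
    if path is None:
        path = table2_path()
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    if "n_class2" not in df.columns:
        df["n_class2"] = 0
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TargetCountRow(str(row.mirna), int(row.n_targets),
                           int(row.n_class2))
        )
    return out
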