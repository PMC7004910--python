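"""Assembly-scale sequence I/O, N-gap cataloguing and summary statistics.

Sequences are plain upper-case strings over the five-letter alphabet
``{A, C, G, T, N}``.  All coordinates are 0-based half-open internally;
GFF3 is written 1-based inclusive and BED 0-based half-open, following the
conventions of those formats.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


class FastaFormatError(ValueError):
    """Raised for files that are not syntactically valid FASTA."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        m = _NON_ACGTN.search(self.seq)
        if m:
            raise ValueError(
                f"record {self.id!r} contains invalid symbol {m.group()!r} "
                f"at position {m.start()}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GapRecord:
    """A maximal run of N inside one sequence (0-based half-open)."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gap interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GappedAssembly:
    """A pseudomolecule together with its catalogued N-gap intervals."""

    record: SequenceRecord
    gaps: tuple[GapRecord, ...]

    @classmethod
    def from_record(cls, record: SequenceRecord, min_len: int = 1) -> "GappedAssembly":
        return cls(record, tuple(scan_gaps(record, min_len)))


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Upper-case ``raw`` and map non-ACGTN IUPAC codes to N.

    Substitution counts are logged; real assemblies routinely contain
    ambiguity codes and rejecting them outright would be unhelpful.
    """
    up = raw.upper().replace("U", "T")
    clean, n_subst = _NON_ACGTN.subn("N", up)
    if n_subst:
        log.info("record %s: %d non-ACGTN symbols replaced by N", record_id, n_subst)
    return clean


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized :class:`SequenceRecord` s.

    Order is preserved; lowercase is upper-cased; IUPAC ambiguity codes
    become N with a logged count.  Empty files or files whose first
    non-blank character is not ``>`` raise :class:`FastaFormatError`.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line.lstrip()
                break
    if not text_head:
        raise FastaFormatError(f"{path}: empty FASTA file")
    if not text_head.startswith(">"):
        raise FastaFormatError(f"{path}: does not start with a FASTA header")

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise FastaFormatError(f"{path}: no records parsed")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


def scan_gaps(record: SequenceRecord, min_len: int = 1) -> list[GapRecord]:
    """Catalogue maximal N-runs of length >= ``min_len``.

    Terminal runs are genuine gaps and are reported; downstream closure
    refuses them because they lack one flank.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [
        GapRecord(record.id, m.start(), m.end())
        for m in re.finditer("N{%d,}" % min_len, record.seq)
    ]


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that pieces of length >= L hold at least half the total."""
    if len(lengths) == 0:
        raise ValueError("n50 of empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")  # pragma: no cover


def write_gap_bed(gaps: Iterable[GapRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(f"{g.seq_id}\t{g.start}\t{g.end}\n")


def read_gap_bed(path: str | Path) -> list[GapRecord]:
    gaps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            gaps.append(GapRecord(fields[0], int(fields[1]), int(fields[2])))
    return gaps


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Pass-through GFF3 reader: 9 standard columns, comments skipped.

    ``start``/``end`` are returned converted to 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS,
        dtype={"seqid": str, "attributes": str},
    )
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (0-based half-open coords) as GFF3."""
    out = features.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        out.to_csv(fh, sep="\t", header=False, index=False, columns=GFF3_COLUMNS)
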