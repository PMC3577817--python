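"""Sequence and annotation I/O with exact coordinate bookkeeping.

All coordinates are 0-based, half-open internally.  BED output stays
0-based; human-readable reports are 1-based.  Sequences are normalized to
lowercase over the alphabet {a, c, g, t, n}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_ALPHABET = frozenset("acgtn")
#: IUPAC ambiguity codes other than N; rejected or mapped to n per config.
_AMBIGUITY = frozenset("rykmswbdhv")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {a,c,g,t,n}."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA string with its offset within the source sequence."""

    id: str
    seq: str
    origin_start: int = 0

    def __post_init__(self) -> None:
        if self.origin_start < 0:
            raise ValueError("origin_start must be >= 0")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TssAnnotation:
    """An annotated transcription start site (0-based position)."""

    seq_id: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def normalize_seq(raw: str, record_id: str = "?", ambiguous: str = "strict") -> str:
    """Lowercase *raw* and resolve IUPAC ambiguity codes.

    ambiguous='strict' rejects any code other than n; 'mask' maps codes
    (and anything unrecognized) to n.
    """
    seq = raw.lower()
    if ambiguous == "mask":
        return re.sub(r"[^acgt]", "n", seq)
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise AlphabetError(
            f"record {record_id!r}: ambiguous/invalid characters {sorted(bad)} "
            "(use ambiguous='mask' to map them to n)"
        )
    return seq


def read_fasta(path: str | Path, ambiguous: str = "strict") -> List[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects."""
    path = Path(path)
    _precheck_fasta(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, normalize_seq(str(rec.seq), rec.id, ambiguous))
        )
    return records


def _precheck_fasta(path: Path) -> None:
    # Biopython silently returns nothing for headerless text; fail loudly
    # and name the first offending line instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header line starting "
                    f"with '>', got {line.strip()[:30]!r}"
                )
            return  # header found; Biopython handles the rest


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def windows(
    record: SequenceRecord, width: int, step: int, allow_short: bool = False
) -> List[SequenceRecord]:
    """Cut sliding windows starting at 0, step, 2*step, ...

    Each window's ``origin_start`` records its offset within *record*'s
    source (the record's own origin plus the window offset).  Windows
    shorter than *width* at the tail are dropped unless *allow_short*.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    out = []
    pos = 0
    n = len(record.seq)
    while pos < n:
        chunk = record.seq[pos : pos + width]
        if len(chunk) == width or (allow_short and chunk):
            out.append(
                SequenceRecord(
                    f"{record.id}:{pos}", chunk, record.origin_start + pos
                )
            )
        pos += step
    return out


def max_n_run(seq: str) -> int:
    """Length of the longest run of 'n' in *seq* (0 if none)."""
    return max((len(m.group()) for m in re.finditer(r"n+", seq)), default=0)


def read_tss_annotations(path: str | Path) -> List[TssAnnotation]:
    """Read TSS annotations from 3-column TSV: seq_id, position, strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            strand = parts[2] if len(parts) > 2 else "+"
            out.append(TssAnnotation(parts[0], int(parts[1]), strand))
    return out


def write_tss_annotations(annos: Iterable[TssAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annos:
            fh.write(f"{a.seq_id}\t{a.position}\t{a.strand}\n")


def write_bed6(
    rows: Sequence[tuple], path: str | Path
) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement()).lower()
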