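"""FASTA/FASTQ reading and writing with the ``;size=N`` header dialect.

gzip is autodetected from the ``.gz`` extension. Qualities are Phred+33.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
_SIZE_RE = re.compile(r";size=(\d+)")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ records, carrying the record index."""


@dataclass
class SeqRecord:
    id: str
    seq: str
    qual: str | None = None  # Phred+33 string for FASTQ records
    size: int | None = None  # parsed from the ';size=N' dialect

    def __post_init__(self) -> None:
        if self.size is None:
            m = _SIZE_RE.search(self.id)
            if m:
                self.size = int(m.group(1))

    @property
    def name(self) -> str:
        """Record id with any ;size= annotation stripped."""
        return _SIZE_RE.sub("", self.id).split()[0]


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    with _open(path) as fh:
        return [SeqRecord(id=title, seq=seq.upper()) for title, seq in SimpleFastaParser(fh)]


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            header = rec.id
            if rec.size is not None and ";size=" not in header:
                header = f"{header};size={rec.size}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    with _open(path) as fh:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                if len(seq) != len(qual):
                    raise ParseError(f"record {i} ({title}): sequence/quality length mismatch")
                yield SeqRecord(id=title, seq=seq.upper(), qual=qual)
        except ValueError as exc:  # Biopython's structural errors
            if isinstance(exc, ParseError):
                raise
            raise ParseError(str(exc)) from exc


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for i, rec in enumerate(records):
            if rec.qual is None or len(rec.qual) != len(rec.seq):
                raise ParseError(f"record {i} ({rec.id}): missing or mismatched qualities")
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def phred_to_quals(qual: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in qual]


def quals_to_phred(quals: Iterable[int]) -> str:
    out = []
    for q in quals:
        q = max(0, min(93, int(q)))
        out.append(chr(q + PHRED_OFFSET))
    return "".join(out)
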