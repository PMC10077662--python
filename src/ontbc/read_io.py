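"""FASTQ input/output and elementary sequence operations.

Reads are held as :class:`SequencedRead` records: an identifier, the base
string over ``{A, C, G, T, N}``, and one integer Phred score per base.
Qualities use the Sanger convention (ASCII offset 33), which is what modern
nanopore basecallers emit; no offset auto-detection is attempted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequencedRead:
    """A single sequenced read with per-base Phred qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.quals and not all(0 <= q <= 93 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred score outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Stream records from a plain or gzipped FASTQ file.

    Qualities are decoded at ASCII offset 33 and bases are uppercased.
    The read id is the header token up to the first whitespace.  Malformed
    records (base/quality length mismatch, missing ``+`` separator, truncated
    record) raise ``ValueError`` naming the 1-based record number.
    """
    with _open_maybe_gzip(path) as handle:
        record_no = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            record_no += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {record_no}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {record_no}: sequence and quality "
                    f"lengths differ ({len(seq)} vs {len(qual)})"
                )
            yield SequencedRead(
                read_id=title.split()[0] if title else "",
                bases=seq.upper(),
                quals=tuple(ord(c) - PHRED_OFFSET for c in qual),
            )


def write_fastq(records: Iterable[SequencedRead], path: str | Path) -> int:
    """Write records to FASTQ (gzipped when the path ends in ``.gz``).

    Returns the number of records written.
    """
    n = 0
    with _open_maybe_gzip(path, "wt") as out:
        for rec in records:
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quals)
            out.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    return n


def reverse_complement(bases: str) -> str:
    """Reverse complement of a DNA string; ``N`` maps to ``N``."""
    if not set(bases) <= _VALID_BASES:
        bad = sorted(set(bases) - _VALID_BASES)
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return bases.translate(_COMPLEMENT)[::-1]


def reverse_complement_read(read: SequencedRead) -> SequencedRead:
    """Reverse-complement a read, reversing qualities to stay base-aligned."""
    return SequencedRead(
        read_id=read.read_id,
        bases=reverse_complement(read.bases),
        quals=read.quals[::-1],
    )


def read_barcode_list(path: str | Path) -> set[str]:
    """Read a one-barcode-per-line text file into a set.

    Tolerates Cell Ranger style ``-1`` suffixes and blank lines.
    """
    out: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for line in handle:
            token = line.strip().split("-")[0]
            if token:
                out.add(token.upper())
    return out
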