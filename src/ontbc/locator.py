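"""Locate the 10x adaptor and extract the putative cell barcode from a read.

In a 10x Chromium 3' library read the cell barcode sits immediately
downstream of the read-1 adaptor, followed by the UMI and the polyT tract.
The locator searches the first ``search_window`` nt of each strand for the
last 10 nt of the adaptor (``CTTCCGATCT``) allowing up to ``max_ed``
mismatches/insertions/deletions, then demands a short run of T's 20-50 nt
downstream (the polyT is often truncated by homopolymer basecalling, hence
the lenient 4-T requirement).  A read is used only if *exactly one* valid
(polyT-confirmed) adaptor is found across both strands; the 16 bases after
the adaptor are the putative barcode and the next ``umi_len`` bases the UMI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .read_io import SequencedRead, reverse_complement

DEFAULT_ADAPTOR_TAIL = "CTTCCGATCT"

FORWARD = "forward"
REVERSE = "reverse"

# rejection reasons tallied by the pipeline
REASON_OK = "ok"
REASON_NO_ADAPTOR = "no_adaptor"
REASON_NO_POLYT = "no_polyT"
REASON_MULTIPLE = "multiple_adaptors"
REASON_TOO_SHORT = "too_short"
REASONS = (REASON_OK, REASON_NO_ADAPTOR, REASON_NO_POLYT, REASON_MULTIPLE, REASON_TOO_SHORT)

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_N_CODE = 4


def _encode(bases: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AdaptorHit:
    """One candidate adaptor location on a single strand.

    ``end_pos`` is the 0-based index of the first base *after* the adaptor
    alignment, in the searched strand's coordinates.
    """

    strand: str
    end_pos: int
    edit_dist: int


@dataclass(frozen=True)
class PutativeBarcode:
    """The 16-mer downstream of a validated adaptor, with its qualities."""

    read_id: str
    barcode: str
    barcode_quals: tuple[int, ...]
    umi: str
    strand: str

    @property
    def min_q(self) -> int:
        return min(self.barcode_quals)


@dataclass(frozen=True)
class LocatorConfig:
    adaptor_tail: str = DEFAULT_ADAPTOR_TAIL
    max_ed: int = 2
    search_window: int = 200
    polyt_start_offset: int = 20
    polyt_end_offset: int = 50
    t_run: int = 4
    barcode_len: int = 16
    umi_len: int = 12


def _semiglobal_end_costs(target: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Minimal edit cost of aligning the full pattern ending at each position.

    Returns ``cost[j]`` for ``j = 0..len(target)``: the cheapest semi-global
    alignment of the whole pattern against a substring of ``target`` that
    ends at position ``j`` (free start, unit costs).  ``N`` in the target
    never matches.  Vectorised over target positions; the in-row horizontal
    propagation uses the prefix-min-with-slope identity
    ``D[i][j] = j + min_{k<=j} (tmp[k] - k)``.
    """
    n = target.size
    idx = np.arange(n + 1)
    prev = np.zeros(n + 1)
    is_n = target == _N_CODE
    for i, p in enumerate(pattern):
        sub = ((target != p) | is_n | (p == _N_CODE)).astype(np.float64)
        vals = np.minimum(prev[:-1] + sub, prev[1:] + 1.0)
        row = np.concatenate(([i + 1.0], vals))
        prev = np.minimum.accumulate(row - idx) + idx
    return prev


def find_adaptor_hits(
    bases: str,
    adaptor_tail: str = DEFAULT_ADAPTOR_TAIL,
    max_ed: int = 2,
    search_window: int = 200,
    strand: str = FORWARD,
) -> list[AdaptorHit]:
    """All distinct adaptor placements in the window of one strand.

    Every end position with total edit cost <= ``max_ed`` is a candidate;
    candidates whose end positions lie within ``len(adaptor_tail)`` of each
    other are collapsed to the single cheapest one (ties -> smallest
    end_pos), so one noisy adaptor copy never counts as several.
    """
    if not adaptor_tail:
        raise ValueError("adaptor_tail must be non-empty")
    window = bases[:search_window]
    if not window:
        return []
    costs = _semiglobal_end_costs(_encode(window), _encode(adaptor_tail))
    (ends,) = np.nonzero(costs <= max_ed)
    ends = ends[ends > 0]  # a full pattern cannot end before any target base
    if ends.size == 0:
        return []
    hits: list[AdaptorHit] = []
    group: list[int] = []

    def _flush(group: list[int]) -> None:
        best = min(group, key=lambda j: (costs[j], j))
        hits.append(AdaptorHit(strand=strand, end_pos=int(best), edit_dist=int(costs[best])))

    for j in ends:
        if group and j - group[-1] > len(adaptor_tail):
            _flush(group)
            group = []
        group.append(int(j))
    _flush(group)
    return hits


def confirm_polyT(
    read_strand_bases: str,
    hit: AdaptorHit,
    window_start_offset: int = 20,
    window_end_offset: int = 50,
    t_run: int = 4,
) -> bool:
    """True iff a run of ``t_run`` T's lies in the window after the adaptor.

    The window is ``[end_pos + start, end_pos + end)``; past-the-end
    positions are simply absent (the window truncates at the read end).
    """
    window = read_strand_bases[hit.end_pos + window_start_offset : hit.end_pos + window_end_offset]
    return "T" * t_run in window


@dataclass(frozen=True)
class LocateResult:
    putative: Optional[PutativeBarcode]
    reason: str


def locate_barcode(read: SequencedRead, config: LocatorConfig = LocatorConfig()) -> LocateResult:
    """Run the full locator on both strands of one read.

    Valid hits are adaptor placements confirmed by downstream polyT.  The
    barcode is extracted only when exactly one valid hit exists across both
    strands and at least ``barcode_len`` bases remain after it.
    """
    strands = {FORWARD: (read.bases, read.quals)}
    strands[REVERSE] = (reverse_complement(read.bases), read.quals[::-1])

    any_hit = False
    valid: list[tuple[str, AdaptorHit]] = []
    for strand, (bases, _) in strands.items():
        hits = find_adaptor_hits(
            bases,
            adaptor_tail=config.adaptor_tail,
            max_ed=config.max_ed,
            search_window=config.search_window,
            strand=strand,
        )
        any_hit = any_hit or bool(hits)
        for hit in hits:
            if confirm_polyT(
                bases,
                hit,
                window_start_offset=config.polyt_start_offset,
                window_end_offset=config.polyt_end_offset,
                t_run=config.t_run,
            ):
                valid.append((strand, hit))

    if not valid:
        return LocateResult(None, REASON_NO_POLYT if any_hit else REASON_NO_ADAPTOR)
    if len(valid) > 1:
        return LocateResult(None, REASON_MULTIPLE)

    strand, hit = valid[0]
    bases, quals = strands[strand]
    start = hit.end_pos
    barcode = bases[start : start + config.barcode_len]
    if len(barcode) < config.barcode_len:
        return LocateResult(None, REASON_TOO_SHORT)
    umi = bases[start + config.barcode_len : start + config.barcode_len + config.umi_len]
    pb = PutativeBarcode(
        read_id=read.read_id,
        barcode=barcode,
        barcode_quals=tuple(quals[start : start + config.barcode_len]),
        umi=umi,
        strand=strand,
    )
    return LocateResult(pb, REASON_OK)


def extract_putative_barcode(
    read: SequencedRead, config: LocatorConfig = LocatorConfig()
) -> Optional[PutativeBarcode]:
    """Putative barcode of the read, or ``None`` if the read is rejected."""
    return locate_barcode(read, config).putative


def extract_all(
    reads: "Iterator[SequencedRead]", config: LocatorConfig = LocatorConfig()
) -> Iterator[LocateResult]:
    for read in reads:
        yield locate_barcode(read, config)
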