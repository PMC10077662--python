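"""Cell calling: quality filtering, counting, and the quantile threshold.

High-quality putative barcodes (minQ >= 15, optionally restricted to the
list of all valid 10x barcodes) are counted per unique 16-mer.  Cells are
called by a rank-quantile rule: with an expected cell number ``N``, take
``c``, the count at (1-based, descending) rank ``ceil(0.95 * N)``, and keep
every barcode whose count strictly exceeds ``T = 0.05 * c``.  High
sensitivity mode lowers ``T`` a further ten-fold, trading precision for
recall.  A set of "background" barcodes far (edit distance > 4) from every
whitelisted barcode can be emitted for downstream ambient-RNA / empty-drops
analysis.
"""

from __future__ import annotations

import math
import random
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import edlib
import pandas as pd

from .locator import PutativeBarcode

MODE_DEFAULT = "default"
MODE_HIGH_SENSITIVITY = "high_sensitivity"

RANK_QUANTILE = 0.95
THRESHOLD_FRACTION = 0.05
HS_FACTOR = 0.1
DEFAULT_MIN_Q = 15
DEFAULT_EXPECTED_CELLS = 500


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit insert/delete/substitute)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _within_edit_distance(a: str, b: str, k: int) -> bool:
    """True iff Levenshtein(a, b) <= k, with edlib's k-bounded early exit."""
    if abs(len(a) - len(b)) > k:
        return False
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"] != -1


def min_edit_distance_le(query: str, references: Iterable[str], k: int) -> bool:
    """True iff some reference is within edit distance ``k`` of ``query``."""
    return any(_within_edit_distance(query, ref, k) for ref in references)


@dataclass
class BarcodeCountTable:
    """Occurrence counts of unique high-quality putative barcodes."""

    entries: dict[str, int] = field(default_factory=dict)

    @property
    def total_hq(self) -> int:
        return sum(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def ranked(self) -> list[tuple[str, int]]:
        """Entries sorted by descending count; ties lexicographic for determinism."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class Whitelist:
    """Called cell barcodes, in descending-count order, plus the call context."""

    barcodes: tuple[str, ...]
    threshold_T: float
    expected_cells_N: int
    mode: str = MODE_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(self, "_set", frozenset(self.barcodes))

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._set

    def __len__(self) -> int:
        return len(self.barcodes)

    def as_set(self) -> frozenset[str]:
        return self._set


def filter_high_quality(
    putative: Iterable[PutativeBarcode], min_q_threshold: int = DEFAULT_MIN_Q
) -> Iterator[PutativeBarcode]:
    """Keep putative barcodes whose minimum base quality meets the threshold."""
    for pb in putative:
        if pb.min_q >= min_q_threshold:
            yield pb


def filter_known_barcodes(
    putative: Iterable[PutativeBarcode], full_list: Optional[set[str]] = None
) -> Iterator[PutativeBarcode]:
    """Drop putative barcodes absent from the list of all valid barcodes.

    ``full_list=None`` disables the filter (synthetic barcode universes).
    """
    if full_list is None:
        yield from putative
        return
    seen_any = False
    for pb in putative:
        seen_any = True
        if pb.barcode in full_list:
            yield pb
    if seen_any and not full_list:
        warnings.warn("empty known-barcode list: every putative barcode was dropped")


def count_barcodes(putative: Iterable[PutativeBarcode]) -> BarcodeCountTable:
    """Exact occurrence counts of the (filtered) putative barcode stream."""
    counter = Counter(pb.barcode for pb in putative)
    return BarcodeCountTable(entries=dict(counter))


def quantile_threshold(
    table: BarcodeCountTable, expected_cells_N: int = DEFAULT_EXPECTED_CELLS
) -> float:
    """The count threshold ``T = 0.05 * c`` from the rank-quantile rule.

    ``c`` is the count at descending rank ``ceil(0.95 * N)``; the rank is
    clamped (with a warning) to the table size so small datasets still run.
    """
    if not table.entries:
        raise ValueError("cannot compute a threshold from an empty count table")
    if expected_cells_N < 1:
        raise ValueError("expected cell number must be >= 1")
    ranked = table.ranked()
    r = math.ceil(RANK_QUANTILE * expected_cells_N)
    if r > len(ranked):
        warnings.warn(
            f"rank {r} exceeds the {len(ranked)} unique barcodes; clamping "
            "(expected cell number is large for this dataset)"
        )
        r = len(ranked)
    r = max(r, 1)
    c = ranked[r - 1][1]
    return THRESHOLD_FRACTION * c


def build_whitelist(
    table: BarcodeCountTable,
    expected_cells_N: int = DEFAULT_EXPECTED_CELLS,
    mode: str = MODE_DEFAULT,
) -> Whitelist:
    """Call cell barcodes: every count strictly greater than the threshold."""
    if mode not in (MODE_DEFAULT, MODE_HIGH_SENSITIVITY):
        raise ValueError(f"unknown mode {mode!r}")
    T = quantile_threshold(table, expected_cells_N)
    if mode == MODE_HIGH_SENSITIVITY:
        T *= HS_FACTOR
    barcodes = tuple(bc for bc, count in table.ranked() if count > T)
    return Whitelist(
        barcodes=barcodes, threshold_T=T, expected_cells_N=expected_cells_N, mode=mode
    )


def background_barcodes(
    table: BarcodeCountTable,
    whitelist: Whitelist,
    n: int = 5000,
    min_ed_exclusive: int = 4,
    seed: int = 0,
) -> list[str]:
    """``n`` barcodes all at edit distance > ``min_ed_exclusive`` from the whitelist.

    Observed non-whitelist barcodes are preferred (they carry a real ambient
    profile downstream); the list is topped up with random 16-mers.
    Deterministic for a fixed seed.
    """
    if n <= 0:
        raise ValueError("number of background barcodes must be positive")
    rng = random.Random(seed)
    wl = whitelist.barcodes
    chosen: list[str] = []
    chosen_set: set[str] = set()

    observed = [bc for bc in sorted(table.entries) if bc not in whitelist]
    rng.shuffle(observed)
    for bc in observed:
        if len(chosen) >= n:
            break
        if not min_edit_distance_le(bc, wl, min_ed_exclusive):
            chosen.append(bc)
            chosen_set.add(bc)
    while len(chosen) < n:
        bc = "".join(rng.choice("ACGT") for _ in range(16))
        if bc in chosen_set:
            continue
        if not min_edit_distance_le(bc, wl, min_ed_exclusive):
            chosen.append(bc)
            chosen_set.add(bc)
    return chosen


def knee_frame(table: BarcodeCountTable) -> pd.DataFrame:
    """Barcode-rank data (rank, barcode, count) for knee plots."""
    ranked = table.ranked()
    return pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "barcode": [bc for bc, _ in ranked],
            "count": [c for _, c in ranked],
        }
    )


def write_barcode_list(
    barcodes: Sequence[str], path: str | Path, cellranger_suffix: bool = False
) -> None:
    """One barcode per line; optionally with the Cell Ranger ``-1`` suffix."""
    suffix = "-1" if cellranger_suffix else ""
    with open(path, "w") as out:
        for bc in barcodes:
            out.write(f"{bc}{suffix}\n")
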