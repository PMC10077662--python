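"""Assign each read's putative barcode to a whitelist entry by edit distance.

An exact match wins immediately; otherwise the unique whitelist barcode at
minimal Levenshtein distance <= ``max_ed`` (default 2) is taken.  When two
or more whitelist entries tie at the minimum the read stays unassigned —
no rescue by quality or abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import edlib

from .locator import PutativeBarcode
from .whitelist import Whitelist


@dataclass(frozen=True)
class Assignment:
    read_id: str
    barcode: Optional[str]  # None when unassigned
    edit_dist: Optional[int]
    umi: str = ""

    @property
    def assigned(self) -> bool:
        return self.barcode is not None


def assign_read(pb: PutativeBarcode, whitelist: Whitelist, max_ed: int = 2) -> Assignment:
    """Assignment of one putative barcode against the whitelist."""
    if len(whitelist) == 0:
        raise ValueError("cannot assign against an empty whitelist")
    if pb.barcode in whitelist:
        return Assignment(pb.read_id, pb.barcode, 0, pb.umi)
    best: Optional[str] = None
    best_ed = max_ed + 1
    n_best = 0
    for candidate in whitelist.barcodes:
        d = edlib.align(pb.barcode, candidate, mode="NW", task="distance", k=max_ed)[
            "editDistance"
        ]
        if d == -1:
            continue
        if d < best_ed:
            best, best_ed, n_best = candidate, d, 1
        elif d == best_ed:
            n_best += 1
    if n_best == 1:
        return Assignment(pb.read_id, best, best_ed, pb.umi)
    return Assignment(pb.read_id, None, None, pb.umi)


def assign_all(
    putative: Iterable[PutativeBarcode], whitelist: Whitelist, max_ed: int = 2
) -> list[Assignment]:
    return [assign_read(pb, whitelist, max_ed) for pb in putative]
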