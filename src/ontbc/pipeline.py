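"""End-to-end pipeline: locate barcodes, call the whitelist, assign reads.

A single streaming pass over the FASTQ collects putative barcodes and
per-read rejection tallies; the count table is built from the high-quality
(and optionally known-list-filtered) putative barcodes; reads are then
assigned to the called whitelist by edit distance.  A JSON manifest records
the resolved configuration, input checksums, and stage tallies, which are
monotone non-increasing along the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .read_io import parse_fastq, read_barcode_list
from .locator import LocatorConfig, locate_barcode, REASONS, REASON_OK
from .whitelist import (
    DEFAULT_EXPECTED_CELLS,
    DEFAULT_MIN_Q,
    MODE_DEFAULT,
    MODE_HIGH_SENSITIVITY,
    background_barcodes,
    build_whitelist,
    count_barcodes,
    filter_high_quality,
    filter_known_barcodes,
    knee_frame,
    write_barcode_list,
)
from .assign import assign_read

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fastq: Sequence[str]
    out_dir: str
    expected_cells: int = DEFAULT_EXPECTED_CELLS
    min_q: int = DEFAULT_MIN_Q
    locator: LocatorConfig = field(default_factory=LocatorConfig)
    assign_max_ed: int = 2
    full_bc_list: Optional[str] = None
    high_sensitivity: bool = False
    emit_background: Optional[int] = None
    do_assign: bool = True
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute locate -> whitelist -> assign and write all outputs.

    Returns the run manifest (also written to ``manifest.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    full_list = None
    if config.full_bc_list is not None:
        full_list = read_barcode_list(config.full_bc_list)

    tallies = {reason: 0 for reason in REASONS}
    stage = {
        "total_reads": 0,
        "adaptor_found": 0,
        "polyt_confirmed": 0,
        "exactly_one_adaptor": 0,
        "known_barcode": 0,
        "high_quality": 0,
        "assigned": 0,
    }
    putative = []
    for path in config.fastq:
        for read in parse_fastq(path):
            stage["total_reads"] += 1
            if stage["total_reads"] % 1_000_000 == 0:
                logger.info("processed %d reads", stage["total_reads"])
            result = locate_barcode(read, config.locator)
            tallies[result.reason] += 1
            if result.reason not in ("no_adaptor",):
                stage["adaptor_found"] += 1
            if result.reason not in ("no_adaptor", "no_polyT"):
                stage["polyt_confirmed"] += 1
            if result.putative is not None:
                stage["exactly_one_adaptor"] += 1
                putative.append(result.putative)
    if stage["total_reads"] == 0:
        raise ValueError("no reads found in input FASTQ(s)")

    known = list(filter_known_barcodes(putative, full_list))
    stage["known_barcode"] = len(known)
    high_quality = list(filter_high_quality(known, config.min_q))
    stage["high_quality"] = len(high_quality)
    table = count_barcodes(high_quality)

    mode = MODE_HIGH_SENSITIVITY if config.high_sensitivity else MODE_DEFAULT
    whitelist = build_whitelist(table, config.expected_cells, mode=mode)
    write_barcode_list(whitelist.barcodes, out_dir / "whitelist.txt")
    knee_frame(table).to_csv(out_dir / "knee.csv", index=False)

    outputs = {
        "whitelist": str(out_dir / "whitelist.txt"),
        "knee": str(out_dir / "knee.csv"),
    }

    if config.emit_background:
        bg = background_barcodes(
            table, whitelist, n=config.emit_background, seed=config.seed
        )
        write_barcode_list(bg, out_dir / "background.txt")
        outputs["background"] = str(out_dir / "background.txt")

    if config.do_assign and len(whitelist) > 0:
        with open(out_dir / "assignments.csv", "w") as fh:
            fh.write("read_id,assigned_barcode,edit_dist,umi\n")
            for pb in putative:
                a = assign_read(pb, whitelist, config.assign_max_ed)
                if a.assigned:
                    stage["assigned"] += 1
                    fh.write(f"{a.read_id},{a.barcode},{a.edit_dist},{a.umi}\n")
                else:
                    fh.write(f"{a.read_id},,,{a.umi}\n")
        outputs["assignments"] = str(out_dir / "assignments.csv")

    manifest = {
        "tool": "ontbc",
        "version": __version__,
        "config": {
            **asdict(config),
            "fastq": [str(p) for p in config.fastq],
            "mode": mode,
        },
        "inputs": {str(p): _sha256(p) for p in config.fastq},
        "stage_tallies": stage,
        "rejection_reasons": {k: v for k, v in tallies.items() if k != REASON_OK},
        "whitelist_size": len(whitelist),
        "threshold_T": whitelist.threshold_T,
        "usable_fraction": (
            stage["assigned"] / stage["total_reads"] if config.do_assign else None
        ),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    logger.info(
        "reads=%d putative=%d high_quality=%d whitelist=%d assigned=%d",
        stage["total_reads"],
        stage["exactly_one_adaptor"],
        stage["high_quality"],
        len(whitelist),
        stage["assigned"],
    )
    return manifest
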