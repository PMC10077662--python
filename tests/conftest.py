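from __future__ import annotations

import pytest
from hypothesis import settings

from ontbc.locator import LocatorConfig, locate_barcode
from ontbc.simulate import SimConfig, simulate
from ontbc.whitelist import (
    build_whitelist,
    count_barcodes,
    filter_high_quality,
    filter_known_barcodes,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def synthetic_knee_table(n_true=1000, true_count=100, n_noise=5000, seed=7):
    """A clean cells-vs-noise count table: plateau at ``true_count``, noise <= 4."""
    import random

    from ontbc.whitelist import BarcodeCountTable

    rng = random.Random(seed)
    entries = {}
    while len(entries) < n_true:
        entries["".join(rng.choice("ACGT") for _ in range(16))] = true_count
    while len(entries) < n_true + n_noise:
        bc = "".join(rng.choice("ACGT") for _ in range(16))
        if bc not in entries:
            entries[bc] = rng.randint(1, 4)
    return BarcodeCountTable(entries=entries)


def locate_all(reads, config=LocatorConfig()):
    return [locate_barcode(read, config) for read in reads]


def whitelist_stage(putative, universe=None, min_q=15, expected_cells=500, mode="default"):
    """Membership filter -> minQ filter -> count -> whitelist."""
    known = filter_known_barcodes(putative, universe)
    table = count_barcodes(filter_high_quality(known, min_q))
    return table, build_whitelist(table, expected_cells, mode=mode)


@pytest.fixture(scope="session")
def zero_error_run():
    """100 cells x 50 reads, no background, no errors (seed 1)."""
    config = SimConfig(
        n_cells=100,
        reads_per_cell=50,
        n_background=0,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        seed=1,
    )
    ds = simulate(config)
    results = locate_all(ds.reads)
    return ds, results


@pytest.fixture(scope="session")
def noisy_run():
    """500 cells at NB(60, 10) depth, 5000 ambient barcodes (1-3 reads),
    ~5% total error (seed 1): the default study conditions."""
    config = SimConfig(seed=1)  # defaults are exactly these conditions
    ds = simulate(config)
    results = locate_all(ds.reads)
    putative = [r.putative for r in results if r.putative is not None]
    return ds, results, putative
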