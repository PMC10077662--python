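"""Simulate nanopore-style single-cell cDNA reads with known truth.

Each perfect (error-free) read is the concatenation

    nanopore_adaptor + tenx_adaptor + barcode(16) + UMI + polyT(15) + fragment(200) + TSO

reverse-complemented with probability 1/2 (both cDNA strands are sequenced).
Errors are then injected with an explicit parametric model: independent
per-base substitution / insertion / deletion events, and a two-component
quality model in which correctly copied bases draw high Phred scores and
substituted/inserted bases draw low ones.  This deliberately simplified
error model (no adjacent-error correlation, no homopolymer effects) keeps
every parameter explicit and the output bit-reproducible for a fixed seed;
its defaults give a ~5% total error rate, typical of recent nanopore
chemistry.

Per-cell read depths default to a negative binomial (mean 60, dispersion
10, clipped to >= 1) — a realistic spread of per-cell coverage — and 5000
ambient "background" barcodes receive 1-3 reads each, skewed towards
singletons as ambient molecules are in real droplet data.  The generator
writes, alongside the FASTQ and per-read truth, the sampled barcode
universe: the synthetic analogue of the list of all valid 10x barcodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .read_io import SequencedRead, reverse_complement, write_fastq
from .locator import FORWARD, REVERSE

# The 10x read-1 primer (its last 10 nt, CTTCCGATCT, is the locator's seed)
# and the template-switch oligo are standard kit sequences; the nanopore
# adaptor is an arbitrary fixed placeholder of realistic length.
DEFAULT_TENX_ADAPTOR = "CTACACGACGCTCTTCCGATCT"
DEFAULT_NANOPORE_ADAPTOR = "TTCGTTCGGTATTACGTATTGCT"
DEFAULT_TSO = "AAGCAGTGGTATCAACGCAGAGTACAT"
DEFAULT_POLYT_LEN = 15

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class NegBinomial:
    """Negative-binomial depth spec: mean and dispersion (size) parameter.

    Variance is ``mean + mean**2 / dispersion``.
    """

    mean: float
    dispersion: float


DepthSpec = Union[int, Sequence[int], Mapping[str, int], NegBinomial]
CountDist = Union[int, Sequence[int], Mapping[int, float], NegBinomial]


@dataclass
class SimConfig:
    n_cells: int = 500
    reads_per_cell: DepthSpec = NegBinomial(mean=60.0, dispersion=10.0)
    n_background: int = 5000
    background_counts: CountDist = field(default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    barcode_universe: Optional[str] = None  # path to 16-mer list, or None for random
    umi_len: int = 12
    fragment_len: int = 200
    fragment_fasta: Optional[str] = None  # transcript FASTA, or None for random fragments
    polyt_len: int = DEFAULT_POLYT_LEN
    sub_rate: float = 0.025
    ins_rate: float = 0.010
    del_rate: float = 0.015
    qual_correct_mean: float = 25.0
    qual_correct_sd: float = 4.0
    qual_error_mean: float = 8.0
    qual_error_sd: float = 3.0
    nanopore_adaptor: str = DEFAULT_NANOPORE_ADAPTOR
    tenx_adaptor: str = DEFAULT_TENX_ADAPTOR
    tso: str = DEFAULT_TSO
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_cells < 0 or self.n_background < 0:
            raise ValueError("cell and background counts must be non-negative")


@dataclass(frozen=True)
class SimTruthRecord:
    read_id: str
    barcode: str
    umi: str
    strand: str
    fragment_id: str
    is_cell: bool


def random_barcodes(rng: np.random.Generator, n: int, length: int = 16) -> list[str]:
    """``n`` distinct random barcodes; collisions are re-drawn."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def build_perfect_read(
    barcode: str,
    umi: str,
    fragment: str,
    strand: str,
    nanopore_adaptor: str = DEFAULT_NANOPORE_ADAPTOR,
    tenx_adaptor: str = DEFAULT_TENX_ADAPTOR,
    tso: str = DEFAULT_TSO,
    polyt_len: int = DEFAULT_POLYT_LEN,
) -> str:
    """Error-free read layout; reverse-complemented for the reverse strand."""
    if len(barcode) != 16:
        raise ValueError(f"cell barcode must be 16 nt, got {len(barcode)}")
    if not umi or not fragment:
        raise ValueError("UMI and fragment must be non-empty")
    read = nanopore_adaptor + tenx_adaptor + barcode + umi + "T" * polyt_len + fragment + tso
    if strand == REVERSE:
        return reverse_complement(read)
    if strand != FORWARD:
        raise ValueError(f"unknown strand {strand!r}")
    return read


def inject_errors(
    seq: str, config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Apply per-base substitution/insertion/deletion and draw qualities.

    Qualities of substituted and inserted bases come from the error
    distribution, all others from the correct-base distribution; both are
    discretised and clipped to [1, 50].
    """
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = codes.size
    if n == 0:
        return "", []
    code_idx = np.searchsorted(_BASES, codes)  # ACGT -> 0..3 (inputs are ACGT-only)

    u = rng.random(n)
    deleted = u < config.del_rate
    substituted = (~deleted) & (u < config.del_rate + config.sub_rate)
    inserted_after = rng.random(n) < config.ins_rate

    new_idx = code_idx.copy()
    if substituted.any():
        shift = rng.integers(1, 4, size=int(substituted.sum()))
        new_idx[substituted] = (code_idx[substituted] + shift) % 4

    emit_base = ~deleted
    counts = emit_base.astype(np.int64) + inserted_after
    total = int(counts.sum())
    if total == 0:
        return "", []
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))

    out = np.empty(total, dtype=np.uint8)
    is_err = np.zeros(total, dtype=bool)
    bpos = starts[emit_base]
    out[bpos] = _BASES[new_idx[emit_base]]
    is_err[bpos] = substituted[emit_base]
    ipos = starts[inserted_after] + emit_base[inserted_after]
    out[ipos] = _BASES[rng.integers(0, 4, size=int(inserted_after.sum()))]
    is_err[ipos] = True

    quals = np.where(
        is_err,
        rng.normal(config.qual_error_mean, config.qual_error_sd, size=total),
        rng.normal(config.qual_correct_mean, config.qual_correct_sd, size=total),
    )
    quals = np.clip(np.rint(quals), 1, 50).astype(int)
    return bytes(out).decode(), quals.tolist()


def _realise_depths(
    spec: DepthSpec, barcodes: Sequence[str], rng: np.random.Generator
) -> list[int]:
    n = len(barcodes)
    if isinstance(spec, NegBinomial):
        p = spec.dispersion / (spec.dispersion + spec.mean)
        depths = rng.negative_binomial(spec.dispersion, p, size=n)
        return np.maximum(depths, 1).astype(int).tolist()
    if isinstance(spec, int):
        return [spec] * n
    if isinstance(spec, Mapping):
        missing = [bc for bc in barcodes if bc not in spec]
        if missing:
            raise ValueError(f"no read count given for {len(missing)} barcodes")
        return [int(spec[bc]) for bc in barcodes]
    depths = [int(d) for d in spec]
    if len(depths) != n:
        raise ValueError(f"{len(depths)} depths for {n} barcodes")
    return depths


def _realise_background_counts(
    dist: CountDist, n: int, rng: np.random.Generator
) -> list[int]:
    if isinstance(dist, NegBinomial):
        p = dist.dispersion / (dist.dispersion + dist.mean)
        return np.maximum(rng.negative_binomial(dist.dispersion, p, size=n), 1).astype(int).tolist()
    if isinstance(dist, int):
        return [dist] * n
    if isinstance(dist, Mapping):
        values = np.array(sorted(dist), dtype=int)
        probs = np.array([dist[int(v)] for v in values], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(values, size=n, p=probs).astype(int).tolist()
    counts = [int(c) for c in dist]
    if len(counts) != n:
        raise ValueError(f"{len(counts)} counts for {n} background barcodes")
    return counts


def _load_fragment_pool(path: str, fragment_len: int) -> list[tuple[str, str]]:
    """(name, sequence) of transcripts long enough to yield a fragment."""
    from Bio import SeqIO

    pool = []
    for record in SeqIO.parse(path, "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if len(seq) >= fragment_len and set(seq) <= set("ACGTN"):
            pool.append((record.id, seq))
    if not pool:
        raise ValueError(f"no transcript of length >= {fragment_len} in {path}")
    return pool


@dataclass
class SimulatedDataset:
    """In-memory result of a simulation run."""

    reads: list[SequencedRead]
    truth: list[SimTruthRecord]
    cell_barcodes: list[str]
    background_barcodes: list[str]

    @property
    def universe(self) -> list[str]:
        return self.cell_barcodes + self.background_barcodes


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate the full dataset in memory (bit-reproducible for a seed)."""
    rng = np.random.default_rng(config.seed)

    if config.barcode_universe is not None:
        from .read_io import read_barcode_list

        universe = sorted(read_barcode_list(config.barcode_universe))
        need = config.n_cells + config.n_background
        if len(universe) < need:
            raise ValueError(f"barcode universe has {len(universe)} < {need} barcodes")
        picked = rng.choice(len(universe), size=need, replace=False)
        pool = [universe[i] for i in picked]
    else:
        pool = random_barcodes(rng, config.n_cells + config.n_background)
    cells = pool[: config.n_cells]
    background = pool[config.n_cells :]

    depths = _realise_depths(config.reads_per_cell, cells, rng)
    bg_counts = _realise_background_counts(config.background_counts, len(background), rng)

    fragments = None
    if config.fragment_fasta is not None:
        fragments = _load_fragment_pool(config.fragment_fasta, config.fragment_len)

    reads: list[SequencedRead] = []
    truth: list[SimTruthRecord] = []
    read_no = 0
    for barcode, depth, is_cell in [
        *zip(cells, depths, [True] * len(cells)),
        *zip(background, bg_counts, [False] * len(background)),
    ]:
        for _ in range(depth):
            umi = bytes(_BASES[rng.integers(0, 4, size=config.umi_len)]).decode()
            if fragments is None:
                fragment = bytes(_BASES[rng.integers(0, 4, size=config.fragment_len)]).decode()
                fragment_id = f"random_{read_no}"
            else:
                t_idx = int(rng.integers(0, len(fragments)))
                name, seq = fragments[t_idx]
                start = int(rng.integers(0, len(seq) - config.fragment_len + 1))
                fragment = seq[start : start + config.fragment_len].replace("N", "A")
                fragment_id = name
            strand = REVERSE if rng.random() < 0.5 else FORWARD
            perfect = build_perfect_read(
                barcode,
                umi,
                fragment,
                strand,
                nanopore_adaptor=config.nanopore_adaptor,
                tenx_adaptor=config.tenx_adaptor,
                tso=config.tso,
                polyt_len=config.polyt_len,
            )
            bases, quals = inject_errors(perfect, config, rng)
            read_id = f"sim{read_no:08d}"
            reads.append(SequencedRead(read_id=read_id, bases=bases, quals=tuple(quals)))
            truth.append(
                SimTruthRecord(
                    read_id=read_id,
                    barcode=barcode,
                    umi=umi,
                    strand=strand,
                    fragment_id=fragment_id,
                    is_cell=is_cell,
                )
            )
            read_no += 1
    return SimulatedDataset(
        reads=reads, truth=truth, cell_barcodes=cells, background_barcodes=background
    )


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Run the simulation and write FASTQ, truth TSV, and barcode lists.

    Returns a dict of output paths: ``fastq``, ``truth``, ``truth_whitelist``,
    ``barcode_universe``, ``config``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate(config)

    paths = {
        "fastq": str(out / "reads.fastq.gz"),
        "truth": str(out / "truth.tsv"),
        "truth_whitelist": str(out / "truth_whitelist.txt"),
        "barcode_universe": str(out / "barcode_universe.txt"),
        "config": str(out / "sim_config.json"),
    }
    write_fastq(ds.reads, paths["fastq"])
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tbarcode\tumi\tstrand\tfragment_id\tis_cell\n")
        for rec in ds.truth:
            fh.write(
                f"{rec.read_id}\t{rec.barcode}\t{rec.umi}\t{rec.strand}\t"
                f"{rec.fragment_id}\t{str(rec.is_cell).lower()}\n"
            )
    with open(paths["truth_whitelist"], "w") as fh:
        fh.writelines(f"{bc}\n" for bc in ds.cell_barcodes)
    with open(paths["barcode_universe"], "w") as fh:
        fh.writelines(f"{bc}\n" for bc in ds.universe)
    with open(paths["config"], "w") as fh:

        def _default(obj):
            return asdict(obj) if isinstance(obj, NegBinomial) else str(obj)

        json.dump(asdict(config), fh, indent=2, default=_default)
        fh.write("\n")
    return paths
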