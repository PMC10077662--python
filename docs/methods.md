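# Methods

## The barcode-identification model

A 10x Chromium 3′ cDNA read, sequenced on a nanopore device, begins (on
one strand or the other) with sequencing/library adaptors, then the
16-nt cell barcode, a 12-nt UMI and the polyT tract, followed by the
cDNA body. `ontbc` recovers the barcode in three stages.

**Locating the adaptor.** The last 10 nt of the read-1 adaptor
(`CTTCCGATCT`) is aligned semi-globally — the adaptor aligned end to end,
free placement in the target — within the first 200 nt of the read,
with unit-cost substitutions, insertions and deletions and a total
budget of 2. The paper-thin scoring choice matters: we deliberately use
plain edit distance rather than an affine or matrix scheme, because the
downstream decision is a hard threshold on the number of edits. The
search is a banded-free DP vectorised over target positions (the in-row
horizontal dependency is resolved with the prefix-min-plus-slope
identity), and every end position with cost ≤ 2 is a candidate.
Candidates closer than the adaptor length collapse to the cheapest one
(ties to the leftmost), so a single noisy adaptor copy is one candidate,
not several. `N` bases match nothing. An exhaustive
all-placements DP oracle in the test suite checks presence and minimal
cost on random reads.

**PolyT confirmation and the exactly-one rule.** A candidate is valid
only if `TTTT` occurs in the window 20–50 nt after the adaptor end — the
polyT itself is frequently truncated by homopolymer basecalling, hence
a short run with a generous window rather than a long exact match. The
same search runs on the reverse complement (qualities reversed to stay
base-aligned), also windowed to the first 200 nt of that strand. Only
reads with exactly one valid candidate across both strands are used;
with two plausible barcode positions the extraction would be a guess.
On error-free simulated reads with random fragments, ~2–4% of reads are
discarded by this rule because a second ED ≤ 2 adaptor-like match with
chance downstream T's occurs in the cDNA body; this is inherent to the
method, not an artefact of the implementation.

**Quality selection and cell calling.** Basecalling errors carry low
Phred scores, so the minimum quality across the 16 barcode bases (minQ)
is a strong proxy for barcode integrity; barcodes with minQ < 15 are
dropped. When a list of all valid barcodes is supplied (the 737K-entry
kit list in real data; the simulator's emitted universe in synthetic
data) non-members are dropped before counting — this removes both
basecalling-corrupted barcodes that slipped past minQ and off-by-one
extractions caused by indels inside the adaptor. The surviving barcodes
are counted, ranked (ties broken lexicographically for determinism),
and thresholded: with expected cell count N (default 500), c is the
count at 1-based descending rank ⌈0.95·N⌉ and cells are barcodes with
count strictly above T = 0.05·c. The rank is clamped to the table size
(with a warning) so small datasets run. High-sensitivity mode multiplies
T by 0.1; it always yields a superset of the default whitelist.

**Assignment and background.** Reads are assigned to the whitelist
entry at minimal Levenshtein distance ≤ 2; an exact match short-circuits
the scan, and a tie at the minimum leaves the read unassigned — we
prefer losing a read to mis-assigning it, and no quality- or
abundance-based rescue is attempted. Background barcodes for ambient-RNA
analysis are drawn preferentially from observed non-whitelist barcodes
(they carry a real ambient expression profile downstream), topped up
with random 16-mers, all at edit distance > 4 from every whitelist
entry so that no true-cell read can be captured by them at the
assignment distance of 2.

## The simulator

Each simulated molecule is a perfect read
`nanopore_adaptor + tenx_adaptor + barcode + UMI + 15×T + 200-nt fragment + TSO`,
reverse-complemented with probability ½. The 10x adaptor and TSO default
to the standard kit sequences (only the adaptor's last 10 nt are load
bearing); the nanopore adaptor is an arbitrary placeholder. Fragments
are random by default or sampled from a transcript FASTA.

Errors are injected with an explicit parametric model: independent
per-base substitution (0.025), insertion (0.010) and deletion (0.015)
events — 5% total, matching the ~4–5% median error of current nanopore
chemistry — and a two-component quality model: correct bases draw from a
discretised normal around Q25 (sd 4) and substituted/inserted bases from
one around Q8 (sd 3), clipped to [1, 50]. The component means are chosen
so that a clean barcode passes minQ ≥ 15 about 90% of the time while an
errored base essentially never does, the regime the quality filter is
designed for. The model is intentionally simpler than real nanopore
error structure: errors are independent (no adjacent-error clustering),
homopolymers are not specially treated, and read-length variation is
absent. Tests passing on this simulator therefore demonstrate the
pipeline's logic and its behaviour under idealised noise, not
performance on real flow-cell data, where clustered errors in the
barcode region make recovery strictly harder.

Default study conditions: 500 cells with depths from a negative
binomial (mean 60, dispersion 10; variance = mean + mean²/dispersion),
clipped to ≥ 1 since a cell with zero captured molecules is
unobservable in principle; 5000 ambient background barcodes with 1–3
reads each (70/20/10%), reflecting the strong singleton skew of ambient
molecules at shallow depth. All randomness flows through one seeded
generator; runs are bit-reproducible.

## Evaluation conventions

Precision/recall are computed over prediction sets `{barcode: count > t}`;
an empty prediction has precision 1 by convention. The curve sweeps
every distinct count value plus zero. For the AUC we take, at each
achieved recall level, the best precision over thresholds attaining it
(several thresholds can share a recall), anchor the curve at
(recall 0, first precision) and integrate by trapezoid over recall; a
count table that separates truth from background with a gap then scores
exactly 1.0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `max_ed` | 2 | edit budget for the 10-nt adaptor search |
| `search_window` | 200 nt | prefix searched on each strand |
| polyT window | 20–50 nt | offset range after the adaptor for `TTTT` |
| `min_q` | 15 | minQ threshold for high-quality barcodes |
| `expected_cells` (N) | 500 | sets the quantile rank ⌈0.95·N⌉ |
| HS factor | 0.1 | threshold multiplier in high-sensitivity mode |
| `assign_max_ed` | 2 | maximal distance for read→whitelist assignment |
| background min ED | > 4 | exclusion distance for background barcodes |
| `umi_len` | 12 | UMI length (10–12 across kit versions) |

## Numerical and degenerate-input choices

The quantile rank uses the ceiling when 0.95·N is fractional (the
conservative, lower-threshold direction) and exact rank otherwise; the
count c is taken at the exact rank, not interpolated. T is kept as a
real number. Whitelist membership uses strict `count > T`. Empty count
tables are a hard error; tables smaller than the rank clamp with a
warning. Empty FASTQ files parse to an empty stream, but a pipeline run
over zero reads is an error. Reads shorter than the adaptor, or with
fewer than 16 bases after it, are rejected with a tallied reason.

## Known limitations

The rank-quantile threshold assumes cell read counts exceed background
counts by well over 20-fold (so that T = 0.05·c lands between them);
at shallow per-cell depth T drops below 1 and every observed barcode
passes — the caller reproduces this faithfully rather than patching it.
For the same reason the whitelist is insensitive to N only while
⌈0.95·N⌉ stays within the cell plateau of the ranked counts; far beyond
the true cell number, c collapses to the ambient tail and the whitelist
inflates. UMIs are extracted and propagated but never deduplicated or
error-corrected here; that belongs to downstream quantification.
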