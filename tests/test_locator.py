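from __future__ import annotations

import random

import pytest
from hypothesis import given, strategies as st

from dp_oracles import semiglobal_end_costs_brute
from ontbc.locator import (
    DEFAULT_ADAPTOR_TAIL,
    FORWARD,
    REVERSE,
    AdaptorHit,
    LocatorConfig,
    confirm_polyT,
    find_adaptor_hits,
    locate_barcode,
)
from ontbc.read_io import SequencedRead, reverse_complement_read

ADAPTOR = DEFAULT_ADAPTOR_TAIL
BARCODE = "AAACCCAAGAAACACT"
UMI = "GTACGTACGTAC"


def make_read(prefix="G" * 40, barcode=BARCODE, umi=UMI, tail="C" * 60, read_id="r"):
    bases = prefix + ADAPTOR + barcode + umi + "T" * 15 + tail
    return SequencedRead(read_id, bases, (30,) * len(bases))


class TestFindAdaptorHits:
    def test_exact_match_position_and_distance(self):
        hits = find_adaptor_hits("A" * 50 + ADAPTOR + "T" * 30 + "A" * 100)
        assert hits == [AdaptorHit(FORWARD, 60, 0)]

    def test_single_substitution_costs_one(self):
        mutated = ADAPTOR[:-2] + "AT"  # CTTCCGATAT
        hits = find_adaptor_hits("A" * 50 + mutated + "T" * 30)
        assert len(hits) == 1 and hits[0].edit_dist == 1

    def test_homopolymer_read_has_no_hit(self):
        assert find_adaptor_hits("A" * 300) == []

    def test_search_restricted_to_window(self):
        bases = "G" * 250 + ADAPTOR + "T" * 30
        assert find_adaptor_hits(bases) == []
        assert find_adaptor_hits(bases, search_window=300) != []

    def test_two_distant_copies_are_distinct_hits(self):
        bases = "G" * 20 + ADAPTOR + "G" * 40 + ADAPTOR + "G" * 40
        hits = find_adaptor_hits(bases)
        assert [h.end_pos for h in hits] == [30, 80]
        assert all(h.edit_dist == 0 for h in hits)

    def test_empty_and_short_reads(self):
        assert find_adaptor_hits("") == []
        assert find_adaptor_hits("CTT") == []

    def test_n_bases_never_match(self):
        # Adaptor copy with three N's cannot reach edit distance <= 2
        noisy = ADAPTOR[:3] + "NNN" + ADAPTOR[6:]
        assert find_adaptor_hits("G" * 30 + noisy + "G" * 30) == []

    def test_agrees_with_brute_force_dp_on_random_reads(self):
        """Presence and minimal distance match an exhaustive placement DP."""
        rng = random.Random(42)
        window = 100
        for _ in range(300):
            length = rng.randint(0, 120)
            bases = "".join(rng.choice("ACGTN") for _ in range(length))
            if rng.random() < 0.5 and length > 12:
                pos = rng.randint(0, length - 10)
                copy = list(ADAPTOR)
                for _ in range(rng.randint(0, 3)):
                    copy[rng.randrange(10)] = rng.choice("ACGT")
                bases = bases[:pos] + "".join(copy) + bases[pos + 10 :]
            hits = find_adaptor_hits(bases, search_window=window)
            oracle = semiglobal_end_costs_brute(bases[:window], ADAPTOR)
            oracle_hits = {e: d for e, d in oracle.items() if d <= 2 and e > 0}
            assert bool(hits) == bool(oracle_hits)
            if hits:
                assert min(h.edit_dist for h in hits) == min(oracle_hits.values())
                for h in hits:
                    assert oracle_hits[h.end_pos] == h.edit_dist


class TestConfirmPolyT:
    @pytest.mark.parametrize(
        "offset,expected", [(30, True), (20, True), (46, True), (10, False), (47, False)]
    )
    def test_window_boundaries(self, offset, expected):
        hit = AdaptorHit(FORWARD, 10, 0)
        bases = "G" * (10 + offset) + "TTTT" + "G" * 60
        assert confirm_polyT(bases, hit) is expected

    def test_truncated_window_without_run(self):
        hit = AdaptorHit(FORWARD, 0, 0)
        assert confirm_polyT("G" * 22 + "TT", hit) is False


class TestLocateBarcode:
    def test_forward_read_yields_barcode_umi_and_quals(self):
        read = make_read()
        pb = locate_barcode(read).putative
        assert pb is not None
        assert (pb.barcode, pb.umi, pb.strand) == (BARCODE, UMI, FORWARD)
        assert pb.barcode_quals == (30,) * 16
        assert pb.min_q == 30

    def test_reverse_read_yields_same_barcode(self):
        rc = reverse_complement_read(make_read())
        pb = locate_barcode(rc).putative
        assert pb is not None
        assert (pb.barcode, pb.umi, pb.strand) == (BARCODE, UMI, REVERSE)

    def test_adaptor_on_both_strands_is_discarded(self):
        fwd = make_read()
        bases = fwd.bases + "A" * 10 + reverse_complement_read(fwd).bases
        result = locate_barcode(SequencedRead("r", bases, (30,) * len(bases)))
        assert result.putative is None
        assert result.reason == "multiple_adaptors"

    def test_missing_polyt_is_discarded(self):
        bases = "G" * 40 + ADAPTOR + BARCODE + UMI + "G" * 60
        result = locate_barcode(SequencedRead("r", bases, (30,) * len(bases)))
        assert result.putative is None
        assert result.reason == "no_polyT"

    def test_no_adaptor_reason(self):
        result = locate_barcode(SequencedRead("r", "G" * 120, (30,) * 120))
        assert result.reason == "no_adaptor"

    def test_too_short_after_adaptor(self):
        # With the default 20-50 nt polyT window a confirmed read always has
        # >= 24 bases after the adaptor, so truncation needs an earlier window.
        config = LocatorConfig(polyt_start_offset=0, polyt_end_offset=20)
        bases = "G" * 40 + ADAPTOR + "TTTTACGT"
        result = locate_barcode(SequencedRead("r", bases, (30,) * len(bases)), config)
        assert result.putative is None
        assert result.reason == "too_short"

    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        """A read and its reverse complement give the same barcode and UMI."""
        rng = random.Random(seed)
        prefix = "".join(rng.choice("ACG") for _ in range(rng.randint(0, 60)))
        barcode = "".join(rng.choice("ACGT") for _ in range(16))
        umi = "".join(rng.choice("ACGT") for _ in range(12))
        tail = "".join(rng.choice("ACG") for _ in range(60))
        read = make_read(prefix=prefix, barcode=barcode, umi=umi, tail=tail)
        fwd = locate_barcode(read)
        rev = locate_barcode(reverse_complement_read(read))
        if fwd.putative is None:
            assert rev.putative is None
        else:
            assert rev.putative is not None
            assert fwd.putative.barcode == rev.putative.barcode
            assert fwd.putative.umi == rev.putative.umi
            assert fwd.putative.barcode_quals == rev.putative.barcode_quals
            assert fwd.putative.strand != rev.putative.strand

    def test_error_free_simulated_reads_recover_truth(self, zero_error_run):
        ds, results = zero_error_run
        extracted = 0
        for result, truth in zip(results, ds.truth):
            if result.putative is None:
                # only the exactly-one-adaptor rule may reject error-free reads
                assert result.reason == "multiple_adaptors"
                continue
            extracted += 1
            assert result.putative.barcode == truth.barcode
            assert result.putative.umi == truth.umi
            assert result.putative.strand == truth.strand
        assert extracted >= 0.9 * len(ds.reads)

    def test_configurable_umi_length(self):
        read = make_read(umi="GTACGTACGT" + "TT")  # layout unchanged
        pb = locate_barcode(read, LocatorConfig(umi_len=10)).putative
        assert pb is not None and pb.umi == "GTACGTACGT"
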