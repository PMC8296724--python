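"""Filtering, merging, windowing and masking rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdrpipe.read_processing import (
    DemultiplexConfigError,
    ProcessParams,
    ReadPair,
    demultiplex,
    extract_window,
    filter_length,
    mask_low_quality,
    merge_pair,
    process_pairs,
    rescue_unassembled,
)
from hdrpipe.sequtil import revcomp


def _pair(fwd, rev, q=38, rid="r1"):
    return ReadPair(rid, fwd, np.full(len(fwd), q, dtype=np.uint8),
                    rev, np.full(len(rev), q, dtype=np.uint8))


def _pair_from_template(template, read_len=250):
    return _pair(template[:read_len], revcomp(template)[:read_len])


def _random_dna(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestDemultiplex:
    def test_printed_primers_route_to_their_locus(self, slc_locus, dnd):
        loci = [slc_locus, dnd]
        pairs = [
            _pair_from_template(slc_locus.amplicon, 250),
            _pair_from_template(dnd.amplicon, 250),
            _pair_from_template(_random_dna(1, 300), 250),
        ]
        assigned, counts = demultiplex(pairs, loci)
        assert counts["slc45a2"] == 1 and counts["dnd"] == 1
        assert counts["unassigned"] == 1 and counts["ambiguous"] == 0
        assert assigned["slc45a2"][0].fwd_seq.startswith("CAGATGTCCAGAGGCTGCTGCT")
        assert assigned["dnd"][0].fwd_seq.startswith("GGGGAAAGGCTAGGGAGAGA")

    def test_two_mismatches_tolerated_three_not(self, slc_locus, dnd):
        template = slc_locus.amplicon
        good = _pair_from_template(template)
        mutated2 = "TT" + good.fwd_seq[2:]
        mutated3 = "TTT" + good.fwd_seq[3:]
        p2 = _pair(mutated2, good.rev_seq)
        p3 = _pair(mutated3, good.rev_seq)
        _, counts = demultiplex([p2, p3], [slc_locus, dnd])
        assert counts["slc45a2"] == 1 and counts["unassigned"] == 1

    def test_near_identical_primer_config_rejected(self, slc_locus):
        clone = type(slc_locus)(
            "clone", slc_locus.amplicon, slc_locus.fwd_primer,
            slc_locus.rev_primer, slc_locus.window, slc_locus.guide)
        with pytest.raises(DemultiplexConfigError):
            demultiplex([], [slc_locus, clone])


class TestFilterLength:
    def test_short_mate_removes_pair(self):
        kept, dropped = filter_length([_pair("A" * 99, "C" * 250)], min_len=100)
        assert kept == [] and dropped == 1

    def test_boundary_inclusive(self):
        kept, dropped = filter_length([_pair("A" * 100, "C" * 100)], min_len=100)
        assert len(kept) == 1 and dropped == 0

    def test_empty_input(self):
        assert filter_length([], 100) == ([], 0)


class TestMergePair:
    def test_identical_fully_overlapping_mates(self):
        template = _random_dna(7, 250)
        merged = merge_pair(_pair_from_template(template), min_overlap=150)
        assert merged is not None
        assert merged.seq == template and merged.overlap == 250
        assert merged.mismatches == 0

    def test_min_overlap_locus_settings(self):
        """250-nt mates from a 330-nt template overlap by 170: enough for a
        150-bp threshold, not for 200."""
        template = _random_dna(8, 330)
        pair = _pair_from_template(template)
        ok = merge_pair(pair, min_overlap=150)
        assert ok is not None and ok.overlap == 170 and ok.seq == template
        assert merge_pair(pair, min_overlap=200) is None

    @pytest.mark.parametrize("n_mismatch,accepted", [(30, True), (31, False)])
    def test_twenty_percent_mismatch_boundary(self, n_mismatch, accepted):
        """150-base overlap: 30 mismatches (20.0%) pass, 31 (20.7%) fail."""
        template = _random_dna(9, 350)
        fwd = template[:250]
        rev_read = revcomp(template)[:250]
        # corrupt n bases of the reverse read inside the 150-base overlap
        rc = revcomp(rev_read)  # sense orientation, equals template[100:350]
        pos = range(105, 105 + 4 * n_mismatch, 4)  # distinct, inside 100..250
        chars = list(rc)
        for p in pos:
            chars[p - 100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p - 100]]
        corrupted = revcomp("".join(chars))
        result = merge_pair(_pair(fwd, corrupted), min_overlap=150)
        assert (result is not None) is accepted
        if accepted:
            assert result.overlap == 150 and result.mismatches == n_mismatch

    def test_consensus_takes_higher_quality_base(self):
        template = _random_dna(10, 250)
        fwd = template
        rev_sense = list(template)
        rev_sense[100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[rev_sense[100]]
        rev_read = revcomp("".join(rev_sense))
        fq = np.full(250, 20, dtype=np.uint8)
        rq = np.full(250, 35, dtype=np.uint8)
        merged = merge_pair(ReadPair("r", fwd, fq, rev_read, rq), min_overlap=150)
        assert merged.seq[100] == "".join(rev_sense)[100]  # higher-quality wins
        # equal quality: forward base wins
        merged_eq = merge_pair(ReadPair("r", fwd, fq, rev_read, fq.copy()),
                               min_overlap=150)
        assert merged_eq.seq[100] == template[100]
        assert (merged.quals == 35).all()

    def test_ties_prefer_longest_overlap(self):
        # homopolymer reads overlap perfectly at every length: longest wins
        pair = _pair("A" * 200, "T" * 200)
        merged = merge_pair(pair, min_overlap=50)
        assert merged.overlap == 200


class TestRescueAndWindow:
    def test_rescue_conserves_read_count(self):
        t_ok = _random_dna(11, 300)
        t_fail = _random_dna(12, 460)  # overlap 40 < 150 -> merge fails
        pairs = [_pair_from_template(t_ok), _pair_from_template(t_fail)]
        merged = [merge_pair(p, 150) for p in pairs]
        ok = [m for m in merged if m is not None]
        failed = [p for p, m in zip(pairs, merged) if m is None]
        out = rescue_unassembled(ok, failed)
        assert len(out) == len(pairs)
        origins = {o[3] for o in out}
        assert origins == {"assembled", "forward_only"}

    @pytest.mark.parametrize("window,expect_len", [((20, 200), 181), ((60, 230), 171)])
    def test_window_lengths(self, window, expect_len):
        seq = _random_dna(13, 250)
        quals = np.full(250, 38, dtype=np.uint8)
        wseq, wq = extract_window(seq, quals, window)
        assert len(wseq) == expect_len and len(wq) == expect_len
        assert wseq == seq[window[0] - 1:window[1]]

    def test_short_read_dropped(self):
        seq = _random_dna(14, 150)
        assert extract_window(seq, np.full(150, 38, dtype=np.uint8), (60, 230)) is None


class TestMasking:
    def test_high_quality_unchanged(self):
        seq = _random_dna(15, 100)
        out, n = mask_low_quality(seq, np.full(100, 40, dtype=np.uint8))
        assert out == seq and n == 0

    @pytest.mark.parametrize("n_low,kept", [(5, True), (6, False)])
    def test_five_n_cap(self, n_low, kept):
        seq = _random_dna(16, 100)
        quals = np.full(100, 40, dtype=np.uint8)
        quals[:n_low] = 19
        result = mask_low_quality(seq, quals)
        if kept:
            masked, n = result
            assert n == n_low and masked[:n_low] == "N" * n_low
            assert masked[n_low:] == seq[n_low:]
        else:
            assert result is None

    def test_quality_exactly_twenty_kept(self):
        seq = "ACGT"
        out, n = mask_low_quality(seq, np.array([20, 20, 20, 20], dtype=np.uint8))
        assert out == seq and n == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_masking_only_introduces_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        quals = rng.integers(2, 41, n).astype(np.uint8)
        result = mask_low_quality(seq, quals, max_n=n + 1)
        masked, n_count = result
        assert len(masked) == len(seq)
        assert n_count == masked.count("N")
        for orig, new, q in zip(seq, masked, quals):
            assert new == (orig if q >= 20 else "N")


def test_pipeline_order_and_conservation(slc_locus, ki_edit):
    """process_pairs accounts for every input pair across all stages."""
    import numpy as np

    from hdrpipe.synthetic_data import ReadSimConfig, build_mixture, simulate_sample

    mix = build_mixture(slc_locus, ki_edit, {"perfect_hdr": 0.4, "wild_type": 0.6},
                        np.random.default_rng(1))
    pairs, _ = simulate_sample(mix, ReadSimConfig(n_read_pairs=500, seed=4))
    short = ReadPair("short", "A" * 90, np.full(90, 38, dtype=np.uint8),
                     "C" * 250, np.full(250, 38, dtype=np.uint8))
    processed, ledger = process_pairs(pairs + [short], slc_locus,
                                      ProcessParams(min_overlap=150))
    assert ledger["input_pairs"] == 501
    assert ledger["dropped_short"] == 1
    total = (ledger["dropped_short"] + ledger["dropped_window"]
             + ledger["dropped_masking"] + ledger["processed"])
    assert total == ledger["input_pairs"]
    assert all(len(r.window_seq) == slc_locus.window_length for r in processed)
    assert all(r.n_count <= 5 for r in processed)
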