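"""Truth-known read simulator: alleles, samples, cohorts."""

import numpy as np
import pytest

from hdrpipe.hdr_classification import classify_variant
from hdrpipe.locus_model import build_expected_alleles
from hdrpipe.pipeline import analyze_pairs
from hdrpipe.read_processing import ProcessParams, read_fastq_pairs, write_fastq_pairs
from hdrpipe.synthetic_data import (
    AlleleMixture,
    CohortGroupSpec,
    ReadSimConfig,
    build_mixture,
    make_allele,
    simulate_cohort,
    simulate_sample,
)
from hdrpipe.group_stats import mann_whitney
from hdrpipe.variant_calling import Variant


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(42)


class TestMakeAllele:
    def test_wild_type_is_amplicon(self, slc_locus, ki_edit, rng):
        assert make_allele(slc_locus, ki_edit, "wild_type", rng) == slc_locus.amplicon

    def test_perfect_hdr_window_matches_expected(self, slc_locus, ki_edit, rng):
        exp = build_expected_alleles(slc_locus, ki_edit)
        allele = make_allele(slc_locus, ki_edit, "perfect_hdr", rng)
        ws, we = slc_locus.window
        assert allele[ws - 1:we] == exp.hdr_window

    @pytest.mark.parametrize("label,intact_side", [
        ("erroneous_hdr_5p", "3p"), ("erroneous_hdr_3p", "5p")])
    def test_erroneous_alleles_carry_core_with_one_broken_side(
            self, slc_locus, ki_edit, rng, label, intact_side):
        exp = build_expected_alleles(slc_locus, ki_edit)
        ws, we = slc_locus.window
        for _ in range(20):
            window = make_allele(slc_locus, ki_edit, label, rng)[ws - 1:we]
            call = classify_variant(Variant(window, 1, ("r",)), exp)
            assert call.label == "erroneous_hdr"
            assert exp.core in window
            if intact_side == "3p":
                assert call.perfect_3p and not call.perfect_5p
            else:
                assert call.perfect_5p and not call.perfect_3p

    def test_nhej_allele_lacks_core_and_differs(self, dnd, snr_edit, rng):
        exp = build_expected_alleles(dnd, snr_edit)
        for _ in range(20):
            allele = make_allele(dnd, snr_edit, "nhej", rng)
            assert allele != dnd.amplicon
            assert exp.core not in allele


class TestSimulateSample:
    def test_same_seed_byte_identical(self, slc_locus, ki_edit):
        mix = build_mixture(slc_locus, ki_edit,
                            {"perfect_hdr": 0.3, "wild_type": 0.7},
                            np.random.default_rng(0))
        cfg = ReadSimConfig(n_read_pairs=200, seed=5)
        a, ta = simulate_sample(mix, cfg)
        b, tb = simulate_sample(mix, cfg)
        assert [(p.id, p.fwd_seq, p.rev_seq) for p in a] == \
               [(p.id, p.fwd_seq, p.rev_seq) for p in b]
        assert all((p.fwd_quals == q.fwd_quals).all() for p, q in zip(a, b))
        assert ta.equals(tb)

    def test_pure_wildtype_errorfree_reads_match_amplicon(self, slc_locus, ki_edit):
        mix = AlleleMixture((("wild_type", slc_locus.amplicon, 1.0),))
        cfg = ReadSimConfig(n_read_pairs=50, per_base_error=0.0, p_lowq=0.0, seed=1)
        pairs, _ = simulate_sample(mix, cfg)
        amp = slc_locus.amplicon
        for p in pairs:
            assert p.fwd_seq == amp[:250]
            rev = p.rev_seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert rev == amp[-250:]

    def test_zero_pairs(self, slc_locus, ki_edit):
        mix = AlleleMixture((("wild_type", slc_locus.amplicon, 1.0),))
        pairs, truth = simulate_sample(mix, ReadSimConfig(n_read_pairs=0, seed=1))
        assert pairs == [] and truth.empty

    def test_bad_fractions_rejected(self, slc_locus):
        with pytest.raises(ValueError):
            AlleleMixture((("wild_type", slc_locus.amplicon, 0.6),))

    def test_errorfree_pipeline_recovers_truth_exactly(self, slc_locus, ki_edit):
        """With no sequencing errors or masking, pipeline class fractions
        equal the multinomial draw fractions exactly (truth-table oracle)."""
        mix = build_mixture(
            slc_locus, ki_edit,
            {"perfect_hdr": 0.10, "erroneous_hdr_5p": 0.05, "wild_type": 0.85},
            np.random.default_rng(2))
        cfg = ReadSimConfig(n_read_pairs=2000, per_base_error=0.0, p_lowq=0.0, seed=3)
        pairs, truth = simulate_sample(mix, cfg)
        res = analyze_pairs(pairs, slc_locus, ki_edit,
                            ProcessParams(min_overlap=150), min_reads=20)
        counts = truth.true_label.value_counts()
        n = len(truth)
        assert res.summary.denominator == n
        assert res.summary.pct_perfect == pytest.approx(100 * counts["perfect_hdr"] / n)
        assert res.summary.pct_erroneous == pytest.approx(
            100 * counts["erroneous_hdr_5p"] / n)
        assert res.summary.pct_wild_type == pytest.approx(100 * counts["wild_type"] / n)


class TestSimulateCohort:
    def test_huge_concentration_pins_fractions_to_mean(self, slc_locus, ki_edit):
        spec = CohortGroupSpec("g", 5, mean_perfect=0.2, mean_erroneous=0.02,
                               mean_nhej=0.3, concentration=1e12)
        samples = simulate_cohort(slc_locus, ki_edit, [spec],
                                  ReadSimConfig(n_read_pairs=0), seed=9)
        for s in samples:
            assert s.truth_fractions["perfect_hdr"] == pytest.approx(0.2, abs=1e-6)

    def test_stratified_cohort_mean_matches_condition(self, slc_locus, ki_edit):
        spec = CohortGroupSpec("g", 30, mean_perfect=0.136, concentration=9.0)
        samples = simulate_cohort(slc_locus, ki_edit, [spec],
                                  ReadSimConfig(n_read_pairs=0), seed=9,
                                  stratified=True)
        perf = np.array([s.truth_fractions["perfect_hdr"] for s in samples])
        assert perf.mean() == pytest.approx(0.136, abs=0.01)
        assert perf.std(ddof=1) == pytest.approx(0.109, abs=0.035)

    def test_identical_groups_rarely_significant(self, slc_locus, ki_edit):
        """Type-I control: two groups simulated from one condition should
        differ significantly in at most ~10% of replicates."""
        spec = dict(mean_perfect=0.15, mean_erroneous=0.02, mean_nhej=0.3,
                    concentration=9.0)
        n_sig = 0
        reps = 200
        for rep in range(reps):
            groups = [CohortGroupSpec("a", 10, **spec), CohortGroupSpec("b", 10, **spec)]
            samples = simulate_cohort(slc_locus, ki_edit, groups,
                                      ReadSimConfig(n_read_pairs=0), seed=1000 + rep)
            a = [s.truth_fractions["perfect_hdr"] for s in samples if s.group == "a"]
            b = [s.truth_fractions["perfect_hdr"] for s in samples if s.group == "b"]
            if mann_whitney(a, b).p_value < 0.05:
                n_sig += 1
        assert n_sig <= 0.10 * reps

    def test_adding_group_does_not_perturb_existing_draws(self, slc_locus, ki_edit):
        one = simulate_cohort(slc_locus, ki_edit,
                              [CohortGroupSpec("a", 3, mean_perfect=0.2)],
                              ReadSimConfig(n_read_pairs=10), seed=5)
        two = simulate_cohort(slc_locus, ki_edit,
                              [CohortGroupSpec("a", 3, mean_perfect=0.2),
                               CohortGroupSpec("b", 3, mean_perfect=0.1)],
                              ReadSimConfig(n_read_pairs=10), seed=5)
        assert [s.truth_fractions for s in one] == \
               [s.truth_fractions for s in two[:3]]
        assert [p.fwd_seq for s in one for p in s.pairs] == \
               [p.fwd_seq for s in two[:3] for p in s.pairs]


def test_fastq_roundtrip(tmp_path, slc_locus, ki_edit):
    mix = build_mixture(slc_locus, ki_edit, {"perfect_hdr": 0.5, "wild_type": 0.5},
                        np.random.default_rng(0))
    pairs, _ = simulate_sample(mix, ReadSimConfig(n_read_pairs=30, seed=2))
    write_fastq_pairs(pairs, tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz")
    back = read_fastq_pairs(tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz")
    assert [(p.id, p.fwd_seq, p.rev_seq) for p in pairs] == \
           [(p.id, p.fwd_seq, p.rev_seq) for p in back]
    assert all((p.fwd_quals == q.fwd_quals).all() and (p.rev_quals == q.rev_quals).all()
               for p, q in zip(pairs, back))
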