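"""Synthetic template and read generation."""

import pytest
from scipy import stats

from plasmidcheck import (
    ErrorModel,
    MutationSpec,
    apply_mutations,
    design_mutations,
    make_reference,
    non_homopolymer_sites,
    reverse_complement,
    simulate_mixture,
    simulate_reads,
)
from plasmidcheck.simulate import find_homopolymer_runs, mixture_counts, simulate_junk_reads

from conftest import as_read


class TestMakeReference:
    def test_embedded_run_exact_length(self):
        t = make_reference(3000, seed=4, homopolymer_runs=[(1500, "A", 17)])
        assert t.sequence[1500:1517] == "A" * 17
        assert t.sequence[1499] != "A" and t.sequence[1517] != "A"

    def test_run_of_18(self):
        t = make_reference(3000, seed=4, homopolymer_runs=[(1000, "G", 18)])
        assert (1000, "G", 18) in find_homopolymer_runs(t.sequence, 18)

    def test_deterministic(self):
        a = make_reference(500, seed=9)
        b = make_reference(500, seed=9)
        assert a.sequence == b.sequence
        assert a.sequence != make_reference(500, seed=10).sequence

    def test_overlapping_runs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_reference(1000, seed=1, homopolymer_runs=[(100, "A", 10), (105, "C", 5)])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_reference(50, seed=1)


class TestApplyMutations:
    def test_snv(self):
        from plasmidcheck import TemplateSequence

        t = TemplateSequence(name="t", sequence="AAGT")
        out = apply_mutations(t, [MutationSpec("SNV", 3, "G", "C")])
        assert out.sequence == "AACT"

    def test_deletion_and_insertion(self):
        from plasmidcheck import TemplateSequence

        t = TemplateSequence(name="t", sequence="AAGT")
        out = apply_mutations(
            t,
            [
                MutationSpec("deletion", 2, ref_base="A"),
                MutationSpec("insertion", 4, alt_base="T"),
            ],
        )
        assert out.sequence == "AGTT"

    def test_ref_base_mismatch_rejected(self):
        from plasmidcheck import TemplateSequence

        t = TemplateSequence(name="t", sequence="AAGT")
        with pytest.raises(ValueError, match="position 3"):
            apply_mutations(t, [MutationSpec("SNV", 3, "T", "C")])

    def test_nine_mutations_nine_alignment_columns(self, template_1k):
        """3 SNVs + 3 insertions + 3 deletions: length unchanged and exactly
        nine differing alignment columns, checked by the pairwise aligner."""
        from plasmidcheck import align_read
        from plasmidcheck.align import OP_MATCH

        kinds = ["SNV", "insertion", "deletion"] * 3
        muts = design_mutations(template_1k, kinds)
        var = apply_mutations(template_1k, muts)
        assert var.length == template_1k.length
        aln = align_read(as_read(var.sequence), template_1k)
        assert int((aln.ops != OP_MATCH).sum()) == 9


class TestSimulateReads:
    def test_zero_error_forward_reads_equal_template(self, template_600):
        reads = simulate_reads(template_600, 10, None, fraction_reverse=0.0, seed=1)
        assert all(r.sequence == template_600.sequence for r in reads)

    def test_zero_error_reverse_reads_invert(self, template_600):
        reads = simulate_reads(template_600, 10, None, fraction_reverse=1.0, seed=1)
        assert all(
            reverse_complement(r.sequence) == template_600.sequence for r in reads
        )

    def test_deterministic_given_seed(self, template_600):
        a = simulate_reads(template_600, 20, ErrorModel.duplex(), seed=5)
        b = simulate_reads(template_600, 20, ErrorModel.duplex(), seed=5)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_orientation_counts_exact(self, template_600):
        reads = simulate_reads(template_600, 101, None, fraction_reverse=0.25, seed=2)
        n_rev = sum(1 for r in reads if r.read_id.endswith("/rev"))
        assert n_rev == 25

    def test_strand_bias_binomial(self):
        """A reverse-strand-only miscall site is hit at the configured
        probability in reverse reads (binomial 99% interval) and never in
        forward reads."""
        t = make_reference(200, seed=3)
        pos, prob = 100, 0.9
        wrong = next(b for b in "ACGT" if b != t.sequence[pos - 1])
        model = ErrorModel(strand_bias_sites=[(pos, "reverse", wrong, prob)])
        n = 3000
        rev = simulate_reads(t, n, model, fraction_reverse=1.0, seed=8)
        hits = sum(
            1
            for r in rev
            if reverse_complement(r.sequence)[pos - 1] == wrong
        )
        lo, hi = stats.binom.interval(0.99, n, prob)
        assert lo <= hits <= hi
        fwd = simulate_reads(t, 200, model, fraction_reverse=0.0, seed=9)
        assert all(r.sequence[pos - 1] == t.sequence[pos - 1] for r in fwd)

    def test_realized_substitution_rate(self):
        """Law of large numbers: realized substitution rate converges to the
        configured rate over >= 1e6 simulated bases (10% tolerance)."""
        t = make_reference(1000, seed=6)
        rate = 0.01
        reads = simulate_reads(
            t, 1100, ErrorModel(substitution_rate=rate), fraction_reverse=0.0, seed=7
        )
        mismatches = sum(
            sum(a != b for a, b in zip(r.sequence, t.sequence)) for r in reads
        )
        realized = mismatches / (1100 * 1000)
        assert abs(realized - rate) / rate < 0.10

    def test_undercall_calibration(self):
        """With P(report 17) = 0.173 configured, the observed fraction of
        reads carrying the full 17-mer is ~17.3%."""
        t = make_reference(400, seed=12, homopolymer_runs=[(200, "A", 17)])
        model = ErrorModel(
            homopolymer_undercall={17: {17: 0.173, 16: 0.27, 15: 0.28, 14: 0.277}}
        )
        n = 10_000
        reads = simulate_reads(t, n, model, fraction_reverse=0.0, seed=13)
        full = sum(1 for r in reads if "A" * 17 in r.sequence)
        assert abs(full / n - 0.173) < 0.02

    def test_undercall_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            ErrorModel(homopolymer_undercall={10: {10: 0.5, 9: 0.4}})

    def test_flag_errors_quality_profile(self):
        t = make_reference(300, seed=14)
        model = ErrorModel(
            substitution_rate=0.02, quality_profile="flag_errors"
        )
        reads = simulate_reads(t, 50, model, fraction_reverse=0.0, seed=15)
        for r in reads:
            for base, tbase, q in zip(r.sequence, t.sequence, r.qualities):
                if base != tbase:
                    assert q == model.error_quality


class TestMixture:
    def test_largest_remainder_counts(self):
        assert mixture_counts([0.95, 0.05], 10_000) == [9500, 500]
        assert mixture_counts([1.0], 7) == [7]
        counts = mixture_counts([0.5, 0.5], 11)
        assert sorted(counts) == [5, 6] and sum(counts) == 11

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            mixture_counts([0.6, 0.5], 10)

    def test_counts_conserved_and_provenance(self, template_600):
        var = apply_mutations(
            template_600, [MutationSpec("SNV", 300, template_600.sequence[299],
                                        next(b for b in "ACGT"
                                             if b != template_600.sequence[299]))]
        )
        reads = simulate_mixture([(template_600, 0.8), (var, 0.2)], 50, None, seed=3)
        assert len(reads) == 50
        sources = [r._source for r in reads]
        assert sources.count(template_600.name) == 40
        assert sources.count(var.name) == 10

    def test_single_template(self, template_600):
        reads = simulate_mixture([(template_600, 1.0)], 9, None, seed=1)
        assert len(reads) == 9
        assert all(r._source == template_600.name for r in reads)


def test_non_homopolymer_sites(template_1k):
    sites = non_homopolymer_sites(template_1k, 5)
    s = template_1k.sequence
    for pos in sites:
        i = pos - 1
        assert s[i - 1] != s[i] != s[i + 1]
    assert all(b - a >= 50 for a, b in zip(sites, sites[1:]))


def test_junk_reads_fail_filters(template_600):
    from plasmidcheck import FilterConfig, apply_filters

    junk = simulate_junk_reads(template_600, 9, seed=2)
    kept, counters = apply_filters(junk, FilterConfig(expected_length=600))
    assert kept == []
    assert counters["rejected_quality"] + counters["rejected_length"] == 9
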