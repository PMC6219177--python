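"""Reference generation, read simulation, contig rearrangement, and spiking."""

import numpy as np
import pytest

import svbench as sb
from svbench.spike_sim import SpikePlan, rearrange_contig, revcomp, truth_record


class TestReference:
    def test_deterministic(self):
        a = sb.generate_reference(5000, seed=7)
        b = sb.generate_reference(5000, seed=7)
        assert a == b
        assert a != sb.generate_reference(5000, seed=8)

    def test_gc_content(self):
        seq = sb.generate_reference(100_000, gc=0.5, seed=1)["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.02)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            sb.generate_reference(0)

    def test_fasta_roundtrip(self, tmp_path):
        from pyfaidx import Fasta

        seqs = sb.generate_reference(3000, seed=2)
        path = tmp_path / "ref.fasta"
        sb.write_fasta(seqs, str(path))
        back = Fasta(str(path))
        assert str(back["chr1"][:]) == seqs["chr1"]


class TestSimulateReads:
    def test_pair_count_matches_coverage(self, reference, background_reads):
        glen = len(reference["chr1"])
        expected_pairs = 30.0 * glen / (2 * 100)
        assert len(background_reads.pairs) == pytest.approx(expected_pairs, rel=0.05)
        depth = background_reads.depth("chr1", 5000, 55_000)
        assert depth == pytest.approx(30.0, rel=0.05)

    def test_zero_fragment_sd_gives_constant_fragments(self):
        ref = sb.generate_reference(10_000, seed=3)
        reads = sb.simulate_reads(ref, 5, fragment_sd=0.0, seed=4)
        assert {p.fragment_length for p in reads.pairs} == {300}

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            sb.simulate_reads(sb.generate_reference(5000, seed=0), 0)

    def test_sam_byte_identical_across_reruns(self, tmp_path):
        ref = sb.generate_reference(8000, seed=5)
        paths = []
        for i in range(2):
            reads = sb.simulate_reads(ref, 10, seed=6)
            path = tmp_path / f"run{i}.sam"
            sb.write_sam(reads, str(path))
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_reads_match_reference(self, reference):
        reads = sb.simulate_reads(reference, 2, seed=9)
        seq = reference["chr1"]
        for pair in reads.pairs[:50]:
            assert pair.mate1.seq == seq[pair.mate1.pos - 1: pair.mate1.pos - 1 + 100]
            assert pair.mate2.seq == seq[pair.mate2.pos - 1: pair.mate2.pos - 1 + 100]


class TestRearrange:
    def test_deletion_removes_middle(self):
        plan = SpikePlan("chr1", 1, 16, "DEL", vaf=1.0, fraction=0.5)
        seq, _segments, junctions = rearrange_contig("AAAACCCCGGGGTTTT", plan)
        assert seq == "AAAATTTT"
        assert junctions == [4]

    def test_inversion_is_involution(self):
        contig = sb.generate_reference(400, seed=10)["chr1"]
        plan = SpikePlan("chr1", 1, 400, "INV", vaf=1.0, fraction=0.5)
        once, _s, _j = rearrange_contig(contig, plan)
        twice, _s, _j = rearrange_contig(once, plan)
        assert once != contig
        assert twice == contig

    def test_duplication_adds_span_length(self):
        contig = "AAAACCCCGGGGTTTT"
        plan = SpikePlan("chr1", 1, 16, "DUP", vaf=1.0, fraction=0.5, copies=1)
        seq, _s, _j = rearrange_contig(contig, plan)
        assert len(seq) == 24
        assert seq == "AAAACCCCGGGG" + "CCCCGGGG" + "TTTT"

    def test_insertion_at_midpoint(self):
        plan = SpikePlan("chr1", 1, 16, "INS", vaf=1.0, insert_seq="TTAA")
        seq, _s, junctions = rearrange_contig("A" * 16, plan)
        assert seq == "A" * 8 + "TTAA" + "A" * 8
        assert junctions == [8, 12]

    def test_length_accounting_per_type(self):
        contig = sb.generate_reference(1000, seed=11)["chr1"]
        cases = {
            "DEL": (SpikePlan("chr1", 1, 1000, "DEL", 1.0, fraction=0.4), -400),
            "DUP": (SpikePlan("chr1", 1, 1000, "DUP", 1.0, fraction=0.4), +400),
            "INS": (SpikePlan("chr1", 1, 1000, "INS", 1.0, insert_seq="ACGT" * 25), +100),
            "INV": (SpikePlan("chr1", 1, 1000, "INV", 1.0, fraction=0.4), 0),
        }
        for svtype, (plan, delta) in cases.items():
            seq, _s, _j = rearrange_contig(contig, plan)
            assert len(seq) - len(contig) == delta, svtype

    def test_bad_plans_rejected(self):
        with pytest.raises(ValueError):
            SpikePlan("chr1", 1, 16, "DEL", vaf=1.0, fraction=1.0)
        with pytest.raises(ValueError):
            SpikePlan("chr1", 1, 16, "DEL", vaf=0.0)
        with pytest.raises(ValueError):
            SpikePlan("chr1", 1, 16, "INS", vaf=0.5)  # no insert sequence
        plan = SpikePlan("chr1", 1, 100, "DEL", vaf=0.5)
        with pytest.raises(ValueError, match="span the plan interval"):
            rearrange_contig("ACGT", plan)


class TestSpike:
    def test_cf_formula_inversion(self, reference, background_reads):
        # INV: L_f == L_o so C_f = VAF * C_o
        plan = SpikePlan("chr1", 15_001, 45_000, "INV", vaf=0.2, fraction=0.5)
        tumor, _truth = sb.spike_sv(background_reads, reference, plan, seed=1)
        assert tumor.ledger["c_f"] == pytest.approx(0.2 * 30.0)
        expected_pairs = tumor.ledger["c_f"] * tumor.ledger["l_f"] / 200
        assert tumor.ledger["n_simulated"] == round(expected_pairs)

    def test_read_ledger_balances(self, reference, background_reads):
        plan = SpikePlan("chr1", 15_001, 45_000, "DEL", vaf=0.5, fraction=0.6)
        tumor, _truth = sb.spike_sv(background_reads, reference, plan, seed=2)
        led = tumor.ledger
        assert led["n_input"] - led["n_removed"] + led["n_simulated"] == led["n_output"]
        assert led["n_output"] == len(tumor.pairs)

    def test_truth_breakpoints_exact(self, reference, background_reads):
        plan = SpikePlan("chr1", 15_001, 45_000, "DEL", vaf=1.0, fraction=0.6)
        _tumor, truth = sb.spike_sv(background_reads, reference, plan, seed=3)
        # deleted middle 60% of a 30 kb interval: 18 kb centred in the interval
        assert (truth.pos, truth.end, truth.svtype) == (21_001, 39_000, "DEL")
        assert truth_record(plan, "t").pos == truth.pos

    def test_deletion_depth_scales_with_vaf(self, reference, background_reads):
        plan_full = SpikePlan("chr1", 15_001, 45_000, "DEL", vaf=1.0, fraction=0.6)
        tumor_full, truth = sb.spike_sv(background_reads, reference, plan_full, seed=4)
        assert tumor_full.depth("chr1", truth.pos, truth.end) <= 1.0

        plan_half = SpikePlan("chr1", 15_001, 45_000, "DEL", vaf=0.5, fraction=0.6)
        tumor_half, _ = sb.spike_sv(background_reads, reference, plan_half, seed=5)
        assert tumor_half.depth("chr1", truth.pos, truth.end) == pytest.approx(15.0, rel=0.2)

    def test_depth_outside_plan_interval_unchanged(self, reference, background_reads):
        plan = SpikePlan("chr1", 15_001, 45_000, "DUP", vaf=0.5, fraction=0.5)
        tumor, _truth = sb.spike_sv(background_reads, reference, plan, seed=6)
        for lo, hi in ((1, 14_000), (46_000, 60_000)):
            assert tumor.depth("chr1", lo, hi) == background_reads.depth("chr1", lo, hi)

    def test_duplication_gains_and_inversion_preserves_depth(self, reference, background_reads):
        dup = SpikePlan("chr1", 15_001, 45_000, "DUP", vaf=0.5, fraction=0.5)
        tumor, truth = sb.spike_sv(background_reads, reference, dup, seed=7)
        assert tumor.ledger["n_output"] > len(background_reads.pairs)
        assert tumor.depth("chr1", truth.pos, truth.end) > 1.1 * 30.0

        inv = SpikePlan("chr1", 15_001, 45_000, "INV", vaf=0.5, fraction=0.5)
        tumor_inv, truth_inv = sb.spike_sv(background_reads, reference, inv, seed=8)
        depth = tumor_inv.depth("chr1", truth_inv.pos, truth_inv.end)
        assert depth == pytest.approx(30.0, rel=0.1)

    def test_junction_spanning_reads_are_softclipped(self, reference, background_reads):
        plan = SpikePlan("chr1", 15_001, 45_000, "DEL", vaf=1.0, fraction=0.6)
        tumor, truth = sb.spike_sv(background_reads, reference, plan, seed=9)
        clipped = [p for p in tumor.pairs if p.origin == "variant"
                   and ("S" in p.mate1.cigar or "S" in p.mate2.cigar)]
        assert clipped, "expected soft-clipped junction reads"
        # a clipped mate's aligned block must abut a deletion breakpoint
        breakpoints = {truth.pos - 1, truth.pos, truth.end, truth.end + 1}
        touching = 0
        for pair in clipped:
            for mate in (pair.mate1, pair.mate2):
                if mate.pos is None or "S" not in mate.cigar:
                    continue
                from svbench.spike_sim import _cigar_aligned_length

                span = {mate.pos - 1, mate.pos, mate.pos + _cigar_aligned_length(mate.cigar) - 1,
                        mate.pos + _cigar_aligned_length(mate.cigar)}
                if span & breakpoints:
                    touching += 1
        assert touching > 0

    def test_inverted_segment_reads_flip_strand_and_sequence(self, reference, background_reads):
        plan = SpikePlan("chr1", 15_001, 45_000, "INV", vaf=1.0, fraction=0.5)
        tumor, truth = sb.spike_sv(background_reads, reference, plan, seed=10)
        seq = reference["chr1"]
        checked = 0
        for pair in tumor.pairs:
            if pair.origin != "variant":
                continue
            for mate in (pair.mate1, pair.mate2):
                if mate.pos is None or mate.cigar != "100M":
                    continue
                if truth.pos <= mate.pos and mate.pos + 99 <= truth.end:
                    assert mate.seq == seq[mate.pos - 1: mate.pos + 99]
                    checked += 1
        assert checked > 10  # fully-inverted-span reads must match the reference forward strand

    def test_overlapping_spikes_rejected(self, reference, background_reads):
        plan_a = SpikePlan("chr1", 15_001, 45_000, "DEL", vaf=0.5, fraction=0.5)
        tumor, _ = sb.spike_sv(background_reads, reference, plan_a, seed=11)
        plan_b = SpikePlan("chr1", 44_000, 59_000, "INV", vaf=0.5, fraction=0.5)
        with pytest.raises(ValueError, match="overlaps a prior spike"):
            sb.spike_sv(tumor, reference, plan_b, seed=12)

    def test_interval_must_exceed_twice_fragment_mean(self, reference, background_reads):
        plan = SpikePlan("chr1", 15_001, 15_500, "DEL", vaf=0.5, fraction=0.5)
        with pytest.raises(ValueError, match="twice"):
            sb.spike_sv(background_reads, reference, plan, seed=13)


class TestPerturb:
    def test_noise_free_submission_is_perfect(self, truth_500):
        calls = sb.perturb_callset(truth_500, jitter_sd=0, fn_rate=0, fp_count=0, seed=1)
        rep = sb.score(sb.match_calls(calls, truth_500))
        assert rep.precision == rep.recall == rep.f_score == 1.0

    def test_full_dropout_scores_zero(self, truth_500):
        calls = sb.perturb_callset(truth_500, fn_rate=1.0, seed=2)
        assert calls == []
        rep = sb.score(sb.match_calls(calls, truth_500))
        assert (rep.precision, rep.recall, rep.f_score) == (0.0, 0.0, 0.0)

    def test_fp_calls_avoid_truth_regions(self, truth_500):
        calls = sb.perturb_callset(truth_500, fn_rate=1.0, fp_count=40, seed=3,
                                   contigs={"chr1": 10_000_000})
        truth_ivals = [(t.pos, t.end) for t in truth_500]
        for call in calls:
            assert not any(call.pos <= e and call.end >= s for s, e in truth_ivals)

    def test_invalid_rates_rejected(self, truth_500):
        with pytest.raises(ValueError):
            sb.perturb_callset(truth_500, fn_rate=1.5)


class TestPlanFile:
    def test_plan_file_parsing(self, tmp_path):
        path = tmp_path / "plans.txt"
        path.write_text(
            "# chrom start end type vaf param\n"
            "chr1 1000 9000 DEL 0.5 0.6\n"
            "chr1 20000 28000 DUP 0.33 2\n"
            "chr1 40000 48000 INS 0.2 ACGTACGT\n"
            "chr1 50000 58000 INV 1.0\n"
        )
        plans = sb.spike_sim.read_plan_file(str(path))
        assert [p.svtype for p in plans] == ["DEL", "DUP", "INS", "INV"]
        assert plans[0].fraction == 0.6
        assert plans[1].copies == 2
        assert plans[2].insert_seq == "ACGTACGT"
        assert plans[3].vaf == 1.0

    def test_spike_all_rejects_overlapping_plans(self, reference, background_reads):
        plans = [
            SpikePlan("chr1", 1_000, 10_000, "DEL", 0.5),
            SpikePlan("chr1", 9_000, 20_000, "INV", 0.5),
        ]
        with pytest.raises(ValueError, match="overlap"):
            sb.spike_all(background_reads, reference, plans)


def test_revcomp():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AACG") == "CGTT"
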