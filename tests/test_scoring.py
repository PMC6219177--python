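"""Similarity schemes, optimal matching, and precision/recall/F reports."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import svbench as sb
from svbench import breakpoint_closeness, jaccard_similarity, match_calls, score

from conftest import make_sv


def brute_force_best_total(called, known, f):
    """Independent oracle: enumerate every injective assignment on qualifying edges."""
    edges = {}
    for i, c in enumerate(called):
        for j, k in enumerate(known):
            sim, partial = breakpoint_closeness(c, k, f)
            if sim > 0 and not partial:
                edges[(i, j)] = sim
    best = 0.0
    for r in range(min(len(called), len(known)) + 1):
        for rows in itertools.combinations(range(len(called)), r):
            for cols in itertools.permutations(range(len(known)), r):
                pairing = list(zip(rows, cols))
                if all(p in edges for p in pairing):
                    best = max(best, sum(edges[p] for p in pairing))
    return best


def random_instance(rng, max_n=6):
    def records(prefix, n):
        out = []
        for i in range(n):
            pos = int(rng.integers(1, 2000))
            end = pos + int(rng.integers(0, 400))
            out.append(make_sv(f"{prefix}{i}", pos, end,
                               svtype=str(rng.choice(["DEL", "DUP", "INV"]))))
        return out

    return records("c", int(rng.integers(1, max_n + 1))), records("k", int(rng.integers(1, max_n + 1)))


class TestJaccard:
    def test_identical_regions(self):
        assert jaccard_similarity(("chr1", 100, 200), ("chr1", 100, 200)) == 1.0

    def test_partial_overlap_matches_base_counting(self):
        # brute-force oracle: count shared/total bases explicitly
        a, b = set(range(100, 201)), set(range(150, 251))
        expected = len(a & b) / len(a | b)
        assert jaccard_similarity(("chr1", 100, 200), ("chr1", 150, 250)) == pytest.approx(expected)
        assert expected == pytest.approx(51 / 151)

    def test_disjoint_and_cross_chromosome(self):
        assert jaccard_similarity(("chr1", 100, 200), ("chr1", 300, 400)) == 0.0
        assert jaccard_similarity(("chr1", 100, 200), ("chr2", 100, 200)) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 5000), st.integers(0, 500), st.integers(1, 5000), st.integers(0, 500))
    def test_symmetric_and_bounded(self, p1, s1, p2, s2):
        a, b = ("chr1", p1, p1 + s1), ("chr1", p2, p2 + s2)
        j1, j2 = jaccard_similarity(a, b), jaccard_similarity(b, a)
        assert j1 == j2
        assert 0.0 <= j1 <= 1.0


class TestCloseness:
    def test_exact_breakpoints(self):
        a = make_sv("a", 1000, 2000)
        assert breakpoint_closeness(a, a, 100) == (1.0, False)

    def test_geometric_mean(self):
        a = make_sv("a", 1000, 2000)
        b = make_sv("b", 1020, 2080)
        c, partial = breakpoint_closeness(a, b, 100)
        assert c == pytest.approx(np.sqrt(0.8 * 0.2)) == pytest.approx(0.4)
        assert not partial

    def test_partial_when_one_breakpoint_outside(self):
        a = make_sv("a", 1000, 2000)
        b = make_sv("b", 1030, 2150)
        assert breakpoint_closeness(a, b, 100) == (0.0, True)

    def test_neither_breakpoint_close(self):
        a = make_sv("a", 1000, 2000)
        b = make_sv("b", 1500, 2500)
        assert breakpoint_closeness(a, b, 100) == (0.0, False)

    def test_single_breakpoint_uses_start_only(self):
        ins_a = make_sv("a", 1000, 1000, svtype="INS")
        ins_b = make_sv("b", 1025, 1025, svtype="INS")
        assert breakpoint_closeness(ins_a, ins_b, 100) == (0.75, False)

    def test_invalid_flank(self):
        a = make_sv("a", 1000, 2000)
        with pytest.raises(ValueError):
            breakpoint_closeness(a, a, 0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 3000), st.integers(0, 400), st.integers(1, 3000), st.integers(0, 400))
    def test_symmetric_bounded_and_one_iff_exact(self, p1, s1, p2, s2):
        a, b = make_sv("a", p1, p1 + s1), make_sv("b", p2, p2 + s2)
        ca, cb = breakpoint_closeness(a, b, 100), breakpoint_closeness(b, a, 100)
        assert ca == cb
        assert 0.0 <= ca[0] <= 1.0
        if a.is_single_breakpoint or b.is_single_breakpoint:
            # single-breakpoint comparisons use the start breakpoint only
            assert (ca[0] == 1.0) == (a.pos == b.pos)
        else:
            assert (ca[0] == 1.0) == (a.pos == b.pos and a.end == b.end)


class TestMatching:
    def test_identity_all_tp(self, truth_60):
        calls = [make_sv(f"c{i}", r.pos, r.end, chrom=r.chrom, svtype=r.svtype)
                 for i, r in enumerate(truth_60)]
        rep = score(match_calls(calls, truth_60))
        assert (rep.n_tp, rep.n_fp, rep.n_fn) == (len(truth_60), 0, 0)
        assert rep.precision == rep.recall == rep.f_score == 1.0

    def test_optimal_reassignment_beats_greedy_pairing(self):
        # A is closest to X, but the best TOTAL pairing is {A-X, B-Y}: verify
        # the one-to-one matching maximizes the summed similarity.
        called = [make_sv("A", 100, 100, svtype="INS"), make_sv("B", 130, 130, svtype="INS")]
        known = [make_sv("X", 110, 110, svtype="INS"), make_sv("Y", 150, 150, svtype="INS")]
        match = match_calls(called, known, f=100)
        assert match.total_similarity == pytest.approx(brute_force_best_total(called, known, 100))
        assert {(c, k) for c, k, _s in match.pairs} == {("A", "X"), ("B", "Y")}

    def test_matching_total_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            called, known = random_instance(rng)
            match = match_calls(called, known, f=100)
            assert match.total_similarity == pytest.approx(
                brute_force_best_total(called, known, 100), abs=1e-9)

    def test_outcompeted_call_is_partial_not_fp(self):
        known = [make_sv("K", 1000, 2000)]
        close = make_sv("C1", 1001, 2001)
        farther = make_sv("C2", 1050, 2050)
        match = match_calls([close, farther], known, f=100)
        assert match.called_status == {"C1": "TP", "C2": "partial"}
        rep = score(match)
        assert (rep.n_tp, rep.n_fp, rep.n_partial) == (1, 0, 1)

    def test_one_sided_similarity_is_partial_both_ways(self):
        known = [make_sv("K", 1000, 2000)]
        calls = [make_sv("C", 1030, 2150)]  # only the start breakpoint is close
        match = match_calls(calls, known, f=100)
        assert match.called_status["C"] == "partial"
        assert match.known_status["K"] == "partial"
        rep = score(match)
        assert (rep.n_tp, rep.n_fp, rep.n_fn) == (0, 0, 0)

    def test_duplicate_ids_rejected(self):
        recs = [make_sv("same", 100, 200), make_sv("same", 300, 400)]
        with pytest.raises(ValueError, match="duplicate"):
            match_calls(recs, [make_sv("k", 100, 200)])

    def test_injective_and_tp_counts_agree(self, truth_60):
        calls = sb.perturb_callset(truth_60, jitter_sd=20, fn_rate=0.3, fp_count=20, seed=5)
        match = match_calls(calls, truth_60, f=100)
        called_ids = [c for c, _k, _s in match.pairs]
        known_ids = [k for _c, k, _s in match.pairs]
        assert len(called_ids) == len(set(called_ids))
        assert len(known_ids) == len(set(known_ids))
        n_tp_called = sum(1 for s in match.called_status.values() if s == "TP")
        n_tp_known = sum(1 for s in match.known_status.values() if s == "TP")
        assert n_tp_called == n_tp_known == len(match.pairs)

    def test_flank_monotonicity_on_perturbed_calls(self, truth_60):
        calls = sb.perturb_callset(truth_60, jitter_sd=15, fn_rate=0.1, fp_count=10, seed=8)
        reps = {f: score(match_calls(calls, truth_60, f=f)) for f in (10, 50, 100, 400)}
        recalls = [reps[f].recall for f in (10, 50, 100, 400)]
        assert recalls == sorted(recalls)
        assert reps[10].n_tp <= reps[100].n_tp

    def test_overlap_scheme_matches_positive_jaccard(self):
        known = [make_sv("K", 1000, 2000)]
        overlapping = make_sv("C1", 1900, 2500)
        disjoint = make_sv("C2", 5000, 5500)
        match = match_calls([overlapping, disjoint], known, scheme="overlap")
        assert match.called_status == {"C1": "TP", "C2": "FP"}

    def test_overlap_scheme_warns_on_single_breakpoint(self):
        with pytest.warns(UserWarning, match="1-bp regions"):
            match_calls([make_sv("C", 100, 100, svtype="INS")],
                        [make_sv("K", 100, 200)], scheme="overlap")

    def test_type_preference_breaks_exact_ties(self):
        # two calls equidistant from two knowns; types should decide
        called = [make_sv("C1", 100, 200, svtype="DEL"), make_sv("C2", 100, 200, svtype="DUP")]
        known = [make_sv("K1", 110, 210, svtype="DUP"), make_sv("K2", 110, 210, svtype="DEL")]
        match = match_calls(called, known, f=100)
        assert {(c, k) for c, k, _ in match.pairs} == {("C1", "K2"), ("C2", "K1")}


class TestMatedBreakpoints:
    def _bnd_pair(self, prefix, chrom_a, pos_a, chrom_b, pos_b):
        a = sb.SVRecord(id=f"{prefix}1", chrom=chrom_a, pos=pos_a, end=pos_a,
                        svtype="BND", mate_id=f"{prefix}2")
        b = sb.SVRecord(id=f"{prefix}2", chrom=chrom_b, pos=pos_b, end=pos_b,
                        svtype="BND", mate_id=f"{prefix}1")
        return [a, b]

    def test_fp_mate_upgraded_to_partial_and_pair_counts_once(self):
        known = self._bnd_pair("K", "chr1", 1000, "chr2", 5000)
        calls = self._bnd_pair("C", "chr1", 1010, "chr2", 9999)  # one mate matches
        match = match_calls(calls, known, f=100)
        assert match.called_status["C1"] == "TP"
        assert match.called_status["C2"] == "partial"  # FP replaced by partial
        rep = score(match)
        assert rep.n_tp == 1  # the mate pair counts as a single SV
        assert rep.n_fp == 0


class TestScoreReport:
    def test_counts_to_ratios(self):
        rep = sb.ScoreReport.from_counts(8, 2, 2)
        assert (rep.precision, rep.recall) == (0.8, 0.8)
        assert rep.f_score == pytest.approx(0.8)

    def test_degenerate_denominators_are_zero(self):
        rep = sb.ScoreReport.from_counts(0, 0, 5)
        assert (rep.precision, rep.recall, rep.f_score) == (0.0, 0.0, 0.0)

    def test_scoped_scoring_with_masks(self, truth_60):
        masks = sb.random_masks({"chr1": 10_000_000}, fraction=0.3, region_len=100_000, seed=3)
        truth = sb.assign_train_test(truth_60, masks)
        calls = sb.perturb_callset(truth, jitter_sd=5, fn_rate=0.2, fp_count=15, seed=4)
        match = match_calls(calls, truth, f=100, masks=masks)
        rep_all = score(match, "all")
        rep_train, rep_test = score(match, "train"), score(match, "test")
        assert rep_train.n_tp + rep_test.n_tp == rep_all.n_tp
        assert rep_train.n_fn + rep_test.n_fn == rep_all.n_fn
        assert rep_train.n_fp + rep_test.n_fp == rep_all.n_fp

    def test_truth_scored_against_itself_both_schemes(self, truth_60):
        for scheme in ("closeness", "overlap"):
            rep = score(match_calls(list(truth_60), truth_60, scheme=scheme))
            assert rep.precision == rep.recall == rep.f_score == 1.0
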