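import numpy as np
import pytest

from splicescan.align import (
    AlignParams,
    SpliceScores,
    junction_set,
    spliced_align,
)

from .oracles import (
    gotoh_glocal_score,
    one_intron_best_score,
    random_one_intron_instance,
)

BASES = list("ACGT")


def _rand_seq(rng, lo, hi):
    return "".join(rng.choice(BASES, rng.integers(lo, hi + 1)))


def rescore_from_traceback(ref, query, aln, params, d_pen, a_pen):
    """Independent re-scoring of a traceback: walk the CIGAR and sum the
    per-column contributions (substitutions, affine gaps, intron costs)."""
    i, j = aln.ref_start, 0
    total = 0.0
    for op, n in aln.cigar:
        if op == "M":
            for _ in range(n):
                same = ref[i] == query[j] and ref[i] != "N" and query[j] != "N"
                total += params.match if same else params.mismatch
                i += 1
                j += 1
        elif op == "D":
            total += -params.gap_open - n * params.gap_extend
            i += n
        elif op == "I":
            total += -params.gap_open - n * params.gap_extend
            j += n
        elif op == "N":
            total += -params.intron_open - d_pen[i] - a_pen[i + n]
            i += n
    assert i == aln.ref_end and j == len(query)
    return total


class TestDegenerateCases:
    def test_identical_sequences_all_match(self):
        ref = "ACGTACGTGGTTACA"
        aln = spliced_align(ref, ref)
        assert aln.cigar == [("M", len(ref))]
        assert aln.score == len(ref) * 1.0
        assert aln.introns == [] and aln.identity == 1.0

    def test_query_contained_in_reference(self):
        ref = "TTTTTACGTACGTTTTTT"
        aln = spliced_align(ref, "ACGTACG")
        assert aln.score == 7.0
        assert (aln.ref_start, aln.ref_end) == (5, 12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="longer"):
            spliced_align("ACG", "ACGT")
        with pytest.raises(ValueError, match="all-N"):
            spliced_align("ACGTACGT", "NNN")
        with pytest.raises(ValueError):
            spliced_align("ACGU", "ACG")

    def test_n_bases_score_as_mismatch(self):
        aln = spliced_align("ACNTA", "ACNTA")
        assert aln.score == 4 * 1.0 - 2.0
        assert aln.matches == 4


class TestGotohEquivalence:
    def test_reduces_to_affine_alignment_without_introns(self):
        """With no usable intron state the DP must equal an independent
        Gotoh implementation on 500 random small instances."""
        rng = np.random.default_rng(11)
        params = AlignParams()  # unscored boundaries forbidden -> no introns
        for _ in range(500):
            ref = _rand_seq(rng, 4, 15)
            query = _rand_seq(rng, 1, min(8, len(ref)))
            got = spliced_align(ref, query, params).score
            want = gotoh_glocal_score(ref, query)
            assert got == pytest.approx(want), (ref, query)

    def test_huge_intron_open_also_disables_introns(self):
        rng = np.random.default_rng(12)
        params = AlignParams(intron_open=1e9, allow_unscored=True,
                             noncanonical_extra=0.0)
        for _ in range(50):
            ref = _rand_seq(rng, 8, 15)
            query = _rand_seq(rng, 2, 8)
            got = spliced_align(ref, query, params).score
            assert got == pytest.approx(gotoh_glocal_score(ref, query))


class TestOneIntronOracle:
    def test_matches_exhaustive_enumeration(self):
        """200 seeded instances with one scored donor/acceptor pair: the
        DP score equals enumeration over every intron placement and query
        split scored with independent Gotoh pieces."""
        rng = np.random.default_rng(21)
        params = AlignParams(min_intron=4, intron_open=3.0)
        n_with_intron = 0
        for _ in range(200):
            ref, query, d, a, ds, as_ = random_one_intron_instance(rng)
            scores = SpliceScores(donor={d: ds}, acceptor={a: as_})
            aln = spliced_align(ref, query, params, scores)
            want = one_intron_best_score(
                ref, query,
                donor_pen={d: params.site_penalty(ds)},
                acceptor_pen={a: params.site_penalty(as_)},
                q=params.gap_open, e=params.gap_extend,
                q_tilde=params.intron_open, min_intron=params.min_intron,
            )
            assert aln.score == pytest.approx(want), (ref, query, d, a)
            n_with_intron += bool(aln.introns)
        assert n_with_intron > 30  # the intron state is genuinely exercised

    def test_traceback_rescoring_additivity(self):
        rng = np.random.default_rng(31)
        params = AlignParams(min_intron=4, intron_open=3.0)
        for _ in range(100):
            ref = _rand_seq(rng, 10, 15)
            n = len(ref)
            d = int(rng.integers(0, n - 4))
            a = int(rng.integers(d + 4, n + 1))
            query = (ref[:d] + ref[a:])[:8] or ref[:3]
            scores = SpliceScores(donor={d: 12.0}, acceptor={a: 12.0})
            d_pen = {i: params.site_penalty(scores.donor.get(i)) for i in range(n + 1)}
            a_pen = {i: params.site_penalty(scores.acceptor.get(i)) for i in range(n + 1)}
            aln = spliced_align(ref, query, params, scores)
            assert aln.score == pytest.approx(
                rescore_from_traceback(ref, query, aln, params, d_pen, a_pen)
            )
            assert junction_set(aln) == set(aln.introns)


def _three_way_ambiguous_instance():
    """A junction whose placement is sequence-ambiguous across 3 shifts.

    ref[d] == ref[a] and ref[d+1] == ref[a+1] make shifts 0, 1 and 2 give
    the same spliced sequence; only shift 1 carries GT..AG."""
    prefix = "TTACCTCACC"  # ends C != A so shift -1 is not equivalent
    d = len(prefix)
    intron_core = "GGT" + "CCTTCCAATCGGTTAACCTT" + "A"  # ref[d..a-1]
    exon2 = "GGCAATTCCGG"  # ref[a] = G, ref[a+1] = G, ref[a+2] = C != T
    ref = prefix + intron_core + exon2
    a = d + len(intron_core)
    query = prefix + exon2
    assert ref[d] == ref[a] and ref[d + 1] == ref[a + 1]
    assert ref[d + 2] != ref[a + 2] and ref[d - 1] != ref[a - 1]
    assert ref[d + 1 : d + 3] == "GT" and ref[a - 1 : a + 1] == "AG"
    return ref, query, d, a


class TestJunctionAmbiguity:
    def test_without_splice_scores_three_placements_tie(self):
        ref, query, d, a = _three_way_ambiguous_instance()
        params = AlignParams(allow_unscored=True, noncanonical_extra=0.0,
                             intron_open=6.0, penalty_base=2.0)
        aln = spliced_align(ref, query, params)
        # hand score: every shift splices perfectly at the same cost
        expected = (
            len(query) * params.match
            - params.intron_open
            - 2 * params.penalty_base
        )
        assert aln.score == pytest.approx(expected)
        for shift in (0, 1, 2):  # the spliced sequence is identical per shift
            assert ref[: d + shift] + ref[a + shift :] == query

    def test_splice_scores_select_the_favored_shift(self):
        ref, query, d, a = _three_way_ambiguous_instance()
        params = AlignParams(allow_unscored=True, noncanonical_extra=0.0,
                             intron_open=6.0, penalty_base=2.0)
        scores = SpliceScores(donor={d + 1: 12.0}, acceptor={a + 1: 12.0})
        aln = spliced_align(ref, query, params, scores)
        assert aln.introns == [(d + 1, a + 1)]
        assert aln.score == pytest.approx(len(query) * 1.0 - params.intron_open)

    @pytest.mark.parametrize("s,expect_favored", [(-5.0, False), (-1.0, False),
                                                  (1.0, True), (5.0, True)])
    def test_monotone_flip_at_computable_threshold(self, s, expect_favored):
        """Raising the donor/acceptor score above the unscored cost (score 0
        at penalty_base) flips the choice to the scored placement."""
        ref, query, d, a = _three_way_ambiguous_instance()
        params = AlignParams(allow_unscored=True, noncanonical_extra=0.0,
                             intron_open=6.0, penalty_base=2.0)
        scores = SpliceScores(donor={d + 1: s}, acceptor={a + 1: s})
        aln = spliced_align(ref, query, params, scores)
        assert ((d + 1, a + 1) in aln.introns) == expect_favored


class TestJunctionSet:
    def test_intron_free_alignment(self):
        aln = spliced_align("ACGTACGTAC", "ACGTACGTAC")
        assert junction_set(aln) == set()

    def test_single_intron_interval(self):
        exon1, exon2 = "ACGTACGTAC" * 3, "TTGGCCAATT" * 3
        ref = exon1 + "GT" + "A" * 96 + "AG" + exon2
        query = exon1 + exon2
        scores = SpliceScores(donor={30: 12.0}, acceptor={130: 12.0})
        aln = spliced_align(ref, query, AlignParams(), scores)
        assert junction_set(aln) == {(30, 130)} == set(aln.introns)
        assert [op for op, _ in aln.cigar] == ["M", "N", "M"]
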