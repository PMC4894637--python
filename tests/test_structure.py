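"""Folding, hairpin calling and star-arm geometry."""

import numpy as np
import pytest

from mircall.mapping import PlacementSet, ReadPlacement
from mircall.seqio import Strain, revcomp
from mircall.structure import (
    assess_hairpin,
    call_hairpin,
    detect_star_reads,
    fold_nussinov,
    predict_star,
)
from mircall.synthetic_data import _mutate, _random_seq

from tests.conftest import enumerate_max_pairs, random_dna

MATURE = "CCAATTTTTATCAAGGAAAGC"  # a known 21-nt mature miRNA (DNA alphabet)


def _hairpin_context(mature, loop="GAAA", flank5="AAACCCAAAG", flank3="CAAAGGGAAA"):
    ctx = flank5 + mature + loop + revcomp(mature) + flank3
    span = (len(flank5), len(flank5) + len(mature))
    return ctx, span


class TestFoldNussinov:
    def test_no_complementary_bases_folds_open(self):
        result = fold_nussinov("AAAAAA")
        assert result.score == 0 and result.dotbracket == "......"

    def test_simple_stem_matches_enumeration(self):
        result = fold_nussinov("GGGGAAAACCCC", min_loop=3)
        assert result.score == enumerate_max_pairs("GGGGAAAACCCC") == 4
        assert result.dotbracket == "((((....))))"

    def test_perfect_complement_construct_pairs_all_mature_bases(self):
        ctx = MATURE + "GAAA" + revcomp(MATURE)
        result = fold_nussinov(ctx)
        assert result.score == len(MATURE)
        partner = result.partner_table()
        assert all(partner[i] is not None for i in range(len(MATURE)))

    def test_score_equals_exhaustive_enumeration_on_random_set(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            seq = random_dna(rng, int(rng.integers(5, 16)), gc=float(rng.uniform(0.2, 0.8)))
            assert fold_nussinov(seq).score == enumerate_max_pairs(seq)

    def test_score_invariant_under_reversal(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            seq = random_dna(rng, int(rng.integers(8, 40)))
            assert fold_nussinov(seq).score == fold_nussinov(seq[::-1]).score

    def test_prefer_span_never_changes_score(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            seq = random_dna(rng, 80, gc=0.25)
            plain = fold_nussinov(seq).score
            preferred = fold_nussinov(seq, prefer_span=(30, 51)).score
            assert plain == preferred

    def test_pairs_are_nested_and_valid(self):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 120, gc=0.3)
        result = fold_nussinov(seq, prefer_span=(40, 61))
        pairs = sorted(result.pairs)
        valid = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
        seen = set()
        for i, j in pairs:
            assert j - i > 3
            assert (result.sequence[i], result.sequence[j]) in valid
            assert i not in seen and j not in seen
            seen |= {i, j}
        for (i, j) in pairs:
            for (k, l) in pairs:
                if i < k < j:
                    assert l < j  # no pseudoknots

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fold_nussinov("")


class TestCallHairpin:
    def test_perfect_constructed_hairpin(self):
        ctx, span = _hairpin_context(MATURE)
        fold = fold_nussinov(ctx, prefer_span=span)
        call = call_hairpin(fold, span)
        assert call.is_hairpin
        assert call.paired_fraction_of_mature == 1.0
        assert call.loop_length == 4
        assert call.mature_is_5p is True

    def test_mature_without_any_complement_fails(self):
        # a poly-A mature in a U/T-free context cannot pair at all
        ctx = "GACCAGGACCGACG" + "A" * 21 + "CAGGCGACCGGACC"
        fold = fold_nussinov(ctx)
        call = call_hairpin(fold, (14, 35))
        assert not call.is_hairpin
        assert call.paired_fraction_of_mature == 0.0

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            ctx = random_dna(rng, 100, gc=0.25)
            fold = fold_nussinov(ctx, prefer_span=(40, 61))
            calls = [
                call_hairpin(fold, (40, 61), theta_pair=t).is_hairpin
                for t in (0.2, 0.4, 0.6, 0.8, 1.0)
            ]
            # raising theta never turns a non-hairpin into a hairpin
            assert calls == sorted(calls, reverse=True)

    def test_span_outside_context_is_error(self):
        fold = fold_nussinov("ACGUACGUACGU")
        with pytest.raises(ValueError):
            call_hairpin(fold, (5, 30))


class TestAssessHairpin:
    def test_planted_stems_pass_at_defaults(self):
        rng = np.random.default_rng(7)
        passed = 0
        n = 60
        for _ in range(n):
            ml = int(rng.integers(20, 25))
            mature = _random_seq(rng, ml, 0.23)
            arm = _mutate(rng, revcomp(mature), float(rng.uniform(0.85, 1.0)))
            loop = _random_seq(rng, int(rng.integers(4, 16)), 0.23)
            f5 = _random_seq(rng, 60, 0.23)
            f3 = _random_seq(rng, 60, 0.23)
            if rng.random() < 0.5:
                ctx, span = f5 + mature + loop + arm + f3, (60, 60 + ml)
            else:
                ctx = f5 + arm + loop + mature + f3
                span = (60 + len(arm) + len(loop), 60 + len(arm) + len(loop) + ml)
            passed += assess_hairpin(ctx, span)[1].is_hairpin
        assert passed >= 0.9 * n

    def test_shuffled_hairpin_context_mostly_rejected(self):
        # shuffling a genuine hairpin context destroys the stem arrangement
        # while preserving composition; most shuffles must fail the call
        rng = np.random.default_rng(5)
        mature = _random_seq(rng, 21, 0.23)
        arm = _mutate(rng, revcomp(mature), 0.95)
        ctx = (
            _random_seq(rng, 60, 0.23) + mature + _random_seq(rng, 8, 0.23)
            + arm + _random_seq(rng, 60, 0.23)
        )
        span = (60, 81)
        assert assess_hairpin(ctx, span)[1].is_hairpin
        chars = np.array(list(ctx))
        rejected = 0
        for _ in range(100):
            rng.shuffle(chars)
            rejected += not assess_hairpin("".join(chars), span)[1].is_hairpin
        assert rejected >= 70


class TestPredictStar:
    def test_perfect_stem_two_nt_overhangs(self):
        ctx, span = _hairpin_context(MATURE)
        fold = fold_nussinov(ctx, prefer_span=span)
        call = call_hairpin(fold, span)
        star = predict_star(fold, call, overhang=2)
        arm_start = span[1] + 4  # loop length 4
        assert star.star_span == (arm_start + 2, arm_start + 2 + len(MATURE))

    def test_internal_bulge_on_star_side_widens_star(self):
        # manual pair-table trace: a 2-nt insertion in the opposite arm makes
        # the star span 2 nt longer than the mature
        mature = "GCATGCAATCGGATCCGTTAC"
        arm = revcomp(mature)
        ctx = "AAACA" + mature + "CCCC" + arm[:10] + "TT" + arm[10:] + "AAGAA"
        span = (5, 26)
        fold = fold_nussinov(ctx, prefer_span=span)
        call = call_hairpin(fold, span, max_bulge=3)
        star = predict_star(fold, call, overhang=2)
        assert star.star_span[1] - star.star_span[0] == len(mature) + 2

    def test_mature_on_3p_arm_places_star_upstream(self):
        flank5, loop, flank3 = "AAACCCAAAG", "GAAA", "CAAAGGGAAA"
        ctx = flank5 + revcomp(MATURE) + loop + MATURE + flank3
        s = len(flank5) + len(MATURE) + len(loop)
        span = (s, s + len(MATURE))
        fold = fold_nussinov(ctx, prefer_span=span)
        call = call_hairpin(fold, span)
        assert call.mature_is_5p is False
        star = predict_star(fold, call)
        assert star.star_span[1] <= span[0] + 3  # strictly upstream arm

    def test_round_trip_recovers_mature_on_perfect_stem(self):
        ctx, span = _hairpin_context(MATURE)
        fold = fold_nussinov(ctx, prefer_span=span)
        star = predict_star(fold, call_hairpin(fold, span))
        back = predict_star(fold, call_hairpin(fold, star.star_span))
        assert back.star_span == span

    def test_requires_positive_hairpin_call(self):
        fold = fold_nussinov("A" * 30)
        call = call_hairpin(fold, (5, 26))
        with pytest.raises(ValueError):
            predict_star(fold, call)


class TestDetectStarReads:
    def _placements(self, start, end, count=1):
        p = ReadPlacement("A" * (end - start), "chr1", start, end, "+", 1, count)
        return PlacementSet(
            placements={Strain.WT: [p]}, total_aligned={Strain.WT: count}
        )

    def _star(self):
        ctx, span = _hairpin_context(MATURE)
        fold = fold_nussinov(ctx, prefer_span=span)
        return predict_star(fold, call_hairpin(fold, span))

    @pytest.mark.parametrize("shift,expected", [(0, True), (2, True), (3, False)])
    def test_tolerance_boundary(self, shift, expected):
        star = self._star()
        lo, hi = star.star_span
        ps = self._placements(lo + shift, hi + shift)
        out = detect_star_reads(ps, star, "chr1", "+", star.star_span, tolerance=2)
        assert out.supported is expected

    def test_no_nearby_reads_means_unsupported(self):
        star = self._star()
        ps = self._placements(0, 21)
        out = detect_star_reads(ps, star, "chr1", "+", star.star_span)
        assert not out.supported and out.supporting_reads == 0

    def test_supporting_reads_sum_collapsed_counts(self):
        star = self._star()
        ps = self._placements(*star.star_span, count=7)
        out = detect_star_reads(ps, star, "chr1", "+", star.star_span)
        assert out.supported and out.supporting_reads == 7
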