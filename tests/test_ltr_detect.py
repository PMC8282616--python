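"""Seeding, extension, overlap resolution, motif refinement and TSD search."""

import numpy as np
import pytest

from ltrscout.formats_io import GenomeSequence
from ltrscout.ltr_detect import (CandidateElement, DetectionParams,
                                 chain_and_extend, detect_elements, detect_tsd,
                                 find_seed_matches, refine_motif,
                                 resolve_overlaps)

from _oracles import seed_oracle, tsd_oracle

PARAMS = DetectionParams()


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSeeding:
    def test_planted_repeat_on_expected_diagonal(self):
        rng = np.random.default_rng(1)
        R = _random_dna(rng, 200)
        s = R + _random_dna(rng, 1500) + R
        seeds = find_seed_matches(s, PARAMS)
        assert any(sd.diag == 1700 and sd.pos5 <= 0 + 5 and sd.length >= 190
                   for sd in seeds)

    def test_spacer_below_dist_min_gives_no_seeds(self):
        rng = np.random.default_rng(2)
        R = _random_dna(rng, 200)
        s = R + _random_dna(rng, 500) + R
        assert find_seed_matches(s, PARAMS) == []

    def test_too_short_sequence_gives_empty_list(self):
        assert find_seed_matches("ACGT" * 100, PARAMS) == []

    def test_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(3)
        R = _random_dna(rng, 80)
        s = _random_dna(rng, 2000) + R + _random_dna(rng, 1200) + R + _random_dna(rng, 2000)
        params = DetectionParams(dist_min=1000, dist_max=5000)
        got = {(sd.pos5, sd.pos3, sd.length) for sd in find_seed_matches(s, params)}
        want = seed_oracle(s, params.k, params.dist_min, params.dist_max)
        assert got == want

    def test_n_kmers_never_seed(self):
        rng = np.random.default_rng(4)
        R = _random_dna(rng, 100)
        Rn = R[:50] + "N" + R[51:]
        s = R + _random_dna(rng, 1500) + Rn
        seeds = find_seed_matches(s, PARAMS)
        for sd in seeds:
            assert "N" not in s[sd.pos5:sd.pos5 + sd.length]
            assert "N" not in s[sd.pos3:sd.pos3 + sd.length]


def _substitute(seq, positions, rng):
    out = list(seq)
    for p in positions:
        old = out[p]
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
    return "".join(out)


class TestChainAndExtend:
    def _embed(self, rng, copy1, copy2, spacer=1700):
        # distinct homopolymer junctions pin the repeat boundaries exactly
        return ("GGGG" + _random_dna(rng, 996) + copy1 + "AAAA"
                + _random_dna(rng, spacer - 8) + "TTTT" + copy2
                + "CCCC" + _random_dna(rng, 996))

    def test_perfect_repeat_recovered_with_identity_one(self):
        rng = np.random.default_rng(5)
        R = "TG" + _random_dna(rng, 296) + "CA"
        s = self._embed(rng, R, R)
        cands = chain_and_extend(s, find_seed_matches(s, PARAMS), PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert c.identity == 1.0
        assert abs(c.ltr5_start - 1000) <= PARAMS.band
        assert abs(c.ltr3_start - (1000 + 300 + 1700)) <= PARAMS.band

    def test_identity_equals_known_substitution_fraction(self):
        rng = np.random.default_rng(6)
        R = _random_dna(rng, 300)
        # 30 substitutions spaced 3 apart, away from the ends
        R2 = _substitute(R, [60 + 3 * i for i in range(30)], rng)
        s = self._embed(rng, R, R2)
        cands = chain_and_extend(s, find_seed_matches(s, PARAMS), PARAMS)
        assert len(cands) == 1
        assert cands[0].identity == pytest.approx(270 / 300)

    def test_identity_at_or_below_threshold_is_rejected(self):
        rng = np.random.default_rng(7)
        R = _random_dna(rng, 300)
        R2 = _substitute(R, [30 + 3 * i for i in range(75)], rng)
        s = self._embed(rng, R, R2)
        cands = chain_and_extend(s, find_seed_matches(s, PARAMS), PARAMS)
        assert cands == []

    def test_determinism(self):
        rng = np.random.default_rng(8)
        R = "TG" + _random_dna(rng, 396) + "CA"
        s = self._embed(rng, R, R)
        seq = GenomeSequence("c", s)
        a = detect_elements(seq, PARAMS)[0]
        b = detect_elements(seq, PARAMS)[0]
        assert a == b

    def test_min_identity_monotonicity(self):
        rng = np.random.default_rng(9)
        R = _random_dna(rng, 300)
        R2 = _substitute(R, [60 + 3 * i for i in range(30)], rng)  # identity 0.90
        s = self._embed(rng, R, R2)
        seeds = find_seed_matches(s, PARAMS)
        lo = chain_and_extend(s, seeds, DetectionParams(min_identity=0.80))
        hi = chain_and_extend(s, seeds, DetectionParams(min_identity=0.95))
        assert len(hi) <= len(lo)
        assert len(lo) == 1 and len(hi) == 0


def _cand(l5s, l5e, l3s, l3e, score, identity=0.95):
    return CandidateElement(chrom="c", ltr5_start=l5s, ltr5_end=l5e,
                            ltr3_start=l3s, ltr3_end=l3e, identity=identity,
                            score=score)


class TestResolveOverlaps:
    def test_shared_ltr_keeps_higher_score(self):
        a = _cand(1000, 1300, 3000, 3300, score=500)
        b = _cand(1000, 1300, 4000, 4300, score=400)
        kept = resolve_overlaps([a, b])
        assert kept == [a]

    def test_nested_candidate_is_kept(self):
        outer = _cand(1000, 1300, 9000, 9300, score=500)
        inner = _cand(2000, 2200, 5000, 5200, score=100)
        kept = resolve_overlaps([outer, inner])
        assert set((k.ltr5_start for k in kept)) == {1000, 2000}

    def test_equal_scores_tie_break_left(self):
        a = _cand(2000, 2300, 5000, 5300, score=400)
        b = _cand(1000, 1300, 5100, 5400, score=400)
        kept = resolve_overlaps([a, b])
        # both overlap each other's LTR spans? spans [2000,5300) vs [1000,5400):
        # a's span overlaps b's 3' LTR -> only the left-most (b) survives
        assert kept == [b]


class TestRefineMotif:
    # Backgrounds are homopolymers so no spurious TG/CA lies in any window.
    def _scaffold(self, ltr, internal_len=1700, flank=1200):
        s = "C" * flank + ltr + "A" * internal_len + ltr + "C" * flank
        cand = CandidateElement(
            chrom="c", ltr5_start=flank, ltr5_end=flank + len(ltr),
            ltr3_start=flank + len(ltr) + internal_len,
            ltr3_end=flank + 2 * len(ltr) + internal_len, identity=1.0)
        return s, cand

    def test_fixed_point_boundaries_already_on_motif(self):
        ltr = "TG" + "A" * 296 + "CA"
        s, cand = self._scaffold(ltr)
        out = refine_motif(s, cand, PARAMS)
        assert (out.ltr5_start, out.ltr5_end, out.ltr3_start, out.ltr3_end) == \
            (cand.ltr5_start, cand.ltr5_end, cand.ltr3_start, cand.ltr3_end)
        assert out.tg_ca == (True, True)

    def test_tg_three_bp_right_shifts_start(self):
        ltr = "TG" + "A" * 296 + "CA"
        s, cand = self._scaffold(ltr)
        from dataclasses import replace
        off = replace(cand, ltr5_start=cand.ltr5_start - 3,
                      ltr3_start=cand.ltr3_start - 3)
        out = refine_motif(s, off, PARAMS)
        assert out.ltr5_start == cand.ltr5_start
        assert out.ltr3_start == cand.ltr3_start
        assert out.tg_ca[0] is True

    def test_no_tg_within_window_leaves_boundary(self):
        ltr = "AA" + "A" * 296 + "CA"  # no TG anywhere
        s, cand = self._scaffold(ltr)
        out = refine_motif(s, cand, PARAMS)
        assert out.ltr5_start == cand.ltr5_start
        assert out.tg_ca[0] is False

    def test_shift_violating_length_reverts(self):
        # LTR exactly at ltr_min; TG sits +3 inside, shifting would shorten
        # the LTR below ltr_min on both copies -> revert
        ltr = "AAA" + "TG" + "A" * (PARAMS.ltr_min - 7) + "CA"
        assert len(ltr) == PARAMS.ltr_min
        s, cand = self._scaffold(ltr)
        out = refine_motif(s, cand, PARAMS)
        assert out.ltr5_start == cand.ltr5_start
        assert out.tg_ca[0] is False


class TestDetectTsd:
    def _with_flanks(self, up, down, ltr_len=200, internal=1500):
        ltr = "T" * ltr_len
        s = "G" * 50 + up + ltr + "A" * internal + ltr + down + "G" * 50
        cand = CandidateElement(
            chrom="c", ltr5_start=50 + len(up), ltr5_end=50 + len(up) + ltr_len,
            ltr3_start=50 + len(up) + ltr_len + internal,
            ltr3_end=50 + len(up) + 2 * ltr_len + internal, identity=1.0)
        return s, cand

    def test_five_mer_match_from_worked_example(self):
        s, cand = self._with_flanks("AGACGT", "GACGTC")
        assert detect_tsd(s, cand, PARAMS) == "GACGT"

    def test_no_shared_flank_gives_none(self):
        s, cand = self._with_flanks("AAAAAA", "CCCCCC")
        assert detect_tsd(s, cand, PARAMS) is None

    def test_longest_first_preference(self):
        s, cand = self._with_flanks("TACGTA", "TACGTA")
        assert detect_tsd(s, cand, PARAMS) == "TACGTA"

    def test_contig_edge_gives_none(self):
        ltr = "T" * 200
        s = ltr + "A" * 1500 + ltr
        cand = CandidateElement(chrom="c", ltr5_start=0, ltr5_end=200,
                                ltr3_start=1700, ltr3_end=1900, identity=1.0)
        assert detect_tsd(s, cand, PARAMS) is None

    def test_n_in_flank_never_matches(self):
        s, cand = self._with_flanks("ANCGTA", "ANCGTA")
        assert detect_tsd(s, cand, PARAMS) is None

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            up = _random_dna(rng, 6)
            down = up if rng.random() < 0.3 else _random_dna(rng, 6)
            s, cand = self._with_flanks(up, down)
            assert detect_tsd(s, cand, PARAMS) == \
                tsd_oracle(s, cand.ltr5_start, cand.ltr3_end)
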