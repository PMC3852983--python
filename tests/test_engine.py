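"""Striped forward pass: profile layout, fill semantics, end location,
second-best extraction, and the engine's structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stripedsw as ssw
from stripedsw.engine import NEG

dna_strings = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestBuildProfile:
    def test_striped_layout_matches_definition(self, dna_setting1):
        qc = ssw.encode("ACGT", dna_setting1)
        prof = ssw.build_profile(qc, dna_setting1, lanes=2)
        assert (prof.seg_len, prof.lanes) == (2, 2)
        # profile[s][i, j] == score(s, query[j*L + i]) for real positions
        for s in range(dna_setting1.size):
            for i in range(2):
                for j in range(2):
                    expected = dna_setting1.scores[s, qc[j * 2 + i]]
                    assert prof.profile[s, i, j] == expected
        # profile[A] in striped order: scores of pos 0, 2 then pos 1, 3 vs A
        a = prof.profile[0]
        assert a[0].tolist() == [2, -1]   # A vs A, A vs G
        assert a[1].tolist() == [-1, -1]  # A vs C, A vs T

    def test_padding_slot_and_sentinel(self, dna_setting1):
        qc = ssw.encode("ACGTA", dna_setting1)
        prof = ssw.build_profile(qc, dna_setting1, lanes=2)
        assert prof.seg_len == 3
        assert prof.pad_mask is not None
        assert prof.pad_mask.sum() == 1 and prof.pad_mask[2, 1]
        assert (prof.profile[:, 2, 1] == NEG).all()

    def test_single_lane_is_plain_query_order(self, dna_setting1):
        qc = ssw.encode("ACGT", dna_setting1)
        prof = ssw.build_profile(qc, dna_setting1, lanes=1)
        for s in range(dna_setting1.size):
            assert prof.profile[s, :, 0].tolist() == \
                dna_setting1.scores[s, qc].tolist()

    def test_lane_count_changes_layout_not_scores(self, dna_setting1, rng):
        qc = ssw.encode("".join(rng.choice(list("ACGT"), size=23)),
                        dna_setting1)
        multisets = []
        for lanes in (1, 2, 8):
            prof = ssw.build_profile(qc, dna_setting1, lanes)
            real = prof.profile[:, ~prof.pad_mask] if prof.pad_mask is not None \
                else prof.profile.reshape(dna_setting1.size, -1)
            multisets.append(np.sort(real.reshape(dna_setting1.size, -1),
                                     axis=1))
        assert all((m == multisets[0]).all() for m in multisets[1:])

    def test_rejects_degenerate_input(self, dna_setting1):
        with pytest.raises(ValueError):
            ssw.build_profile(np.array([], dtype=int), dna_setting1)
        with pytest.raises(ValueError):
            ssw.build_profile(ssw.encode("ACGT", dna_setting1),
                              dna_setting1, lanes=0)


class TestStripedFill:
    def _fill(self, q, t, scheme, lanes=8):
        qc, tc = ssw.encode(q, scheme), ssw.encode(t, scheme)
        prof = ssw.build_profile(qc, scheme, lanes)
        return ssw.striped_fill(prof, tc, scheme.gap_open, scheme.gap_extend)

    def test_perfect_match(self, dna_setting1):
        s = self._fill("ACGT", "ACGT", dna_setting1)
        assert s.best_score == 8
        assert s.best_target_index == 3
        assert s.column_maxima.tolist() == [2, 4, 6, 8]

    def test_no_positive_cell(self):
        scheme = ssw.make_dna_scheme(2, 3, 5, 2)
        s = self._fill("AAAA", "TTTT", scheme)
        assert s.best_score == 0
        assert s.column_maxima.tolist() == [0, 0, 0, 0]

    def test_two_copy_target_ties_resolve_leftmost(self, dna_setting1):
        q, t = "ACGT", "ACGTAAAAAAACGT"
        s = self._fill(q, t, dna_setting1)
        assert s.best_score == 8
        assert s.best_target_index == 3  # leftmost of the tied columns 3, 13
        oracle = ssw.naive_column_maxima(ssw.encode(q, dna_setting1),
                                         ssw.encode(t, dna_setting1),
                                         dna_setting1)
        assert s.column_maxima.tolist() == oracle
        # the first copy's match tail decays through deletion extensions
        assert oracle == [2, 4, 6, 8, 6, 5, 4, 3, 2, 2, 2, 4, 6, 8]

    def test_empty_target_rejected(self, dna_setting1):
        prof = ssw.build_profile(ssw.encode("ACGT", dna_setting1),
                                 dna_setting1)
        with pytest.raises(ValueError):
            ssw.striped_fill(prof, np.array([], dtype=int), 2, 1)

    def test_matches_oracle_on_random_instances(self, instance_sampler, rng):
        for _ in range(40):
            scheme, q, t = instance_sampler(rng, qlen=(5, 40), tlen=(10, 120))
            qc, tc = ssw.encode(q, scheme), ssw.encode(t, scheme)
            lanes = int(rng.choice([1, 2, 4, 8, 16]))
            prof = ssw.build_profile(qc, scheme, lanes)
            summ = ssw.striped_fill(prof, tc, scheme.gap_open,
                                    scheme.gap_extend)
            oracle = ssw.naive_column_maxima(qc, tc, scheme)
            assert summ.column_maxima.tolist() == oracle
            assert summ.best_score == max(oracle)

    def test_lane_invariance_bit_identical(self, instance_sampler, rng):
        for _ in range(8):
            scheme, q, t = instance_sampler(rng, qlen=(5, 50), tlen=(10, 150))
            qc, tc = ssw.encode(q, scheme), ssw.encode(t, scheme)
            ref = None
            for lanes in (1, 2, 4, 8, 16):
                prof = ssw.build_profile(qc, scheme, lanes)
                s = ssw.striped_fill(prof, tc, scheme.gap_open,
                                     scheme.gap_extend)
                view = (s.best_score, s.best_target_index,
                        s.column_maxima.tolist(),
                        s.best_column_scores.tolist())
                if ref is None:
                    ref = view
                else:
                    assert view == ref

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(q=dna_strings, t=dna_strings, c=st.integers(1, 5))
    def test_scale_covariance(self, q, t, c):
        scheme = ssw.make_dna_scheme(2, 1, 2, 1)
        base = self._fill(q, t, scheme)
        scaled = self._fill(q, t, scheme.scaled(c))
        assert scaled.best_score == c * base.best_score
        assert scaled.column_maxima.tolist() == \
            (c * base.column_maxima).tolist()

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(q=dna_strings, t=dna_strings, extra=st.text(alphabet="ACGT",
                                                       min_size=1,
                                                       max_size=20))
    def test_target_extension_monotone(self, q, t, extra):
        scheme = ssw.make_dna_scheme(2, 1, 2, 1)
        base = self._fill(q, t, scheme)
        longer = self._fill(q, t + extra, scheme)
        assert longer.best_score >= base.best_score
        assert longer.column_maxima[:len(t)].tolist() == \
            base.column_maxima.tolist()


class TestLocateQueryEnd:
    def test_perfect_match_end(self, dna_setting1):
        qc = ssw.encode("ACGT", dna_setting1)
        prof = ssw.build_profile(qc, dna_setting1)
        s = ssw.striped_fill(prof, qc, 2, 1)
        assert ssw.locate_query_end(s) == 3

    def test_tied_query_prefixes_pick_smallest(self, dna_setting1):
        # both prefixes ending at 3 and 7 can reach score 8 in the best column
        qc = ssw.encode("ACGTACGT", dna_setting1)
        tc = ssw.encode("ACGT", dna_setting1)
        s = ssw.striped_fill(ssw.build_profile(qc, dna_setting1), tc, 2, 1)
        assert s.best_score == 8
        assert (s.best_column_scores == 8).sum() >= 1
        assert ssw.locate_query_end(s) == 3

    def test_zero_score_signals_no_alignment(self):
        scheme = ssw.make_dna_scheme(2, 3, 5, 2)
        qc = ssw.encode("AAAA", scheme)
        tc = ssw.encode("TTTT", scheme)
        s = ssw.striped_fill(ssw.build_profile(qc, scheme), tc, 5, 2)
        assert ssw.locate_query_end(s) is None


class TestSecondBest:
    def test_two_copy_mask(self):
        cm = [2, 4, 6, 8, 6, 5, 4, 3, 2, 2, 2, 4, 6, 8]
        assert ssw.second_best(cm, 0, 3) == (8, 13)

    def test_everything_masked(self):
        assert ssw.second_best([5], 0, 0) == (0, None)
        assert ssw.second_best([3, 7, 2], 0, 2) == (0, None)

    def test_all_unmasked_zero(self):
        assert ssw.second_best([0, 0, 5, 0], 2, 2) == (0, None)

    def test_malformed_interval(self):
        with pytest.raises(ValueError):
            ssw.second_best([1, 2, 3], 2, 1)
        with pytest.raises(ValueError):
            ssw.second_best([1, 2, 3], 0, 3)

    def test_never_exceeds_best_and_avoids_mask(self, instance_sampler, rng):
        for _ in range(20):
            scheme, q, t = instance_sampler(rng, qlen=(5, 30), tlen=(10, 80))
            qc, tc = ssw.encode(q, scheme), ssw.encode(t, scheme)
            s = ssw.striped_fill(ssw.build_profile(qc, scheme), tc,
                                 scheme.gap_open, scheme.gap_extend)
            lo = int(rng.integers(0, len(t)))
            hi = int(rng.integers(lo, len(t)))
            score2, ref2 = ssw.second_best(s.column_maxima, lo, hi)
            assert score2 <= max(s.best_score, 0)
            if ref2 is not None:
                assert not lo <= ref2 <= hi
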