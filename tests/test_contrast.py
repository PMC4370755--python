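import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import condiv as cv
from condiv.contrast import (ball_in_urn_pvalue, detect_inserts, freq_to_tenths,
                             henikoff_weights, score_contrast, select_pattern,
                             weighted_profile)


def exact_tail(k_f: int, n_f: int, k_b: int, n_b: int) -> Fraction:
    """Independent oracle: exact hypergeometric upper tail by enumeration."""
    T, K = n_f + n_b, k_f + k_b
    total = math.comb(T, n_f)
    acc = Fraction(0)
    for x in range(k_f, min(K, n_f) + 1):
        if n_f - x <= T - K:
            acc += Fraction(math.comb(K, x) * math.comb(T - K, n_f - x), total)
    return acc


class TestBallInUrn:
    def test_hand_enumerated_example(self):
        # (C(5,4)C(5,1) + C(5,5)C(5,0)) / C(10,5) = 26/252
        assert ball_in_urn_pvalue(4, 5, 1, 5) == pytest.approx(26 / 252, abs=1e-12)

    def test_zero_matches_gives_one(self):
        assert ball_in_urn_pvalue(0, 10, 3, 20) == 1.0

    def test_saturated_urn_gives_one(self):
        assert ball_in_urn_pvalue(5, 5, 7, 7) == 1.0

    def test_agrees_with_scipy_cross_check(self):
        from scipy.stats import hypergeom
        for (kf, nf, kb, nb) in [(4, 5, 1, 5), (10, 40, 3, 60), (7, 9, 2, 11)]:
            expected = float(hypergeom.sf(kf - 1, nf + nb, kf + kb, nf))
            assert ball_in_urn_pvalue(kf, nf, kb, nb) == pytest.approx(expected, abs=1e-12)

    def test_weighted_inputs_rounded(self):
        assert ball_in_urn_pvalue(3.6, 5.1, 1.2, 4.9) == ball_in_urn_pvalue(4, 5, 1, 5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ball_in_urn_pvalue(-1, 5, 0, 5)
        with pytest.raises(ValueError):
            ball_in_urn_pvalue(6, 5, 0, 5)
        with pytest.raises(ValueError):
            ball_in_urn_pvalue(0, 0, 0, 0)

    def test_monotone_nonincreasing_in_foreground_count(self):
        # K = k_F + k_B fixed, totals fixed: moving matches into the foreground
        # can only make the observation more surprising
        n_f, n_b, K = 12, 18, 10
        last = 1.0
        for k_f in range(0, min(K, n_f) + 1):
            k_b = K - k_f
            if k_b > n_b:
                continue
            p = ball_in_urn_pvalue(k_f, n_f, k_b, n_b)
            assert p <= last + 1e-15
            last = p


def test_freq_to_tenths_display_convention():
    assert freq_to_tenths(0.65) == 6          # 60-70% band
    assert freq_to_tenths(0.0) == 0
    assert freq_to_tenths(1.0) == 9           # clamped single display digit
    assert freq_to_tenths(0.999) == 9
    with pytest.raises(ValueError):
        freq_to_tenths(1.2)


class TestHenikoffWeights:
    def test_single_column_hand_computed(self):
        aln = cv.LabeledAlignment(
            records=[("s1", "A"), ("s2", "A"), ("s3", "C")], label_of={}, n_columns=1)
        w = henikoff_weights(aln)
        # raw contributions 1/(r*s): (1/4, 1/4, 1/2); rescaled to mean 1
        assert w.weight_of["s1"] == pytest.approx(0.75)
        assert w.weight_of["s2"] == pytest.approx(0.75)
        assert w.weight_of["s3"] == pytest.approx(1.5)

    def test_identical_sequences_all_weight_one(self):
        aln = cv.LabeledAlignment(
            records=[(f"s{i}", "ACDEF") for i in range(4)], label_of={}, n_columns=5)
        w = henikoff_weights(aln)
        assert all(v == pytest.approx(1.0) for v in w.weight_of.values())

    def test_weights_positive_and_mean_one(self, planted_alignment):
        aln, _ = planted_alignment
        w = henikoff_weights(aln)
        vals = np.array(list(w.weight_of.values()))
        assert (vals > 0).all()
        assert vals.sum() == pytest.approx(aln.n_sequences, abs=1e-9)

    def test_all_gap_alignment_rejected(self):
        aln = cv.LabeledAlignment(records=[("a", "--"), ("b", "--")],
                                  label_of={}, n_columns=2)
        with pytest.raises(ValueError):
            henikoff_weights(aln)


@settings(deadline=None, max_examples=25)
@given(st.data())
def test_duplication_leaves_weighted_frequencies_unchanged(data):
    n_seq = data.draw(st.integers(3, 8))
    n_col = data.draw(st.integers(2, 6))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    alphabet = "ACDEFG-"
    rows = ["".join(rng.choice(list(alphabet), size=n_col)) for _ in range(n_seq)]
    if all(set(r) == {"-"} for r in rows):
        rows[0] = "A" * n_col
    records = [(f"s{i}", r) for i, r in enumerate(rows)]
    aln = cv.LabeledAlignment(records=records, label_of={}, n_columns=n_col)
    w = henikoff_weights(aln)
    prof = weighted_profile(aln, w, aln.seq_ids)
    freq_before = prof.frequencies()

    dup_i = data.draw(st.integers(0, n_seq - 1))
    m = data.draw(st.integers(1, 3))
    records2 = records + [(f"dup{j}", rows[dup_i]) for j in range(m)]
    aln2 = cv.LabeledAlignment(records=records2, label_of={}, n_columns=n_col)
    w2 = henikoff_weights(aln2)
    freq_after = weighted_profile(aln2, w2, aln2.seq_ids).frequencies()
    assert np.abs(freq_before - freq_after).max() <= 1e-9


class TestWeightedProfile:
    def test_unit_weights_count_residues(self):
        aln = cv.LabeledAlignment(records=[("a", "AA"), ("b", "AC")],
                                  label_of={}, n_columns=2)
        w = cv.SequenceWeights(weight_of={"a": 1.0, "b": 1.0})
        prof = weighted_profile(aln, w, ["a", "b"])
        assert prof.counts[0, 0] == pytest.approx(2.0)      # column 1: two A
        assert prof.effective_n[0] == pytest.approx(2.0)

    def test_gap_mass_tracked_separately(self):
        aln = cv.LabeledAlignment(records=[("a", "A"), ("b", "-")],
                                  label_of={}, n_columns=1)
        w = cv.SequenceWeights(weight_of={"a": 1.5, "b": 0.5})
        prof = weighted_profile(aln, w, ["a", "b"])
        assert prof.counts[0, 0] == pytest.approx(1.5)
        assert prof.gap_count[0] == pytest.approx(0.5)
        assert prof.effective_n[0] == pytest.approx(1.5)

    def test_empty_subset_rejected(self, tiny_alignment):
        w = henikoff_weights(tiny_alignment)
        with pytest.raises(ValueError):
            weighted_profile(tiny_alignment, w, [])

    def test_mass_conservation_random_inputs(self, rng):
        n_seq, n_col = 12, 9
        alphabet = "ACDEFGHIKLMNPQRSTVWYX-"
        rows = ["".join(rng.choice(list(alphabet), size=n_col)) for _ in range(n_seq)]
        rows[0] = "A" * n_col
        aln = cv.LabeledAlignment(records=[(f"s{i}", r) for i, r in enumerate(rows)],
                                  label_of={}, n_columns=n_col)
        w = henikoff_weights(aln)
        prof = weighted_profile(aln, w, aln.seq_ids)
        total = prof.counts.sum(axis=1) + prof.gap_count + prof.unknown_count
        assert np.abs(total - prof.total_weight).max() <= 1e-9


def _profile_from_counts(fg_counts, gaps=0.0):
    counts = np.zeros((1, 20))
    for aa, c in fg_counts.items():
        counts[0, "ACDEFGHIKLMNPQRSTVWY".index(aa)] = c
    return cv.ColumnProfile(counts=counts, gap_count=np.array([gaps]),
                            unknown_count=np.zeros(1),
                            total_weight=float(counts.sum() + gaps))


class TestSelectPattern:
    def test_dominant_single_residue_not_diluted(self):
        fg = _profile_from_counts({"E": 90.0, "D": 10.0})
        bg = _profile_from_counts({"E": 15.0, "A": 95.0, "C": 95.0, "D": 95.0})
        pc = select_pattern(1, fg, bg)
        assert pc.pattern_set == frozenset("E")

    def test_split_conserved_pair_beats_singletons(self):
        fg = _profile_from_counts({"D": 100.0, "E": 80.0, "A": 20.0})
        bg = _profile_from_counts({"D": 30.0, "E": 30.0, "A": 540.0})
        pc = select_pattern(1, fg, bg)
        assert pc.pattern_set == frozenset("DE")
        # the pair's adjusted p beats each singleton's
        p_d = ball_in_urn_pvalue(100, 200, 30, 600) * 20
        p_e = ball_in_urn_pvalue(80, 200, 30, 600) * 20
        assert pc.p_value < min(p_d, p_e)

    def test_no_contrast_yields_high_p(self):
        fg = _profile_from_counts({"A": 50.0, "C": 50.0})
        bg = _profile_from_counts({"A": 150.0, "C": 150.0})
        pc = select_pattern(1, fg, bg)
        assert pc.p_value > 0.05

    def test_low_coverage_column_skipped(self):
        fg = _profile_from_counts({"E": 10.0}, gaps=90.0)
        bg = _profile_from_counts({"A": 100.0})
        assert select_pattern(1, fg, bg, min_fg_coverage=0.5) is None


class TestScoreContrast:
    def test_overlapping_sets_rejected(self, planted_alignment):
        aln, truth = planted_alignment
        w = henikoff_weights(aln)
        with pytest.raises(ValueError, match="overlap"):
            score_contrast(aln, w, truth["fg_ids"], truth["fg_ids"][:5] + truth["bg_ids"])
        with pytest.raises(ValueError):
            score_contrast(aln, w, [], truth["bg_ids"])

    def test_ranked_positions_sorted_and_deterministic(self, planted_alignment):
        aln, truth = planted_alignment
        w = henikoff_weights(aln)
        res1 = score_contrast(aln, w, truth["fg_ids"], truth["bg_ids"])
        res2 = score_contrast(aln, w, truth["fg_ids"], truth["bg_ids"])
        assert res1.ranked_positions == res2.ranked_positions
        ps = [res1.column_result(c).p_value for c in res1.ranked_positions]
        assert ps == sorted(ps)
        for pc in res1.columns:
            assert np.isfinite(pc.height) and pc.height >= 0
            assert 0 < pc.p_value <= 1

    def test_top_k_override(self, planted_alignment):
        aln, truth = planted_alignment
        w = henikoff_weights(aln)
        res = score_contrast(aln, w, truth["fg_ids"], truth["bg_ids"], top_k=5)
        assert len(res.ranked_positions) == 5


class TestSubfamilyContrasts:
    def test_child_covering_whole_parent_is_skipped(self):
        records = [(f"s{i}", "ACD") for i in range(4)]
        labels = {f"s{i}": "X/y" for i in range(4)}
        aln = cv.LabeledAlignment(records=records, label_of=labels, n_columns=3)
        tree = cv.build_hyperpartition(aln)
        w = henikoff_weights(aln)
        results = cv.subfamily_contrasts(aln, w, tree)
        assert results == {}

    def test_sibling_background_definition(self, nested_alignment):
        aln, _ = nested_alignment
        tree = cv.build_hyperpartition(aln)
        p38 = tree.node("CMGC/MAPK/p38")
        mapk = tree.node("CMGC/MAPK")
        assert set(p38.members) < set(mapk.members)
        sibling_bg = set(mapk.members) - set(p38.members)
        assert sibling_bg == set(tree.node("CMGC/MAPK/JNK").members)


class TestDetectInserts:
    def test_planted_insert_called_exactly(self, planted_alignment):
        aln, truth = planted_alignment
        w = henikoff_weights(aln)
        calls = detect_inserts(aln, w, truth["fg_ids"], truth["bg_ids"])
        assert [(c.start, c.end) for c in calls] == [(60, 63)]
        call = calls[0]
        assert 0 <= call.fg_occupancy <= 1 and 0 <= call.bg_gap_fraction <= 1
        assert call.p_value < 1e-10

    def test_no_insert_in_null_alignment(self):
        spec = cv.SyntheticAlignmentSpec(n_fg=50, n_bg=150, n_columns=60, seed=9)
        aln, truth = cv.gen_alignment(spec)
        w = henikoff_weights(aln)
        assert detect_inserts(aln, w, truth["fg_ids"], truth["bg_ids"]) == []

    def test_shared_occupancy_not_called(self):
        # background only 50% gapped: below the 90% gap threshold
        spec = cv.SyntheticAlignmentSpec(
            n_fg=50, n_bg=150, n_columns=60, seed=9,
            inserts=[cv.PlantedInsert(start=20, end=23, fg_occupancy=0.95,
                                      bg_gap_fraction=0.5)])
        aln, truth = cv.gen_alignment(spec)
        w = henikoff_weights(aln)
        calls = detect_inserts(aln, w, truth["fg_ids"], truth["bg_ids"])
        assert calls == []
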