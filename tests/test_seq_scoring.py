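import math

import numpy as np
import pytest

from ptpscout.sequence_library import AA20, PeptideWindow
from ptpscout.seq_scoring import (
    ALPHABET21,
    CandidateRecord,
    FrequencyMatrices,
    ScoringError,
    build_logo,
    build_pssm,
    calibrate_threshold,
    classifier_pass,
    classifier_score,
    consensus,
    logo_score,
    pssm_score,
    rank_descending,
    train_classifier,
)
from ptpscout.synthetic_data import MotifSpec, sample_windows

from conftest import random_window

LOG2_20 = math.log2(20)


def uniform_windows():
    """20 windows whose columns each contain all 20 amino acids once."""
    return [PeptideWindow(a * 5 + "Y" + a * 5) for a in AA20]


class TestLogo:
    def test_uniform_column_has_zero_information(self):
        logo = build_logo(uniform_windows(), correction=False)
        assert np.allclose(logo.heights, 0.0)

    def test_pure_column_has_maximal_information(self):
        logo = build_logo([PeptideWindow("EEEEEYEEEEE")] * 3, correction=False)
        e_row = logo.heights[AA20.index("E")]
        assert np.allclose(e_row, LOG2_20)

    def test_small_sample_correction_value(self):
        # 10 identical sequences, pure-E columns: R = log2(20) - 19/(2 ln2 n)
        logo = build_logo([PeptideWindow("EEEEEYEEEEE")] * 10, correction=True)
        expected = LOG2_20 - 19.0 / (20.0 * math.log(2.0))
        assert logo.heights[AA20.index("E")][0] == pytest.approx(expected, abs=1e-12)

    def test_column_information_bounded(self, training_windows):
        positives, _ = training_windows
        logo = build_logo(positives, correction=True)
        r = logo.column_information()
        assert np.all(r >= 0) and np.all(r <= LOG2_20 + 1e-12)

    def test_duplicating_alignment_leaves_logo_unchanged(self, training_windows):
        positives, _ = training_windows
        a = build_logo(positives, correction=False)
        b = build_logo(positives * 3, correction=False)
        assert np.allclose(a.heights, b.heights)

    def test_empty_positive_set_rejected(self):
        with pytest.raises(ScoringError):
            build_logo([])


class TestLogoScore:
    def test_uniform_logo_scores_zero(self, rng):
        logo = build_logo(uniform_windows(), correction=False)
        assert logo_score(random_window(rng), logo) == pytest.approx(0.0)

    def test_perfect_match_of_degenerate_logo_scores_max(self):
        w = PeptideWindow("DPSDNYAEPID")
        logo = build_logo([w], correction=False)
        assert logo_score(w, logo) == pytest.approx(10 * LOG2_20)

    def test_blank_contributes_zero(self):
        logo = build_logo([PeptideWindow("EEEEEYEEEEE")] * 3, correction=False)
        assert logo_score(PeptideWindow("----EYEEEEE"), logo) == pytest.approx(6 * LOG2_20)

    def test_matches_bruteforce_height_lookup(self, motif_spec, rng):
        positives = sample_windows(motif_spec, 50, planted=True, rng=rng)
        logo = build_logo(positives, correction=True)
        for _ in range(25):
            w = random_window(rng)
            flanks = w.sequence[:5] + w.sequence[6:]
            expected = sum(
                logo.heights[AA20.index(a)][j]
                for j, a in enumerate(flanks)
                if a != "-"
            )
            assert logo_score(w, logo) == pytest.approx(expected, abs=1e-9)


class TestPssm:
    def test_identical_classes_give_identical_matrices(self, training_windows):
        positives, _ = training_windows
        m = build_pssm(positives, list(positives))
        assert np.allclose(m.positive, m.negative)
        assert np.allclose(m.positive, m.total)

    def test_single_positive_gives_unit_frequencies(self):
        m = build_pssm([PeptideWindow("AAAAAYAAAAA")], [PeptideWindow("CCCCCYCCCCC")])
        assert np.allclose(m.positive[ALPHABET21.index("A")], 1.0)

    def test_total_is_mixture_of_classes(self, motif_spec, rng):
        positives = sample_windows(motif_spec, 3, planted=True, rng=rng)
        negatives = sample_windows(motif_spec, 7, planted=False, rng=rng)
        m = build_pssm(positives, negatives)
        assert np.allclose(m.total, 0.3 * m.positive + 0.7 * m.negative, atol=1e-12)

    def test_columns_sum_to_one(self, training_windows):
        m = build_pssm(*training_windows)
        for mat in (m.positive, m.negative, m.total):
            assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_class_rejected(self, training_windows):
        positives, _ = training_windows
        with pytest.raises(ScoringError):
            build_pssm(positives, [])


class TestPssmScore:
    def test_symmetric_classes_score_zero(self, training_windows, rng):
        positives, _ = training_windows
        m = build_pssm(positives, list(positives))
        assert pssm_score(random_window(rng), m) == pytest.approx(0.0)

    def test_positive_only_symbol_scores_positive(self):
        m = build_pssm(
            [PeptideWindow("WWWWWYWWWWW")] * 3, [PeptideWindow("AAAAAYAAAAA")] * 3
        )
        assert pssm_score(PeptideWindow("WWWWWYWWWWW"), m, alpha=0.01) > 0

    def test_hand_computed_two_symbol_matrices(self):
        # hand-set frequencies: positives 80% A / 20% C, negatives 30% A / 70% C
        pos = np.zeros((21, 10))
        neg = np.zeros((21, 10))
        ia, ic = ALPHABET21.index("A"), ALPHABET21.index("C")
        pos[ia], pos[ic] = 0.8, 0.2
        neg[ia], neg[ic] = 0.3, 0.7
        m = FrequencyMatrices(pos, neg, 0.5 * pos + 0.5 * neg)
        alpha = 0.05
        ft_a = 0.55
        term_a = math.log2((0.8 + alpha * ft_a) / (0.3 + alpha * ft_a))
        expected = 10 * term_a
        assert pssm_score(PeptideWindow("AAAAAYAAAAA"), m, alpha) == pytest.approx(
            expected, abs=1e-12
        )

    def test_score_negates_when_classes_swap(self, training_windows, rng):
        positives, negatives = training_windows
        m = build_pssm(positives, negatives)
        m_swapped = build_pssm(negatives, positives)
        w = random_window(rng)
        assert pssm_score(w, m) == pytest.approx(-pssm_score(w, m_swapped), abs=1e-9)

    def test_absent_symbol_contributes_zero(self):
        m = build_pssm([PeptideWindow("AAAAAYAAAAA")], [PeptideWindow("CCCCCYCCCCC")])
        # W appears in neither class: each W position contributes 0
        assert pssm_score(PeptideWindow("WWWWWYWWWWW"), m) == pytest.approx(0.0)

    def test_matches_bruteforce_term_sum(self, training_windows, rng):
        positives, negatives = training_windows
        m = build_pssm(positives, negatives)
        alpha = 0.05
        for _ in range(25):
            w = random_window(rng)
            flanks = w.sequence[:5] + w.sequence[6:]
            expected = 0.0
            for j, a in enumerate(flanks):
                i = ALPHABET21.index(a)
                ft = m.total[i, j]
                if ft > 0:
                    expected += math.log2(
                        (m.positive[i, j] + alpha * ft) / (m.negative[i, j] + alpha * ft)
                    )
            assert pssm_score(w, m, alpha) == pytest.approx(expected, abs=1e-9)


class TestClassifier:
    def test_threshold_is_order_statistic(self):
        scores = np.arange(1, 101)
        threshold = calibrate_threshold(scores, 0.95)
        assert threshold == 96  # exactly 5 of 100 scores pass
        assert np.mean(scores >= threshold) <= 0.05

    def test_separable_classes_reach_high_sensitivity(self, motif_spec, rng):
        positives = sample_windows(motif_spec, 60, planted=True, rng=rng)
        negatives = sample_windows(motif_spec, 400, planted=False, rng=rng)
        clf = train_classifier(positives, negatives, 0.95, seed=7)
        held_out = sample_windows(motif_spec, 100, planted=True, rng=rng)
        sens = np.mean([classifier_pass(w, clf) for w in held_out])
        assert sens >= 0.95

    def test_no_signal_null_passes_at_one_minus_specificity(self):
        spec = MotifSpec(motif={}, seed=11)
        rng = np.random.default_rng(11)
        positives = sample_windows(spec, 150, planted=True, rng=rng)
        negatives = sample_windows(spec, 400, planted=False, rng=rng)
        clf = train_classifier(positives, negatives, 0.95, seed=11)
        fresh = sample_windows(spec, 400, planted=True, rng=rng)
        rate = np.mean([classifier_pass(w, clf) for w in fresh])
        se = math.sqrt(0.05 * 0.95 / 400)
        assert rate <= 0.05 + 3 * se

    def test_small_class_rejected_with_minimum(self, training_windows):
        positives, negatives = training_windows
        with pytest.raises(ScoringError, match="at least 20"):
            train_classifier(positives[:5], negatives)

    def test_deterministic_given_seed(self, training_windows):
        positives, negatives = training_windows
        a = train_classifier(positives, negatives, seed=3)
        b = train_classifier(positives, negatives, seed=3)
        assert a.threshold == b.threshold
        assert np.allclose(a.model.coef_, b.model.coef_)

    def test_blank_windows_are_scorable(self, training_windows):
        positives, negatives = training_windows
        clf = train_classifier(positives, negatives, seed=0)
        assert np.isfinite(classifier_score(PeptideWindow("----AYCCCCC"), clf))

    def test_batch_equals_per_item(self, training_windows, rng):
        positives, negatives = training_windows
        clf = train_classifier(positives, negatives, seed=0)
        windows = [random_window(rng) for _ in range(10)]
        batch = classifier_score(windows, clf)
        singles = [classifier_score(w, clf) for w in windows]
        assert np.allclose(batch, singles)


def make_records(rng, n):
    records = []
    seen = set()
    while len(records) < n:
        w = random_window(rng)
        if w.sequence in seen:
            continue
        seen.add(w.sequence)
        records.append(
            CandidateRecord(
                window=w,
                score_logo=float(rng.normal()),
                score_pssm=float(rng.normal()),
                score_clf=float(rng.normal()),
            )
        )
    return records


def brute_force_consensus(records, q):
    import math as _math

    cutoff = _math.ceil(q * len(records))
    tops = []
    for attr in ("score_logo", "score_pssm", "score_clf"):
        ordered = sorted(records, key=lambda r: (-getattr(r, attr), r.peptide))
        tops.append({r.peptide for r in ordered[:cutoff]})
    return tops[0] & tops[1] & tops[2]


class TestConsensus:
    def test_q_one_includes_everything(self, rng):
        records = consensus(make_records(rng, 20), q=1.0)
        assert all(r.in_consensus for r in records)

    def test_unanimous_top_record_is_sole_consensus(self, rng):
        records = make_records(rng, 10)
        for attr in ("score_logo", "score_pssm", "score_clf"):
            setattr(records[0], attr, 100.0)
        records = consensus(records, q=0.1)
        assert [r.peptide for r in records if r.in_consensus] == [records[0].peptide]

    def test_equals_bruteforce_intersection(self, rng):
        records = make_records(rng, 100)
        flagged = {r.peptide for r in consensus(records, 0.1) if r.in_consensus}
        assert flagged == brute_force_consensus(records, 0.1)

    def test_ranks_are_permutation(self, rng):
        records = consensus(make_records(rng, 50), q=0.2)
        for attr in ("rank_logo", "rank_pssm", "rank_clf"):
            assert sorted(getattr(r, attr) for r in records) == list(range(1, 51))

    def test_monotone_in_q(self, rng):
        records = make_records(rng, 60)
        small = {r.peptide for r in consensus(records, 0.1) if r.in_consensus}
        large = {r.peptide for r in consensus(records, 0.3) if r.in_consensus}
        assert small <= large

    def test_missing_score_raises(self, rng):
        records = make_records(rng, 5)
        records[2].score_pssm = None
        with pytest.raises(ScoringError, match="score_pssm"):
            consensus(records, 0.1)

    def test_rank_ties_break_lexicographically(self):
        a = CandidateRecord(PeptideWindow("AAAAAYAAAAA"), 1.0, 1.0, 1.0)
        b = CandidateRecord(PeptideWindow("CCCCCYCCCCC"), 1.0, 1.0, 1.0)
        ranks = rank_descending([1.0, 1.0], [a.peptide, b.peptide])
        assert ranks == [1, 2]
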