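"""Likert score reconstruction and the derived test statistics."""

import itertools
import math

import numpy as np
import pytest

from erisnet.reader_stats import (
    LikertSummary,
    ReconstructionError,
    TABLE_SUMMARIES,
    analyze_table,
    ci95,
    cohens_d,
    holm_adjust,
    one_sample_t,
    reconstruct_scores,
    results_to_frame,
    summarize_scores,
)


class TestReconstruction:
    def test_degenerate_all_fives(self):
        s = LikertSummary("Q", 5.0, 0.0, 5.0, 0.0, 6)
        assert reconstruct_scores(s) == (5, 5, 5, 5, 5, 5)

    @pytest.mark.parametrize(
        "summary,expected",
        [
            (LikertSummary("Q1", 4.5, 0.55, 4.5, 1.0), (4, 4, 4, 5, 5, 5)),
            (LikertSummary("Q9", 4.83, 0.41, 5.0, 0.0), (4, 5, 5, 5, 5, 5)),
        ],
    )
    def test_exhaustive_search_recovers_scores(self, summary, expected):
        assert reconstruct_scores(summary) == expected

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ReconstructionError):
            reconstruct_scores(LikertSummary("bad", 4.99, 0.01, 1.0, 4.0, 6))

    def test_roundtrip_identity_on_unambiguous_multisets(self):
        """summarize -> reconstruct is the identity for every 6-score
        multiset whose 2-decimal summary is unambiguous (210 cases; exactly
        one colliding pair exists and must be reported as ambiguous)."""
        ambiguous = []
        for combo in itertools.combinations_with_replacement(range(1, 6), 6):
            summary = summarize_scores("Q", combo)
            try:
                assert reconstruct_scores(summary) == combo
            except ReconstructionError as err:
                assert str(tuple(combo)) in str(err)  # true multiset is listed
                ambiguous.append(combo)
        # the single collision: mean 3.0, SD 1.10, median 3, IQR 0.75 twice
        assert ambiguous == [(1, 3, 3, 3, 4, 4), (2, 2, 3, 3, 3, 5)]


class TestOneSampleT:
    def test_published_q1_statistic(self):
        t, df, p = one_sample_t((4, 4, 4, 5, 5, 5))
        assert round(t, 2) == 6.71
        assert df == 5

    def test_published_q9_statistic_and_p(self):
        t, df, p = one_sample_t((4, 5, 5, 5, 5, 5))
        assert round(t, 2) == 11.00
        assert float(f"{p:.3g}") == 0.000108

    def test_mean_equal_to_null_gives_zero(self):
        t, df, p = one_sample_t((2, 3, 4, 2, 3, 4))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t((4, 4, 4, 4, 4, 4))


class TestCohensD:
    @pytest.mark.parametrize(
        "scores,expected",
        [((4, 5, 5, 5, 5, 5), 4.49), ((4, 4, 4, 5, 5, 5), 2.74)],
    )
    def test_published_effect_sizes(self, scores, expected):
        assert round(cohens_d(scores), 2) == expected

    def test_null_mean_gives_zero(self):
        assert cohens_d((2, 3, 4, 2, 3, 4)) == pytest.approx(0.0)

    def test_t_equals_d_times_sqrt_n(self, rng):
        for _ in range(10):
            scores = tuple(rng.integers(1, 6, size=6))
            if np.std(scores, ddof=1) == 0:
                continue
            t, _, _ = one_sample_t(scores)
            assert t == pytest.approx(cohens_d(scores) * math.sqrt(6), abs=1e-12)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == [0.03]

    def test_all_equal_multiplied_by_k_capped(self):
        assert holm_adjust([0.3, 0.3, 0.3, 0.3]) == [1.0, 1.0, 1.0, 1.0]
        out = holm_adjust([0.01, 0.01])
        assert out == [0.02, 0.02]

    def test_hand_computed_stepdown(self):
        # sorted: 0.01*3=0.03, 0.02*2=0.04, 0.05*1=0.05 (monotone already)
        assert holm_adjust([0.02, 0.05, 0.01]) == pytest.approx([0.04, 0.05, 0.03])

    def test_never_below_raw(self, rng):
        p = rng.uniform(0.001, 0.9, size=9)
        adj = holm_adjust(list(p))
        assert all(a >= r for a, r in zip(adj, p))

    def test_monotone_in_sorted_raw(self, rng):
        p = list(rng.uniform(0.001, 0.9, size=9))
        adj = holm_adjust(p)
        order = np.argsort(p)
        sorted_adj = np.asarray(adj)[order]
        assert all(a <= b for a, b in zip(sorted_adj, sorted_adj[1:]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.0, 0.5])

    def test_tie_averaged_variant_known_values(self):
        # duplicate smallest p: average rank 1.5 -> multiplier k - 0.5
        out = holm_adjust([0.01, 0.01, 0.5], variant="tie-averaged")
        assert out[0] == pytest.approx(0.01 * 2.5)
        assert out[2] == pytest.approx(0.5)


class TestCI95:
    def test_published_q9_half_width(self):
        lo, hi, half, se = ci95((4, 5, 5, 5, 5, 5))
        assert round(half, 2) == 0.43
        assert round(se, 2) == 0.17

    def test_published_q4_standard_error(self):
        _, _, _, se = ci95((3, 4, 5, 5, 5, 5))
        assert round(se, 2) == 0.34

    def test_constant_scores_zero_width(self):
        lo, hi, half, se = ci95((5, 5, 5, 5, 5, 5))
        assert half == 0.0
        assert lo == hi == 5.0


class TestAnalyzeTable:
    def test_full_t_row_reproduced(self):
        results = analyze_table(summaries=list(TABLE_SUMMARIES))
        t_row = [round(r.t, 2) for r in results]
        assert t_row == [6.71, 6.71, 7.91, 4.39, 6.32, 6.32, 5.00, 2.71, 11.00]

    def test_single_question_holm_equals_raw(self):
        results = analyze_table(raw_scores={"Q": (4, 5, 5, 5, 5, 5)})
        assert results[0].p_holm == pytest.approx(results[0].p_raw)

    def test_export_roundtrip(self):
        results = analyze_table(summaries=list(TABLE_SUMMARIES))
        frame = results_to_frame(results)
        # re-derive raw scores from the frame's summary rows and re-analyze
        summaries = [
            LikertSummary(
                q,
                round(frame[q]["mean"], 2),
                round(frame[q]["sd"], 2),
                round(frame[q]["median"], 2),
                round(frame[q]["iqr"], 2),
                6,
            )
            for q in frame.columns
        ]
        again = analyze_table(summaries=summaries)
        for a, b in zip(results, again):
            assert a.scores == b.scores
            assert a.t == pytest.approx(b.t)
            assert a.p_holm == pytest.approx(b.p_holm)

    def test_ci_invariant(self):
        for r in analyze_table(summaries=list(TABLE_SUMMARIES)):
            assert r.ci_high - r.ci_low == pytest.approx(2 * r.ci_width)
            assert r.p_holm >= r.p_raw
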