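"""Global alignment, truncation, and window statistics against oracles."""

import numpy as np
import pytest
from scipy.stats import binom

from mottle.align import (
    AlignParams,
    PairwiseAlignment,
    _window_stats_arrays,
    binomial_acceptance_region,
    filter_leading_gaps,
    gc_corrected_identity,
    geometric_indel_pmf,
    indel_fraction,
    needleman_wunsch,
    truncate_on_identity_change,
    window_statistics,
)

PARAMS = AlignParams()


def aln_from_text(q: str, t: str, origin_state: str = "match") -> PairwiseAlignment:
    assert len(q) == len(t)
    return PairwiseAlignment(
        query_row=np.frombuffer(q.encode(), dtype=np.uint8),
        target_row=np.frombuffer(t.encode(), dtype=np.uint8),
        score=0.0,
        origin_state=origin_state,
    )


def brute_force_best_score(a, b, match, mismatch, gap_open, gap_extend):
    """Exhaustive enumeration of all global alignments (affine gaps scored
    as open + (k-1)*extend).  Independent of any DP recurrence."""
    best = -np.inf

    def rec(i, j, state, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            rec(i + 1, j, "Q", score + (gap_extend if state == "Q" else gap_open))
        if j < len(b):
            rec(i, j + 1, "T", score + (gap_extend if state == "T" else gap_open))

    rec(0, 0, "M", 0.0)
    return best


class TestNeedlemanWunsch:
    def test_identical_sequences_align_gap_free(self):
        aln = needleman_wunsch("ACGT", "ACGT", PARAMS)
        assert aln.query_text == "ACGT" and aln.target_text == "ACGT"
        assert aln.score == 4 * PARAMS.match

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            needleman_wunsch("A", "", PARAMS)

    def test_gattaca_linear_gap_matches_enumeration(self):
        params = AlignParams(match=1, mismatch=-1, gap_open=-1, gap_extend=-1)
        aln = needleman_wunsch("GATTACA", "GCATGCT", params)
        expected = brute_force_best_score("GATTACA", "GCATGCT", 1, -1, -1, -1)
        assert aln.score == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_optimal_score_matches_brute_force(self, seed):
        """>= 200 random short pairs: NW score equals the exhaustively
        enumerated optimum under the affine scheme."""
        rng = np.random.default_rng(seed)
        for _ in range(60):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            aln = needleman_wunsch(a, b, PARAMS)
            expected = brute_force_best_score(
                a, b, PARAMS.match, PARAMS.mismatch,
                PARAMS.gap_open, PARAMS.gap_extend,
            )
            assert aln.score == pytest.approx(expected), (a, b)
            # removing gaps recovers both inputs
            assert aln.query_text.replace("-", "") == a
            assert aln.target_text.replace("-", "") == b


class TestLeadingGapFilter:
    def test_clean_head_kept(self):
        assert filter_leading_gaps(aln_from_text("ACGTACGTAC", "ACGTACGTAC"),
                                   PARAMS)

    def test_gap_inside_head_discards(self):
        assert not filter_leading_gaps(
            aln_from_text("AC-TACGTAC", "ACGTACGTAC"), PARAMS
        )

    def test_gap_just_past_head_kept(self):
        # leading_gap_n = 5: a first gap at column 6 is tolerated
        assert filter_leading_gaps(
            aln_from_text("ACGTA-CGTA", "ACGTACCGTA"), PARAMS
        )


class TestBinomialRegion:
    @pytest.mark.parametrize("n", [10, 30, 50])
    @pytest.mark.parametrize("p", [0.3, 0.5, 0.9])
    def test_region_matches_exact_tail_sums(self, n, p):
        """Acceptance bounds agree with direct pmf summation."""
        lo, hi = binomial_acceptance_region(n, p, 0.75)
        alpha = 0.25
        pmf = np.array([binom.pmf(k, n, p) for k in range(n + 1)])
        cdf = np.cumsum(pmf)
        lo_oracle = int(np.searchsorted(cdf, alpha / 2))
        hi_oracle = int(np.searchsorted(cdf, 1 - alpha / 2))
        assert (lo, hi) == (lo_oracle, hi_oracle)
        # the region really carries >= the central mass
        assert cdf[hi] - (cdf[lo - 1] if lo > 0 else 0.0) >= 0.75 - 1e-12


class TestTruncation:
    def test_all_match_alignment_unchanged(self):
        text = "ACGT" * 100
        aln = aln_from_text(text, text)
        out = truncate_on_identity_change(aln, PARAMS)
        assert out is aln

    def test_divergence_clipped_within_one_window(self):
        """200 matched columns then 200 columns at ~25% identity: the clip
        point lands within one window of the changepoint."""
        rng = np.random.default_rng(3)
        bases = list("ACGT")
        head = "".join(rng.choice(bases, size=200))
        tail_q = "".join(rng.choice(bases, size=200))
        tail_t = "".join(rng.choice(bases, size=200))
        aln = aln_from_text(head + tail_q, head + tail_t)
        out = truncate_on_identity_change(aln, PARAMS)
        assert out is not None
        assert 200 - PARAMS.window <= len(out) <= 200 + PARAMS.window

    def test_early_clip_discards_short_alignment(self):
        rng = np.random.default_rng(4)
        bases = list("ACGT")
        head = "".join(rng.choice(bases, size=60))
        aln = aln_from_text(
            head + "".join(rng.choice(bases, size=140)),
            head + "".join(rng.choice(bases, size=140)),
        )
        # clip point near column 60 < min_clipped=100 -> discarded
        assert truncate_on_identity_change(aln, PARAMS) is None

    def test_truncation_is_idempotent(self):
        rng = np.random.default_rng(5)
        bases = list("ACGT")
        for trial in range(10):
            q = rng.choice(bases, size=300)
            t = q.copy()
            flip = rng.random(300) < 0.3
            t[flip] = rng.choice(bases, size=int(flip.sum()))
            aln = aln_from_text("".join(q), "".join(t))
            once = truncate_on_identity_change(aln, PARAMS)
            if once is None:
                continue
            twice = truncate_on_identity_change(once, PARAMS)
            assert twice is not None and len(twice) == len(once)


class TestWindowStatistics:
    def test_all_match_balanced_window(self):
        text = "ACGT" * 15
        ws = window_statistics(aln_from_text(text, text), PARAMS)
        assert len(ws) == 1  # trailing partial window dropped
        w = ws[0]
        assert w.identity_raw == 1.0
        assert w.identity_gc == 1.0
        assert w.indel_frac == 0.0
        # 50 columns of the ACGT repeat: near-balanced composition
        assert w.chance_match == pytest.approx(0.25, abs=0.001)

    def test_indel_fraction_toy_alignment_by_hand(self):
        """(A,A)(C,C)(G,-)(G,G)(T,T): 3 adjacent non-gap pairs, 2 without an
        intervening gap -> q = 2/3, p = 1/3."""
        q = np.frombuffer(b"ACGGT", dtype=np.uint8)
        t = np.frombuffer(b"AC-GT", dtype=np.uint8)
        assert indel_fraction(q, t) == pytest.approx(1.0 / 3.0)
        w = _window_stats_arrays(q, t)
        assert w.indel_frac == pytest.approx(1.0 / 3.0)
        assert w.identity_raw == 1.0  # 4 matching non-gap columns

    def test_geometric_pmf_against_run_length_enumeration(self):
        """Build an alignment from a known geometric indel process, estimate
        p from q, and compare the implied pmf with the enumerated run-length
        distribution."""
        p_true = 1.0 / 3.0
        rng = np.random.default_rng(11)
        q_parts, t_parts, runs = [], [], []
        for _ in range(4000):
            q_parts.append("A")
            t_parts.append("A")
            run = rng.geometric(1.0 - p_true) - 1  # P(L=l) = p^l (1-p)
            runs.append(run)
            q_parts.append("C" * run)
            t_parts.append("-" * run)
        q_parts.append("A")
        t_parts.append("A")
        q = np.frombuffer("".join(q_parts).encode(), dtype=np.uint8)
        t = np.frombuffer("".join(t_parts).encode(), dtype=np.uint8)
        p_hat = indel_fraction(q, t)
        assert p_hat == pytest.approx(np.mean(np.asarray(runs) > 0), abs=1e-12)
        counts = np.bincount(runs, minlength=4)
        freq = counts / counts.sum()
        for l in range(3):
            assert geometric_indel_pmf(l, p_hat) == pytest.approx(
                freq[l], abs=0.03
            )
        assert geometric_indel_pmf(1, 1.0 / 3.0) == pytest.approx(2.0 / 9.0)

    def test_window_match_counts_sum_to_alignment_total(self):
        rng = np.random.default_rng(6)
        bases = list("ACGT")
        q = rng.choice(bases, size=237)
        t = q.copy()
        flip = rng.random(237) < 0.4
        t[flip] = rng.choice(bases, size=int(flip.sum()))
        aln = aln_from_text("".join(q), "".join(t))
        ws = window_statistics(aln, PARAMS)
        k = len(ws) * PARAMS.window
        direct = int((aln.query_row[:k] == aln.target_row[:k]).sum())
        # gap-free alignment: every column is valid, so per-window match
        # counts are identity_raw * window and must sum to the direct count
        assert sum(round(x.identity_raw * x.n_cols) for x in ws) == direct

    def test_gc_corrected_identity_properties(self):
        # chance identity maps to the floor, perfect identity to 1
        assert gc_corrected_identity(0.25, 0.25) == 0.25
        assert gc_corrected_identity(1.0, 0.25) == 1.0
        # monotone in raw identity at fixed composition
        grid = np.linspace(0, 1, 21)
        vals = [gc_corrected_identity(x, 0.3) for x in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_short_alignment_yields_no_windows(self):
        text = "ACGT" * 10  # 40 columns < window
        assert window_statistics(aln_from_text(text, text), PARAMS) == []

    def test_params_invariants_enforced(self):
        with pytest.raises(ValueError):
            AlignParams(window=5)
        with pytest.raises(ValueError):
            AlignParams(min_clipped=40, window=50)
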