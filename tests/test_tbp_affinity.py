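"""Affinity model: matrix loading, log-odds scoring, KD calibration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tatakd as tk
from tatakd.tbp_affinity import MatrixFormatError, Strand, scan_best_window

from conftest import TOY_MATRIX_TEXT, random_dna


def brute_best(seq, matrix):
    """Independent exhaustive scan: score every window on both strands
    with plain-Python log sums; forward strand wins ties, then the
    smaller forward start."""
    w = matrix.width
    best = (-math.inf, None, None)
    probs = {b: matrix.probs[:, "ACGT".index(b)] for b in "ACGT"}
    bg = {b: matrix.background["ACGT".index(b)] for b in "ACGT"}

    def score(window):
        return sum(math.log(probs[b][j] / bg[b]) for j, b in enumerate(window))

    n = len(seq)
    fwd = [(score(seq[s - 1:s - 1 + w]), s) for s in range(1, n - w + 2)]
    rc = tk.reverse_complement(seq)
    rev = [(score(rc[j:j + w]), n - w - j + 1) for j in range(n - w + 1)]
    best_f = max(fwd, key=lambda c: (c[0], -c[1]))
    best_r = max(rev, key=lambda c: (c[0], -c[1]))
    # forward strand wins unless reverse is strictly better (same tie
    # tolerance the scanner documents)
    if best_r[0] > best_f[0] + 1e-12:
        best, strand = best_r, Strand.REVERSE
    else:
        best, strand = best_f, Strand.FORWARD
    s_norm = min(1.0, max(0.0, best[0] / matrix.max_score))
    return s_norm, best[1], strand


class TestLoadMatrix:
    def test_probability_table_preserved(self, default_matrix):
        # packaged matrix: pseudocount slightly flattens, consensus intact
        assert default_matrix.width == 15
        assert default_matrix.consensus[3:11] == "TATAAAAA"
        assert np.allclose(default_matrix.probs.sum(axis=1), 1.0)

    def test_count_normalization_matches_hand_value(self, toy_matrix):
        # column 1 counts A=10, C=2, G=1, T=1; pseudocount 0.01
        expected_a = 10.01 / (14 + 0.04)
        assert toy_matrix.probs[0, 0] == pytest.approx(expected_a, rel=1e-12)

    def test_zero_column_becomes_uniform(self, toy_matrix):
        # column 3 has counts (0, 0, 12, 0); a zero count is pseudocount-only
        assert toy_matrix.probs[2, 0] == pytest.approx(
            0.01 / 12.04, rel=1e-12)

    @pytest.mark.parametrize("text, msg", [
        ("A 1 2\nC 1 2\nG 1 2\nT 1 2\n", "width"),
        ("A 1 2 3 4 5 x\nC 1 2 3 4 5 6\nG 1 2 3 4 5 6\nT 1 2 3 4 5 6\n",
         "non-numeric"),
        ("A 1 2 3 4 5 -6\nC 1 2 3 4 5 6\nG 1 2 3 4 5 6\nT 1 2 3 4 5 6\n",
         "negative"),
        ("A 1 2 3 4 5 6\nC 1 2 3 4 5 6\nG 1 2 3 4 5 6\n", "need rows"),
    ])
    def test_malformed_sources_rejected(self, tmp_path, text, msg):
        p = tmp_path / "bad.txt"
        p.write_text(text)
        with pytest.raises(MatrixFormatError, match=msg):
            tk.load_matrix(p)


class TestScoring:
    def test_consensus_scores_s_max(self, toy_matrix):
        s = tk.log_odds_score(toy_matrix.consensus, toy_matrix)
        assert s == pytest.approx(toy_matrix.max_score, rel=1e-12)
        assert tk.normalized_site_score(toy_matrix.consensus, toy_matrix) == 1.0

    def test_every_width6_window_matches_plain_sum(self, toy_matrix):
        # exhaustive check over a sample of the 4^6 window space
        rng = np.random.default_rng(7)
        windows = ["".join(w) for w in itertools.product("ACGT", repeat=6)]
        for w in rng.choice(windows, size=300, replace=False):
            expected = sum(
                math.log(toy_matrix.probs[j, "ACGT".index(b)] / 0.25)
                for j, b in enumerate(w)
            )
            assert tk.log_odds_score(w, toy_matrix) == pytest.approx(
                expected, rel=1e-12)

    def test_uniform_matrix_scores_zero_and_is_degenerate(self):
        m = tk.TataMatrix(probs=np.full((6, 4), 0.25),
                          background=np.full(4, 0.25))
        assert tk.log_odds_score("ACGTAC", m) == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            tk.normalized_site_score("ACGTAC", m)

    def test_negative_scores_clip_to_zero(self, toy_matrix):
        # anti-consensus window: least likely base everywhere
        anti = "".join("ACGT"[int(np.argmin(col))] for col in toy_matrix.probs)
        assert tk.log_odds_score(anti, toy_matrix) < 0
        assert tk.normalized_site_score(anti, toy_matrix) == 0.0

    def test_ambiguous_base_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="non-ACGT"):
            tk.log_odds_score("ACGTAN", toy_matrix)


class TestReverseComplement:
    @pytest.mark.parametrize("seq, expected", [
        ("ACGT", "ACGT"),
        ("TATAAA", "TTTATA"),
        ("AAAA", "TTTT"),
    ])
    def test_known_values(self, seq, expected):
        assert tk.reverse_complement(seq) == expected

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    def test_involution(self, seq):
        assert tk.reverse_complement(tk.reverse_complement(seq)) == seq

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            tk.reverse_complement("ACGN")


class TestEstimateKd:
    def test_consensus_site_hits_specific_anchor(self, default_matrix, anchors):
        seq = "G" * 40 + default_matrix.consensus + "G" * (50 - 15)
        est = tk.estimate_kd(seq, default_matrix, anchors)
        assert est.kd == anchors.kd_specific
        assert est.best_score == 1.0

    def test_all_g_hits_nonspecific_anchor(self, default_matrix, anchors):
        est = tk.estimate_kd("G" * 90, default_matrix, anchors)
        assert est.kd == anchors.kd_nonspecific
        assert est.best_score == 0.0

    def test_half_score_interpolates_to_1e7(self, default_matrix, anchors):
        # ln KD is linear in the normalised score: s*=0.5 -> 1e-7 M
        ln = (math.log(anchors.kd_nonspecific)
              + 0.5 * (math.log(anchors.kd_specific)
                       - math.log(anchors.kd_nonspecific)))
        assert math.exp(ln) == pytest.approx(1e-7, rel=1e-12)

    def test_kd_bounded_by_anchors(self, default_matrix, anchors):
        rng = np.random.default_rng(11)
        for _ in range(50):
            est = tk.estimate_kd(random_dna(rng), default_matrix, anchors)
            assert anchors.kd_specific <= est.kd <= anchors.kd_nonspecific
            assert 1 <= est.best_start <= 90 - default_matrix.width + 1
            assert est.ln_kd == pytest.approx(math.log(est.kd), rel=1e-12)

    def test_wrong_length_rejected(self, default_matrix):
        with pytest.raises(ValueError, match="length"):
            tk.estimate_kd("ACGT", default_matrix)

    def test_strand_symmetry(self, default_matrix, anchors):
        rng = np.random.default_rng(23)
        for _ in range(50):
            seq = random_dna(rng)
            kd_f = tk.estimate_kd(seq, default_matrix, anchors).kd
            kd_r = tk.estimate_kd(
                tk.reverse_complement(seq), default_matrix, anchors).kd
            assert kd_f == pytest.approx(kd_r, rel=1e-9)

    def test_scan_matches_brute_force_oracle(self, toy_matrix):
        rng = np.random.default_rng(31)
        for _ in range(50):
            seq = random_dna(rng)
            score, start, strand = scan_best_window(seq, toy_matrix)
            o_score, o_start, o_strand = brute_best(seq, toy_matrix)
            assert score == pytest.approx(o_score, abs=1e-10)
            assert (start, strand) == (o_start, o_strand)

    def test_mutation_toward_consensus_never_weakens_binding(
            self, default_matrix, anchors):
        # repair a degraded planted site base by base; kd must not rise
        rng = np.random.default_rng(47)
        cons = default_matrix.consensus
        degraded = tk.degrade_to_score(cons, 0.3, default_matrix, rng)
        seq = list("G" * 90)
        start = 30  # 0-based insert position
        seq[start:start + 15] = degraded
        prev_kd = tk.estimate_kd("".join(seq), default_matrix, anchors).kd
        for j, base in enumerate(cons):
            seq[start + j] = base
            kd = tk.estimate_kd("".join(seq), default_matrix, anchors).kd
            assert kd <= prev_kd + 1e-18
            prev_kd = kd
        assert prev_kd == anchors.kd_specific

    def test_planted_consensus_always_wins(self, default_matrix, anchors):
        rng = np.random.default_rng(53)
        for _ in range(20):
            seq = list(random_dna(rng))
            pos = int(rng.integers(0, 90 - 15 + 1))
            seq[pos:pos + 15] = default_matrix.consensus
            est = tk.estimate_kd("".join(seq), default_matrix, anchors)
            assert est.kd == anchors.kd_specific
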