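"""Entropy and mutual-information spectra against analytic values and
brute-force oracles."""

import math

import numpy as np
import pytest

import _oracles as oracle
from conftest import make_alignment, random_alignment
from infospectra import (
    LN4,
    JointDistribution,
    SpectrumConfig,
    column_entropy,
    hmi_single_sequence,
    hmi_spectrum,
    joint_distribution_vertical,
    mutual_information,
    vertical_entropy_spectrum,
    vmi_matrix,
)


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "column, expected_nat",
        [
            ("A" * 8, 0.0),  # conserved
            ("AAAAGGGG", math.log(2)),  # 50/50 two-state, 0.693 nat
            ("AACCGGTT", math.log(4)),  # equiprobable, 1.386 nat = 1 MER
        ],
    )
    def test_analytic_values(self, column, expected_nat):
        v, _ = column_entropy(column)
        assert v == pytest.approx(expected_nat, abs=1e-12)

    def test_max_entropy_is_one_mer(self):
        v, _ = column_entropy("AACCGGTT", SpectrumConfig(unit="MER"))
        assert v == pytest.approx(1.0, abs=1e-12)

    def test_bias_correction_adds_roulston_term(self):
        # H + (M-1)/(2N) = ln 2 + 1/16
        v, _ = column_entropy("AAAAGGGG", SpectrumConfig(bias_correction=True))
        assert v == pytest.approx(math.log(2) + 1 / 16, abs=1e-12)

    def test_bias_correction_noop_for_one_state(self):
        plain, _ = column_entropy("AAAA")
        corr, _ = column_entropy("AAAA", SpectrumConfig(bias_correction=True))
        assert plain == corr == 0.0

    def test_se_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            col = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 12)))
            _, se = column_entropy(col)
            assert se == pytest.approx(oracle.entropy_se_nat(col), abs=1e-12)

    def test_empty_column_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            column_entropy("")

    def test_unit_round_trip(self):
        nat, _ = column_entropy("AAGGCCTT")
        mnat, _ = column_entropy("AAGGCCTT", SpectrumConfig(unit="mnat"))
        mer, _ = column_entropy("AAGGCCTT", SpectrumConfig(unit="MER"))
        assert mnat == pytest.approx(nat * 1000, rel=1e-15)
        assert mer == pytest.approx(nat / LN4, rel=1e-15)


class TestVerticalSpectrum:
    def test_worked_example_profile(self, worked_alignment):
        s = vertical_entropy_spectrum(worked_alignment)
        assert list(s.index) == [1, 2, 3, 4]
        assert s.values[0] == pytest.approx(0.0, abs=1e-12)
        assert s.values[1] == pytest.approx(0.693, abs=5e-4)
        assert s.values[3] == pytest.approx(1.386, abs=5e-4)
        # third column more polymorphic than the second, less than the fourth
        assert s.values[1] < s.values[2] < s.values[3]

    def test_constant_alignment_is_zero(self, aln):
        s = vertical_entropy_spectrum(aln(["ACGT"] * 5))
        assert np.allclose(s.values, 0.0)
        assert np.allclose(s.se, 0.0)

    def test_single_column_composes_column_entropy(self, aln):
        a = aln(["A", "A", "G"])
        s = vertical_entropy_spectrum(a)
        assert len(s) == 1
        assert s.values[0] == pytest.approx(column_entropy("AAG")[0], abs=1e-15)

    def test_bound_ln4_per_word(self, aln):
        a = aln(["AC", "GT", "CA", "TG"])
        for nol in (1, 2):
            s = vertical_entropy_spectrum(a, SpectrumConfig(nol=nol))
            assert (s.values <= nol * LN4 + 1e-12).all()

    def test_word_spectrum_matches_oracle(self, aln):
        rows = ["ACGTAC", "ACGGAC", "TCGTAA", "ACTTAC"]
        for nol in (1, 2, 3):
            s = vertical_entropy_spectrum(make_alignment(rows), SpectrumConfig(nol=nol))
            assert np.allclose(s.values, oracle.vh_spectrum(rows, nol=nol), atol=1e-12)


class TestJointAndMI:
    def test_bijective_pairing(self, aln):
        a = aln(["AC", "AC", "AC", "AC", "GT", "GT", "GT", "GT"])
        jd = joint_distribution_vertical(a, 0, 1)
        p = jd.p_mn
        assert p[0, 1] == pytest.approx(0.5)  # A -> C
        assert p[2, 3] == pytest.approx(0.5)  # G -> T
        assert p.sum() == pytest.approx(1.0)
        mi, _ = mutual_information(jd)
        hx, _ = column_entropy([r.residues[0] for r in a.records])
        assert mi == pytest.approx(hx, abs=1e-12) == pytest.approx(math.log(2), abs=1e-12)

    def test_same_position_rejected(self, aln):
        with pytest.raises(ValueError, match="i < j"):
            joint_distribution_vertical(aln(["AC"]), 1, 1)

    def test_overlapping_words_rejected(self, aln):
        with pytest.raises(ValueError, match="overlap"):
            joint_distribution_vertical(aln(["ACGT"]), 0, 1, nol=2)

    def test_probabilities_are_count_multiples(self, aln):
        a = aln(["AC"] * 3 + ["GT"] * 5)
        jd = joint_distribution_vertical(a, 0, 1)
        assert jd.N == 8
        assert np.allclose((jd.p_mn * 8) % 1, 0)

    def test_product_distribution_gives_zero(self):
        # independent halves: p_mn = p_m * p_n exactly
        counts = np.outer([2, 2, 0, 0], [1, 3, 0, 0])
        mi, _ = mutual_information(JointDistribution(counts))
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_quarter_table_is_ln4(self):
        mi, _ = mutual_information(JointDistribution(np.eye(4, dtype=int) * 2))
        assert mi == pytest.approx(LN4, abs=1e-12)

    def test_identity_route_equals_direct_sum(self):
        """MI via H(i)+H(j)-H(i,j) equals the direct plug-in sum."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            counts = rng.integers(0, 5, size=(4, 4))
            if counts.sum() == 0:
                continue
            pairs = [
                (m, n) for m in range(4) for n in range(4) for _ in range(counts[m, n])
            ]
            direct, _ = mutual_information(JointDistribution(counts))
            assert direct == pytest.approx(oracle.mi_via_entropies(pairs), abs=1e-12)

    def test_bias_and_se_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            counts = rng.integers(0, 4, size=(4, 4))
            if counts.sum() < 2:
                continue
            pairs = [
                (m, n) for m in range(4) for n in range(4) for _ in range(counts[m, n])
            ]
            mi, se = mutual_information(
                JointDistribution(counts), SpectrumConfig(bias_correction=True)
            )
            assert mi == pytest.approx(oracle.mi_nat(pairs, bias=True), abs=1e-12)
            assert se == pytest.approx(oracle.mi_se_nat(pairs), abs=1e-12)


class TestVMIMatrix:
    def test_pair_count_for_four_columns(self, worked_alignment):
        m = vmi_matrix(worked_alignment)
        assert len(m) == 6  # C(4,2)

    def test_constant_alignment_all_zero(self, aln):
        m = vmi_matrix(aln(["ACGT"] * 6))
        assert np.allclose(m.values, 0.0)

    def test_planted_pair_is_unique_nonzero(self, aln):
        rows = []
        for x, y in [("A", "T"), ("A", "T"), ("C", "G"), ("C", "G")] * 2:
            rows.append("AAA" + x + "CCC" + y + "GG")
        m = vmi_matrix(make_alignment(rows))
        assert m.argmax == (4, 8)  # 1-based
        nz = np.abs(m.values) > 1e-12
        assert nz.sum() == 1

    def test_symmetry_under_input_swap(self, aln):
        a = aln(["ACGT", "AGCT", "TCGA", "ACGA", "GCGT"])
        m = vmi_matrix(a)
        for i, j, v in zip(m.i, m.j, m.values):
            jd = joint_distribution_vertical(a, int(i), int(j))
            swapped = JointDistribution(jd.counts.T)
            assert mutual_information(swapped)[0] == pytest.approx(v, abs=1e-12)

    def test_bounded_by_min_marginal_entropy(self, aln):
        rng = np.random.default_rng(11)
        a = random_alignment(rng, n=6, L=8)
        m = vmi_matrix(a)
        s = vertical_entropy_spectrum(a)
        for i, j, v in zip(m.i, m.j, m.values):
            assert -1e-12 <= v <= min(s.values[i], s.values[j]) + 1e-9

    def test_matches_oracle_with_bias_and_se(self):
        rng = np.random.default_rng(13)
        for bias in (False, True):
            a = random_alignment(rng, n=5, L=7)
            rows = [r.residues for r in a.records]
            m = vmi_matrix(a, SpectrumConfig(bias_correction=bias))
            want = oracle.vmi(rows, bias=bias)
            got = {(int(i), int(j)): v for i, j, v in zip(m.i, m.j, m.values)}
            assert got.keys() == want.keys()
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-12)


class TestHMI:
    def test_periodic_sequence_saturates(self):
        assert hmi_single_sequence("ACGT" * 10, 4) == pytest.approx(LN4, abs=1e-12)

    def test_constant_sequence_is_zero(self):
        assert hmi_single_sequence("A" * 30, 5) == pytest.approx(0.0, abs=1e-15)

    def test_lag_bounds(self):
        with pytest.raises(ValueError, match="k must be >= 3"):
            hmi_single_sequence("ACGTACGT", 2)
        with pytest.raises(ValueError, match="no word pairs"):
            hmi_single_sequence("ACGTA", 5)

    def test_matches_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(12, 30)))
            k = int(rng.integers(3, 6))
            for bias in (False, True):
                got = hmi_single_sequence(seq, k, SpectrumConfig(bias_correction=bias))
                assert got == pytest.approx(oracle.hmi(seq, k, bias=bias), abs=1e-12)

    def test_spectrum_lag_range_and_se(self, aln):
        a = aln(["ACGTACGTACGT"] * 4)
        s = hmi_spectrum(a)
        assert list(s.index) == list(range(3, 7))
        assert np.allclose(s.se, 0.0)  # identical sequences: zero ensemble spread
        assert s.values[1] == pytest.approx(LN4, abs=1e-12)  # k=4 periodicity

    def test_spectrum_is_ensemble_mean(self, aln):
        rows = ["ACGTACGTAC", "AAGTACGTAC", "ACGTTCGTAC"]
        s = hmi_spectrum(make_alignment(rows))
        want = oracle.hmi_spectrum(rows)
        assert np.allclose(s.values, [want[k] for k in s.index], atol=1e-12)

    def test_too_short_alignment_is_error(self, aln):
        with pytest.raises(ValueError, match="< 6"):
            hmi_spectrum(aln(["ACGTA"] * 3))


class TestOracleEquivalence:
    """All three spectra agree exactly with brute-force enumeration on
    small random alignments."""

    def test_sampled_alignments(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            a = random_alignment(rng)
            rows = [r.residues for r in a.records]
            bias = bool(rng.integers(2))
            cfg = SpectrumConfig(bias_correction=bias)
            vh = vertical_entropy_spectrum(a, cfg)
            assert np.allclose(vh.values, oracle.vh_spectrum(rows, bias=bias), atol=1e-12)
            m = vmi_matrix(a, cfg)
            want = oracle.vmi(rows, bias=bias)
            for i, j, v in zip(m.i, m.j, m.values):
                assert v == pytest.approx(want[(int(i), int(j))], abs=1e-12)
            if a.L >= 6:
                hs = hmi_spectrum(a, cfg)
                want_h = oracle.hmi_spectrum(rows, bias=bias)
                assert np.allclose(hs.values, [want_h[k] for k in hs.index], atol=1e-12)
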