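import math

import numpy as np
import pytest

from phosctx.features import (
    ACH_WINDOW_SIZES,
    SWEET_EISENBERG,
    TAYLOR_CLASSES,
    FeatureLayout,
    ach,
    assemble_feature_vector,
    background_vector,
    profile_from_psiblast,
    read_residue_table,
    relative_entropy,
    residue_level_features,
    shannon_entropy,
    taylor_op,
)
from phosctx.seqio import STANDARD_AA, ProteinRecord
from phosctx.synthetic import synthetic_profile_provider


def random_simplex(rng, n=20):
    return rng.dirichlet(np.ones(n))


class TestShannonEntropy:
    def test_uniform_is_maximal(self):
        assert shannon_entropy(np.full(20, 0.05)) == pytest.approx(math.log2(20), abs=1e-12)

    def test_one_hot_is_zero(self):
        row = np.zeros(20)
        row[3] = 1.0
        assert shannon_entropy(row) == 0.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.zeros(20))

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(200):
            p = random_simplex(rng)
            expected = 0.0
            for a in range(20):
                if p[a] > 0:
                    expected -= p[a] * math.log2(p[a])
            assert abs(shannon_entropy(p) - expected) < 1e-12

    def test_permutation_invariance(self, rng):
        p = random_simplex(rng)
        assert shannon_entropy(p) == pytest.approx(
            shannon_entropy(rng.permutation(p)), abs=1e-12
        )

    def test_bounds(self, rng):
        for _ in range(50):
            h = shannon_entropy(random_simplex(rng))
            assert 0 <= h <= math.log2(20) + 1e-12


class TestRelativeEntropy:
    def test_identity_is_zero(self, rng):
        for _ in range(20):
            p = random_simplex(rng)
            assert relative_entropy(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_vs_uniform_closed_form(self):
        p = np.zeros(20)
        p[7] = 1.0
        q = np.full(20, 0.05)
        assert relative_entropy(p, q) == pytest.approx(math.log2(20), abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        q = background_vector()
        for _ in range(200):
            p = random_simplex(rng)
            expected = sum(
                p[a] * math.log2(p[a] / q[a]) for a in range(20) if p[a] > 0
            )
            assert abs(relative_entropy(p) - expected) < 1e-12

    def test_zero_background_under_support_errors(self):
        p = np.full(20, 0.05)
        q = np.full(20, 1 / 19)
        q[0] = 0.0
        with pytest.raises(ValueError):
            relative_entropy(p, q)

    def test_non_negative(self, rng):
        for _ in range(100):
            assert relative_entropy(random_simplex(rng)) >= 0


class TestTaylorOP:
    def test_all_standard_letters_give_10_bits(self):
        for aa in STANDARD_AA:
            v = taylor_op(aa)
            assert v.shape == (10,)
            assert set(np.unique(v)) <= {0.0, 1.0}

    def test_unknown_letter_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.array_equal(taylor_op("X"), np.zeros(10))

    def test_glycine_matches_membership_table(self):
        v = taylor_op("G")
        expected = [1.0 if "G" in members else 0.0 for _, members in TAYLOR_CLASSES]
        assert np.array_equal(v, expected)
        # glycine is hydrophobic (Taylor), small and tiny; nothing else
        assert v.sum() == 3

    def test_proline_only_in_proline_and_small(self):
        v = taylor_op("P")
        assert v[2] == 1 and v[9] == 1 and v.sum() == 2


class TestACH:
    def test_homopolymer_all_windows_equal_index(self):
        seq = "A" * 21
        v = ach(seq, 10)
        assert np.allclose(v, SWEET_EISENBERG["A"], atol=1e-12)

    def test_output_length(self):
        assert ach("MKVLASTGY", 4).shape == (len(ACH_WINDOW_SIZES),)

    def test_matches_explicit_loop_oracle(self, rng):
        letters = list(STANDARD_AA)
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=25))
            i = int(rng.integers(0, 25))
            got = ach(seq, i)
            for k, w in enumerate(ACH_WINDOW_SIZES):
                m = w // 2
                vals = [
                    SWEET_EISENBERG[seq[j]]
                    for j in range(max(0, i - m), min(len(seq), i + m + 1))
                ]
                assert abs(got[k] - sum(vals) / len(vals)) < 1e-12

    def test_boundary_truncation(self):
        seq = "MKVLASTGY"
        got = ach(seq, 0)
        for k, w in enumerate(ACH_WINDOW_SIZES):
            m = w // 2
            vals = [SWEET_EISENBERG[c] for c in seq[: m + 1]]
            assert got[k] == pytest.approx(sum(vals) / len(vals), abs=1e-12)

    def test_zero_padding_option(self):
        seq = "MKV"
        got = ach(seq, 0, boundary="zero")
        vals = sum(SWEET_EISENBERG[c] for c in "MK")  # window size 3: positions -1,0,1
        assert got[0] == pytest.approx(vals / 3, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            ach("MKV", 5)


PSSM_FIXTURE = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
           A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M   -2 -2 -3 -4 -2 -1 -3 -3 -2  1  2 -2  8 -1 -3 -2 -1 -2 -2  0   0  0  0  0  0  0  0  0  0  0  0  0 100  0  0  0  0  0  0  0
    2 K   -1  2  0 -1 -4  1  1 -2 -1 -3 -3  5 -2 -4 -1 -1 -1 -4 -2 -3   6  10  4  2  0  4  8  2  2  2  2 50  0  0  2  4  2  0  0  0
    3 V    0 -3 -3 -4 -1 -3 -3 -4 -4  3  1 -3  1 -1 -3 -2  0 -3 -1  4   4  0  0  0  2  0  0  0  0 20 10  0  2  2  0  2  6  0  2 50

                      K         Lambda
Standard Ungapped    0.1358     0.3172
"""


class TestPsiblastProfile:
    def test_fixture_values_and_normalisation(self, tmp_path):
        p = tmp_path / "prof.pssm"
        p.write_text(PSSM_FIXTURE)
        wop = profile_from_psiblast(p)
        assert wop.shape == (3, 20)
        assert np.allclose(wop.sum(axis=1), 1.0, atol=1e-12)
        # row 1 is one-hot on M
        assert wop[0, STANDARD_AA.index("M")] == 1.0
        # row 2: K has 50 of 100 -> 0.5
        assert wop[1, STANDARD_AA.index("K")] == pytest.approx(0.5)

    def test_all_zero_row_replaced_by_background(self, tmp_path):
        fixture = PSSM_FIXTURE.replace(
            "   0  0  0  0  0  0  0  0  0  0  0  0 100  0  0  0  0  0  0  0",
            "   0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0",
        )
        p = tmp_path / "prof.pssm"
        p.write_text(fixture)
        with pytest.warns(UserWarning):
            wop = profile_from_psiblast(p)
        assert np.allclose(wop[0], background_vector(), atol=1e-12)

    def test_malformed_file_errors(self, tmp_path):
        p = tmp_path / "bad.pssm"
        p.write_text("not a profile at all\n")
        with pytest.raises(ValueError):
            profile_from_psiblast(p)


class TestResidueTable:
    def test_reads_disorder_and_ss3(self, tmp_path):
        p = tmp_path / "diso.tsv"
        p.write_text("# comment\n1 M 0.9\n2 K 0.1\n")
        assert np.allclose(read_residue_table(p, 1), [[0.9], [0.1]])
        p2 = tmp_path / "ss3.tsv"
        p2.write_text("1 M 0.2 0.3 0.5\n")
        assert np.allclose(read_residue_table(p2, 3), [[0.2, 0.3, 0.5]])


class TestSyntheticProfile:
    def test_determinism_and_normalisation(self):
        rec = ProteinRecord("P1", "MKVLASTGY")
        a = synthetic_profile_provider(rec, seed=7)
        b = synthetic_profile_provider(rec, seed=7)
        assert np.array_equal(a.wop, b.wop)
        assert np.array_equal(a.disorder, b.disorder)
        assert np.allclose(a.wop.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((a.disorder >= 0) & (a.disorder <= 1))

    def test_pure_one_hot_limit_has_zero_entropy(self):
        rec = ProteinRecord("P1", "MKVLASTGY")
        prof = synthetic_profile_provider(rec, seed=7, mix=1.0)
        for i in range(len(rec.sequence)):
            assert shannon_entropy(prof.wop[i]) == pytest.approx(0.0, abs=1e-12)


class TestAssembly:
    def make_inputs(self):
        rec = ProteinRecord("P1", "MKVLASTGYRRSAKEDLLMV")
        prof = synthetic_profile_provider(rec, seed=3)
        return rec, prof

    def test_total_length_126_with_dim_100(self, rng):
        rec, prof = self.make_inputs()
        fv = assemble_feature_vector(rec, 6, prof, rng.normal(size=100))
        assert len(fv) == 126

    def test_group_layout_partitions_vector(self, rng):
        rec, prof = self.make_inputs()
        fv = assemble_feature_vector(rec, 6, prof, rng.normal(size=100))
        slices = fv.layout.slices()
        recomposed = np.concatenate([fv.values[slices[n]] for n, _ in fv.layout.groups])
        assert np.array_equal(recomposed, fv.values)
        assert fv.layout.names()[:4] == ["shannon", "rel_entropy", "diso", "pss_0"]

    def test_context_independent_of_residue_block(self, rng):
        rec, prof = self.make_inputs()
        ctx = rng.normal(size=100)
        fv1 = assemble_feature_vector(rec, 6, prof, ctx)
        fv2 = assemble_feature_vector(rec, 6, prof, np.zeros(100))
        assert np.array_equal(fv1.values[:26], fv2.values[:26])
        assert np.array_equal(fv2.group("context"), np.zeros(100))

    def test_deterministic_assembly(self, rng):
        rec, prof = self.make_inputs()
        ctx = rng.normal(size=100)
        a = assemble_feature_vector(rec, 6, prof, ctx)
        b = assemble_feature_vector(rec, 6, prof, ctx)
        assert np.array_equal(a.values, b.values)

    def test_residue_block_is_26(self):
        rec, prof = self.make_inputs()
        assert residue_level_features(rec, 6, prof).shape == (26,)

    def test_layout_total(self):
        assert FeatureLayout(100).total == 126
        assert FeatureLayout(64).total == 90
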