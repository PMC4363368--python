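import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsppred.aaindex import (
    AAIndexTable,
    curated_table,
    default_table,
    read_aaindex_flatfile,
    synthetic_screening_table,
    write_aaindex_flatfile,
)
from qsppred.features import (
    EncodingError,
    EncodingSpec,
    encode,
    encode_aac,
    encode_binary,
    encode_dpc,
    encode_peptide,
    encode_physico,
    hybrid,
    select_top_indices,
    physico_spec,
)
from qsppred.seqio import AMINO_ACIDS, AA_INDEX, Peptide, PeptideSet, scramble

peptide_seqs = st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=50)


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac("AAAAA")
        assert v[AA_INDEX["A"]] == 1.0 and v.sum() == 1.0

    def test_uniform(self):
        v = encode_aac("ACDE")
        np.testing.assert_allclose(sorted(v)[-4:], [0.25] * 4)
        assert np.count_nonzero(v) == 4

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seq=peptide_seqs)
    def test_sums_to_one_and_scramble_invariant(self, seq):
        s = PeptideSet([Peptide("p", seq)])
        v1 = encode_aac(s[0])
        v2 = encode_aac(scramble(s, 1)[0])
        assert abs(v1.sum() - 1.0) < 1e-9
        np.testing.assert_array_equal(v1, v2)


class TestDPC:
    def test_single_dipeptide_type(self):
        v = encode_dpc("AAA")
        assert v[0] == 1.0 and v.sum() == 1.0  # AA is first in row-major order

    def test_overlapping_counts_hand_check(self):
        # "ACAC": dipeptides AC, CA, AC -> AC 2/3, CA 1/3
        v = encode_dpc("ACAC")
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["C"]] == pytest.approx(2 / 3)
        assert v[AA_INDEX["C"] * 20 + AA_INDEX["A"]] == pytest.approx(1 / 3)

    def test_not_scramble_invariant_witness(self):
        assert not np.array_equal(encode_dpc("ACAC"), encode_dpc("AACC"))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seq=peptide_seqs)
    def test_normalization(self, seq):
        assert abs(encode_dpc(seq).sum() - 1.0) < 1e-9

    def test_length_precondition(self):
        with pytest.raises(EncodingError):
            encode_dpc("A")


class TestBinary:
    def test_one_hot_structure(self):
        v = encode_binary("ACDEFGHIKL", 5, 5)
        assert v.shape == (200,) and v.sum() == 10
        assert set(np.unique(v)) == {0.0, 1.0}
        # each 20-slot block has exactly one 1
        assert all(v[20 * i : 20 * (i + 1)].sum() == 1 for i in range(10))

    def test_full_overlap_for_length_five(self):
        v = encode_binary("ACDEF", 5, 5)
        np.testing.assert_array_equal(v[:100], v[100:])

    def test_too_short_rejected(self):
        with pytest.raises(EncodingError):
            encode_binary("ACDE", 5, 5)

    def test_n_and_c_blocks_encode_the_right_residues(self):
        v = encode_binary("ACDEFGHIKL", 2, 2)
        assert v[AA_INDEX["A"]] == 1 and v[20 + AA_INDEX["C"]] == 1
        assert v[40 + AA_INDEX["K"]] == 1 and v[60 + AA_INDEX["L"]] == 1


class TestPhysicoEncoding:
    def test_homopolymer_equals_table_value(self):
        t = curated_table()
        v = encode_physico("GGGG", t, ["KYTJ820101"])
        assert v[0] == pytest.approx(t["KYTJ820101"]["G"])

    def test_hand_average_two_ids(self):
        t = curated_table()
        ids = ["KYTJ820101", "HOPT810101"]
        v = encode_physico("AC", t, ids)
        for j, acc in enumerate(ids):
            expected = (t[acc]["A"] + t[acc]["C"]) / 2
            assert v[j] == pytest.approx(expected)

    def test_scramble_invariant(self):
        t = curated_table()
        s = PeptideSet([Peptide("p", "ACDEFGHIKLW")])
        ids = t.accessions[:3]
        np.testing.assert_allclose(
            encode_physico(s[0], t, ids), encode_physico(scramble(s, 2)[0], t, ids),
            atol=1e-12,
        )

    def test_unknown_accession(self):
        with pytest.raises(KeyError, match="NOPE"):
            encode_physico("ACD", curated_table(), ["NOPE999999"])


class TestEncodeAndHybrids:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (EncodingSpec("AAC"), 20),
            (EncodingSpec("DPC"), 400),
            (EncodingSpec("N5Bin"), 100),
            (EncodingSpec("C5Bin"), 100),
            (EncodingSpec("N5C5Bin"), 200),
            (hybrid(EncodingSpec("AAC"), EncodingSpec("DPC")), 420),
        ],
    )
    def test_dimensionality(self, spec, expected):
        assert spec.n_features == expected

    def test_full_hybrid_is_630_columns(self, small_sets):
        t = curated_table()
        spec = hybrid(
            EncodingSpec("AAC"), EncodingSpec("DPC"), EncodingSpec("N5C5Bin"),
            physico_spec(t, t.accessions[: min(10, len(t))]),
        )
        assert spec.n_features == 620 + min(10, len(t))

    def test_hybrid_concatenates_in_order(self):
        p = Peptide("p", "ACDEFGHIKL")
        spec = hybrid(EncodingSpec("AAC"), EncodingSpec("DPC"))
        v = encode_peptide(p, spec)
        np.testing.assert_array_equal(v[:20], encode_aac(p))
        np.testing.assert_array_equal(v[20:], encode_dpc(p))

    def test_empty_set_zero_rows(self, aac_spec):
        m = encode(aac_spec, PeptideSet([]))
        assert m.shape == (0, 20)

    def test_row_order_follows_set(self, toy_set, aac_spec):
        m = encode(aac_spec, toy_set)
        assert m.row_ids == toy_set.ids
        np.testing.assert_array_equal(m.values[2], encode_aac(toy_set[2]))

    def test_encoding_error_names_peptide(self, aac_spec):
        s = PeptideSet([Peptide("tiny", "ACD")])
        with pytest.raises(EncodingError, match="tiny"):
            encode(EncodingSpec("N5C5Bin"), s)

    def test_feature_names_match_columns(self, toy_set):
        spec = hybrid(EncodingSpec("AAC"), EncodingSpec("N5C5Bin"))
        df = encode(spec, toy_set).to_dataframe()
        assert list(df.columns) == spec.feature_names
        assert df.shape == (3, 220)


class TestAAIndexTable:
    def test_curated_scales_complete(self):
        t = curated_table()
        for acc in t.accessions:
            assert len(t[acc]) == 20

    def test_flatfile_round_trip(self, tmp_path):
        t = curated_table()
        f = tmp_path / "scales.aaindex"
        write_aaindex_flatfile(t, f)
        back = read_aaindex_flatfile(f)
        assert back.accessions == t.accessions
        for acc in t.accessions:
            for aa in AMINO_ACIDS:
                assert back[acc][aa] == pytest.approx(t[acc][aa], abs=1e-3)

    def test_synthetic_table_is_seeded_and_sized(self):
        a = synthetic_screening_table(50, seed=9)
        b = synthetic_screening_table(50, seed=9)
        assert len(a) == 50 and a.values == b.values

    def test_default_table_has_screening_scale_count(self):
        assert len(default_table(n_total=544)) == 544


class TestIndexScreening:
    def test_separating_index_ranked_first(self):
        # one scale separates Trp-rich from Trp-free peptides; the other two
        # are constant and useless
        t = AAIndexTable()
        t.add("SEP0000001", {aa: (1.0 if aa == "W" else 0.0) for aa in AMINO_ACIDS})
        t.add("FLAT000001", {aa: 1.0 for aa in AMINO_ACIDS})
        t.add("FLAT000002", {aa: 2.0 for aa in AMINO_ACIDS})
        from qsppred.fixtures import make_separable

        s = make_separable(60, seed=5)
        y = [1 if p.label == "positive" else 0 for p in s]
        top = select_top_indices(s, y, t, k=1, n_folds=5, seed=0)
        assert top == ["SEP0000001"]

    def test_k_equals_table_size_returns_permutation(self):
        t = synthetic_screening_table(5, seed=1)
        from qsppred.fixtures import make_separable

        s = make_separable(40, seed=6)
        y = [1 if p.label == "positive" else 0 for p in s]
        out = select_top_indices(s, y, t, k=5, n_folds=4, seed=0)
        assert sorted(out) == sorted(t.accessions)

    def test_tied_indices_break_lexically(self):
        t = AAIndexTable()
        row = {aa: float(i) for i, aa in enumerate(AMINO_ACIDS)}
        t.add("ZZZ0000001", row)
        t.add("AAA0000001", dict(row))
        from qsppred.fixtures import make_separable

        s = make_separable(40, seed=7)
        y = [1 if p.label == "positive" else 0 for p in s]
        out = select_top_indices(s, y, t, k=2, n_folds=4, seed=0)
        assert out == ["AAA0000001", "ZZZ0000001"]
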