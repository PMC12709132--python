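"""Pocket featurization: compositions, k-mer frequencies, exposure, DSSP parsing."""

import numpy as np
import pytest

from kinoreg import (
    AA_ALPHABET,
    EXPOSURE_ALPHABET,
    KINASE_FEATURE_LENGTH,
    SS8_ALPHABET,
    PocketAnnotation,
    classify_exposure,
    featurize_kinase,
    kinase_feature_names,
    kmer_frequencies,
    parse_dssp_output,
    residue_frequencies,
)
from kinoreg.errors import ValidationError
from kinoreg.kinase_features import (
    KINASE_FEATURE_BLOCKS,
    annotations_from_table,
    kmer_names,
)


def brute_force_kmer_freqs(s: str, alphabet: str, k: int) -> np.ndarray:
    """Independent oracle: dictionary count over explicit windows."""
    counts: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        window = s[i : i + k]
        if all(c in alphabet for c in window):
            counts[window] = counts.get(window, 0) + 1
    total = sum(counts.values())
    vec = np.zeros(len(alphabet) ** k)
    if total == 0:
        return vec
    for j, mer in enumerate(kmer_names(alphabet, k)):
        vec[j] = counts.get(mer, 0) / total
    return vec


class TestResidueFrequencies:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ("AAAA", {"A": 1.0}),
            ("ACAC", {"A": 0.5, "C": 0.5}),
        ],
    )
    def test_hand_examples(self, s, expected):
        vec = residue_frequencies(s, AA_ALPHABET)
        for i, aa in enumerate(AA_ALPHABET):
            assert vec[i] == pytest.approx(expected.get(aa, 0.0))

    def test_amino_acid_output_length_is_twenty(self):
        assert residue_frequencies("ACD", AA_ALPHABET).shape == (20,)

    def test_out_of_alphabet_symbols_dropped_from_denominator(self):
        vec = residue_frequencies("AXA", AA_ALPHABET)
        assert vec[0] == pytest.approx(1.0)

    def test_empty_after_filtering_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            vec = residue_frequencies("XXX", AA_ALPHABET)
        assert np.all(vec == 0)


class TestKmerFrequencies:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ("AAA", {"AAA": 1.0}),
            ("ACDA", {"ACD": 0.5, "CDA": 0.5}),
        ],
    )
    def test_hand_examples(self, s, expected):
        vec = kmer_frequencies(s, AA_ALPHABET, 3)
        names = kmer_names(AA_ALPHABET, 3)
        for j, mer in enumerate(names):
            assert vec[j] == pytest.approx(expected.get(mer, 0.0)), mer

    def test_ss8_3mer_space_has_512_entries(self):
        assert kmer_frequencies("GHI", SS8_ALPHABET, 3).shape == (512,)

    def test_too_short_string_gives_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            vec = kmer_frequencies("AC", AA_ALPHABET, 3)
        assert np.all(vec == 0)

    def test_window_with_invalid_symbol_is_skipped(self):
        # AXC invalidates windows covering X; only "ACD" window of "ACDX..." counts
        vec = kmer_frequencies("ACDX", AA_ALPHABET, 3)
        names = kmer_names(AA_ALPHABET, 3)
        assert vec[names.index("ACD")] == pytest.approx(1.0)
        assert vec.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("alphabet", [AA_ALPHABET, SS8_ALPHABET, EXPOSURE_ALPHABET])
    def test_matches_brute_force_dictionary_count(self, alphabet):
        rng = np.random.default_rng(42)
        symbols = list(alphabet) + ["X"]  # occasional out-of-alphabet symbol
        probs = np.full(len(symbols), 0.95 / len(alphabet))
        probs[-1] = 0.05
        for _ in range(200):
            n = int(rng.integers(3, 51))
            s = "".join(rng.choice(symbols, size=n, p=probs))
            fast = kmer_frequencies(s, alphabet, 3)
            slow = brute_force_kmer_freqs(s, alphabet, 3)
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestKmerProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.text(alphabet=AA_ALPHABET + "X", min_size=3, max_size=40))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_frequency_vector_sums_to_one_or_zero(self, s):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            vec = kmer_frequencies(s, AA_ALPHABET, 3)
        total = vec.sum()
        assert np.all(vec >= 0)
        assert total == pytest.approx(1.0, abs=1e-9) or total == 0.0

    @given(st.text(alphabet=SS8_ALPHABET, min_size=3, max_size=40))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_on_arbitrary_ss8_strings(self, s):
        np.testing.assert_allclose(
            kmer_frequencies(s, SS8_ALPHABET, 3),
            brute_force_kmer_freqs(s, SS8_ALPHABET, 3),
            atol=1e-12,
        )


class TestClassifyExposure:
    @pytest.mark.parametrize(
        "rsa, expected",
        [([0.5], "E"), ([0.0], "B"), ([0.49, 0.5, 0.51], "BEE")],
    )
    def test_threshold(self, rsa, expected):
        assert classify_exposure(rsa) == expected

    def test_out_of_range_error_names_position(self):
        with pytest.raises(ValidationError, match="position 1"):
            classify_exposure([0.3, 1.2])


class TestFeaturizeKinase:
    def test_vector_length_is_8551(self, tiny_pocket):
        assert featurize_kinase(tiny_pocket).values.shape == (KINASE_FEATURE_LENGTH,)
        assert len(kinase_feature_names()) == KINASE_FEATURE_LENGTH

    def test_single_symbol_pocket_composes_trivially(self):
        p = PocketAnnotation("K1", "AAA", "HHH", [1.0, 1.0, 1.0], 100.0)
        v = featurize_kinase(p)
        s = v.to_series()
        assert s["aa_A"] == 1.0
        assert s["aa3_AAA"] == 1.0
        assert s["ss_H"] == 1.0
        assert s["ss3_HHH"] == 1.0
        assert s["exp_E"] == 1.0
        assert s["exp3_EEE"] == 1.0
        assert s["pocket_volume"] == 100.0

    def test_frequency_blocks_sum_to_one(self, tiny_pocket):
        v = featurize_kinase(tiny_pocket)
        for name, _ in KINASE_FEATURE_BLOCKS[:-1]:
            assert v.block(name).sum() == pytest.approx(1.0, abs=1e-9), name

    def test_composition_blocks_permutation_invariant_3mers_not(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(AA_ALPHABET), size=30))
        ss8 = "".join(rng.choice(list(SS8_ALPHABET), size=30))
        rsa = rng.uniform(size=30)
        perm = rng.permutation(30)
        p1 = PocketAnnotation("a", seq, ss8, rsa, 1.0)
        p2 = PocketAnnotation(
            "b", "".join(seq[i] for i in perm), "".join(ss8[i] for i in perm), rsa[perm], 1.0
        )
        v1, v2 = featurize_kinase(p1), featurize_kinase(p2)
        for comp_block in ("aa_freq", "ss_freq", "exp_freq"):
            np.testing.assert_allclose(v1.block(comp_block), v2.block(comp_block), atol=1e-12)
        assert not np.allclose(v1.block("aa_3mer"), v2.block("aa_3mer"))

    def test_reversed_pocket_shares_composition_blocks(self):
        seq, ss8 = "ACDEFACD", "HHEEHHEE"
        rsa = [0.6, 0.4, 0.6, 0.4, 0.4, 0.6, 0.4, 0.6]  # palindromic exposure
        v_fwd = featurize_kinase(PocketAnnotation("f", seq, ss8, rsa, 10.0))
        v_rev = featurize_kinase(PocketAnnotation("r", seq[::-1], ss8[::-1], rsa[::-1], 10.0))
        np.testing.assert_allclose(v_fwd.block("aa_freq"), v_rev.block("aa_freq"), atol=1e-12)
        assert not np.allclose(v_fwd.block("aa_3mer"), v_rev.block("aa_3mer"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length mismatch"):
            PocketAnnotation("K1", "ACDE", "HHH", [0.1, 0.2, 0.3], 10.0)


def _classic_dssp_text(rows):
    """Craft a minimal classic DSSP file: (resnum, aa, ss, acc) per row."""
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N",
    ]
    lines = []
    for i, (num, aa, ss, acc) in enumerate(rows, start=1):
        ln = f"{i:5d}{num:5d} A {aa}  {ss}"
        ln = ln.ljust(34) + f"{acc:4d}"
        lines.append(ln)
    return "\n".join(header + lines) + "\n"


class TestParseDssp:
    def test_tsv_row_maps_directly(self, tmp_path):
        f = tmp_path / "ann.tsv"
        f.write_text("kinase_id\tposition\taa\tss8\trsa\nK1\t1\tA\tH\t0.7\n")
        rec = parse_dssp_output(f)
        assert list(rec.iloc[0][["aa", "ss8"]]) == ["A", "H"]
        assert rec.iloc[0]["rsa"] == pytest.approx(0.7)

    def test_blank_structure_column_becomes_coil(self, tmp_path):
        f = tmp_path / "k1.dssp"
        f.write_text(_classic_dssp_text([(1, "A", "H", 50), (2, "G", " ", 30)]))
        rec = parse_dssp_output(f)
        assert list(rec["ss8"]) == ["H", "C"]

    def test_asa_converted_to_rsa_via_reference(self, tmp_path):
        # alanine max ASA 129 (should be overridable); with a custom table of 106 -> RSA 1.0
        f = tmp_path / "k1.dssp"
        f.write_text(_classic_dssp_text([(1, "A", "H", 106)]))
        rec = parse_dssp_output(f, max_asa={"A": 106.0})
        assert rec.iloc[0]["rsa"] == pytest.approx(1.0)
        assert classify_exposure([rec.iloc[0]["rsa"]]) == "E"

    def test_unknown_residue_skipped_with_warning(self, tmp_path):
        f = tmp_path / "k1.dssp"
        f.write_text(_classic_dssp_text([(1, "A", "H", 10), (2, "Z", "H", 10), (3, "G", "E", 10)]))
        with pytest.warns(UserWarning, match="unknown residue"):
            rec = parse_dssp_output(f)
        assert list(rec["aa"]) == ["A", "G"]

    def test_parse_then_featurize_is_deterministic(self, tmp_path):
        rows = [(i, aa, ss, acc) for i, (aa, ss, acc) in enumerate(
            zip("ACDEFGH", "HHHEETC", [10, 60, 90, 120, 5, 44, 70]), start=1)]
        f = tmp_path / "k1.dssp"
        f.write_text(_classic_dssp_text(rows))
        vecs = []
        for _ in range(2):
            table = parse_dssp_output(f)
            pockets = annotations_from_table(table, {"k1": 321.0})
            vecs.append(featurize_kinase(pockets[0]).values)
        assert np.array_equal(vecs[0], vecs[1])
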