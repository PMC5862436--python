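"""Inventory, feature systems and tokenization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonosym.phonology import (
    ChartParseError,
    DISTINCTIVE_FEATURES,
    IPA_FEATURES,
    TokenizationError,
    UnknownPhonemeError,
    decompose_phoneme,
    default_table,
    derive_ipa_from_distinctive,
    ipa_flags,
    load_feature_table,
    tokenize_ipa,
)

F_VECTOR = (0, 0, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0)  # /f/: consonantal, continuant, anterior


def _ipa_dict(vec):
    return dict(zip(IPA_FEATURES, vec.tolist()))


class TestChart:
    def test_f_distinctive_vector_matches_published_decomposition(self, table):
        assert tuple(decompose_phoneme(table, "f")) == F_VECTOR

    def test_u_is_a_high_back_round_vowel(self, table):
        d = dict(zip(DISTINCTIVE_FEATURES, decompose_phoneme(table, "u").tolist()))
        assert d["consonantal"] == 0 and d["syllabic"] == 1
        assert d["high"] == 1 and d["back"] == 1 and d["round"] == 1

    def test_f_ipa_flags_labial_fricative_unvoiced(self, table):
        d = _ipa_dict(ipa_flags(table, "f"))
        assert d["labial"] == 1 and d["fricative"] == 1 and d["voiced"] == 0
        assert all(d[k] == 0 for k in ("open", "mid", "close", "round", "back"))

    def test_u_ipa_flags_close_back_round_no_consonant_flags(self, table):
        d = _ipa_dict(ipa_flags(table, "u"))
        assert d["close"] == 1 and d["back"] == 1 and d["round"] == 1
        assert all(
            d[k] == 0
            for k in ("radical", "dorsal", "coronal", "labial",
                      "plosive", "fricative", "liquid", "nasal")
        )

    def test_decomposition_is_deterministic(self, table):
        a = decompose_phoneme(table, "ŋ")
        b = decompose_phoneme(table, "ŋ")
        assert np.array_equal(a, b)

    def test_unknown_symbol_raises_lookup_error_with_symbol(self, table):
        with pytest.raises(UnknownPhonemeError, match="ʘ"):
            decompose_phoneme(table, "ʘ")

    def test_every_symbol_is_exactly_vowel_or_consonant(self, table):
        for sym in table.symbols:
            is_v = table.is_vowel(sym)
            assert is_v == (table.decompose(sym)[2] == 0)  # consonantal flag

    def test_vowels_have_exactly_one_height_flag(self, table):
        for sym in table.symbols:
            if table.is_vowel(sym):
                d = _ipa_dict(table.ipa_flags(sym))
                assert d["open"] + d["mid"] + d["close"] == 1

    def test_symbols_map_to_unique_feature_points(self, table):
        points = {tuple(table.decompose(s)) for s in table.symbols}
        assert len(points) == len(table.symbols)


class TestDeriveIpa:
    def test_derivation_matches_stored_flags_for_whole_inventory(self, table):
        """Round-trip: wildcard patterns reproduce the chart's IPA classes."""
        for sym in table.symbols:
            derived = derive_ipa_from_distinctive(table.decompose(sym), table.klass(sym))
            assert np.array_equal(derived, table.ipa_flags(sym)), sym

    def test_f_pattern_labial_and_fricative_and_unvoiced(self):
        d = _ipa_dict(derive_ipa_from_distinctive(F_VECTOR, "consonant"))
        assert d["labial"] and d["fricative"] and not d["voiced"]

    def test_all_zero_vowel_sets_no_consonant_flag(self):
        d = _ipa_dict(derive_ipa_from_distinctive([0] * 12, "vowel"))
        assert all(d[k] == 0 for k in IPA_FEATURES[:9])
        assert d["mid"] == 1  # neither high nor low

    def test_inconsistent_consonant_pattern_raises(self):
        # obstruent + continuant + nasal: both fricative and nasal manners fire
        v = (0, 0, 1, 1, 1, 0, 0, 0, 0, 1, 0, 1)
        with pytest.raises(ValueError, match="manner"):
            derive_ipa_from_distinctive(v, "consonant")

    def test_rejects_wrong_length_and_non_binary(self):
        with pytest.raises(ValueError):
            derive_ipa_from_distinctive([0] * 11, "vowel")
        with pytest.raises(ValueError):
            derive_ipa_from_distinctive([2] + [0] * 11, "vowel")


class TestTokenize:
    def test_fung_tokenizes_to_three_phonemes(self, table):
        assert tokenize_ipa(table, "fuŋ") == ["f", "u", "ŋ"]

    def test_empty_string_is_an_error(self, table):
        with pytest.raises(TokenizationError):
            tokenize_ipa(table, "")

    def test_strict_policy_raises_with_position(self, table):
        with pytest.raises(TokenizationError, match="position 1"):
            tokenize_ipa(table, "f%ŋ", policy="strict")

    def test_skip_policy_drops_unknown_and_warns(self, table, caplog):
        with caplog.at_level("WARNING", logger="sonosym.phonology"):
            assert tokenize_ipa(table, "f%ŋ", policy="skip") == ["f", "ŋ"]
        assert any("skipped 1" in r.getMessage() for r in caplog.records)

    def test_absorbed_variants_map_to_canonical_partner(self, table):
        assert tokenize_ipa(table, "bɔl") == ["b", "o", "l"]

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_tokenizing_concatenation_concatenates_token_lists(self, table, data):
        syms = list(table.symbols)
        w1 = "".join(data.draw(st.lists(st.sampled_from(syms), min_size=1, max_size=5)))
        w2 = "".join(data.draw(st.lists(st.sampled_from(syms), min_size=1, max_size=5)))
        assert tokenize_ipa(table, w1 + w2) == (
            tokenize_ipa(table, w1) + tokenize_ipa(table, w2)
        )


class TestLoadErrors:
    def _write(self, tmp_path, body):
        p = tmp_path / "chart.tsv"
        header = "symbol\t" + "\t".join(DISTINCTIVE_FEATURES)
        p.write_text(header + "\n" + body, encoding="utf-8")
        return p

    def test_empty_chart_rejected(self, tmp_path):
        with pytest.raises(ChartParseError, match="no symbols"):
            load_feature_table(self._write(tmp_path, ""))

    def test_non_binary_cell_names_the_row(self, tmp_path):
        bad = "f\t0\t0\t1\t1\t0\t0\t0\t0\t0\t2\t0\t0"
        with pytest.raises(ChartParseError, match="row 2.*'2'"):
            load_feature_table(self._write(tmp_path, bad))

    def test_duplicate_symbol_rejected(self, tmp_path):
        row = "a\t1\t1\t0\t1\t0\t0\t1\t0\t0\t0\t0\t1"
        with pytest.raises(ChartParseError, match="duplicate"):
            load_feature_table(self._write(tmp_path, row + "\n" + row))

    def test_loader_accepts_valid_minimal_chart(self, tmp_path):
        rows = (
            "f\t0\t0\t1\t1\t0\t0\t0\t0\t0\t1\t0\t0\n"
            "a\t1\t1\t0\t1\t0\t0\t1\t0\t0\t0\t0\t1"
        )
        t = load_feature_table(self._write(tmp_path, rows))
        assert t.symbols == ("f", "a")
        assert t.klass("f") == "consonant" and t.klass("a") == "vowel"

    def test_default_table_is_cached(self):
        assert default_table() is default_table()
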