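"""Phoneme inventory and the two phonological feature systems.

Every phoneme is represented twice:

* as a binary 12-dimensional *distinctive feature* vector, the minimal
  phonological units from which phonemes are composed (sonorant, syllabic,
  consonantal, continuant, nasal, high, low, back, round, anterior, coronal,
  voiced), and
* as a vector of *IPA class* flags read off the IPA chart: consonant place
  (radical, dorsal, coronal, labial), consonant manner (plosive, fricative,
  liquid, nasal), consonant voicing, vowel height (open, mid, close), vowel
  roundness and backness.

The two systems are linked: each IPA class corresponds to a wildcard
pattern over distinctive features (a labial consonant is ``anterior & ~coronal``,
a fricative is ``~sonorant & continuant``, ...), so the IPA flags can be
*derived* from the distinctive vector.  The packaged chart stores both,
which lets the derivation be checked exhaustively against the chart.

The packaged inventory (``data/feature_chart.tsv``) is compiled from
standard distinctive-feature and IPA chart assignments; IPA-chart cells
holding two symbols are absorbed into a single canonical symbol via the
companion absorption map, so that every symbol occupies a unique point in
feature space.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical distinctive-feature order; all serialization uses it.
DISTINCTIVE_FEATURES: tuple[str, ...] = (
    "sonorant",
    "syllabic",
    "consonantal",
    "continuant",
    "nasal",
    "high",
    "low",
    "back",
    "round",
    "anterior",
    "coronal",
    "voiced",
)

#: IPA class flags in chart-row order: 4 places, 4 manners, consonant
#: voicing, 3 vowel heights, vowel roundness and backness (14 flags).
IPA_FEATURES: tuple[str, ...] = (
    "radical",
    "dorsal",
    "coronal",
    "labial",
    "plosive",
    "fricative",
    "liquid",
    "nasal",
    "voiced",
    "open",
    "mid",
    "close",
    "round",
    "back",
)

#: The machine-learning feature set drops the voicing flag (13 features).
IPA_ML_FEATURES: tuple[str, ...] = tuple(f for f in IPA_FEATURES if f != "voiced")
#: Consonant subset: 4 places + 4 manners.
IPA_CONSONANT_FEATURES: tuple[str, ...] = IPA_FEATURES[:8]
#: Vowel subset: 3 heights + round + back.
IPA_VOWEL_FEATURES: tuple[str, ...] = IPA_FEATURES[9:]

PhonemeClass = Literal["vowel", "consonant"]


class ChartParseError(ValueError):
    """Raised when the feature chart file is malformed."""


class UnknownPhonemeError(KeyError):
    """Raised when a symbol is not in the inventory (after absorption)."""

    def __init__(self, symbol: str, position: int | None = None):
        self.symbol = symbol
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"unknown phoneme {symbol!r}{where}")


class TokenizationError(ValueError):
    """Raised for untokenizable input under the strict policy."""


def derive_ipa_from_distinctive(
    vector: np.ndarray | Iterable[int], phoneme_class: PhonemeClass
) -> np.ndarray:
    """Derive the 14 IPA class flags from a 12-dim distinctive vector.

    Consonant places and manners follow the wildcard patterns linking the
    two systems: labial = anterior & ~coronal; coronal place = coronal;
    dorsal = ~anterior & ~coronal & (high | back); radical = the remaining
    back-of-tract consonants; plosive = ~sonorant & ~continuant; fricative =
    ~sonorant & continuant; nasal manner = nasal; liquid = sonorant & ~nasal.
    The consonant voicing flag is copied from *voiced*.  Vowel height maps
    high -> close, low -> open, neither -> mid; roundness and backness are
    copied.  Vowels carry no consonant flags and vice versa.

    Raises
    ------
    ValueError
        If the vector is not a valid 12-dim binary tuple, or if the pattern
        match is inconsistent (e.g. two manners fire for one consonant).
    """
    v = np.asarray(list(vector), dtype=np.int8)
    if v.shape != (12,):
        raise ValueError(f"distinctive vector must have 12 entries, got {v.shape}")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("distinctive vector entries must be 0 or 1")
    d = dict(zip(DISTINCTIVE_FEATURES, (int(x) for x in v)))

    out = dict.fromkeys(IPA_FEATURES, 0)
    if phoneme_class == "consonant":
        out["labial"] = int(d["anterior"] and not d["coronal"])
        out["coronal"] = d["coronal"]
        nonfront = not d["anterior"] and not d["coronal"]
        out["dorsal"] = int(nonfront and (d["high"] or d["back"]))
        out["radical"] = int(nonfront and not d["high"] and not d["back"])
        out["plosive"] = int(not d["sonorant"] and not d["continuant"] and not d["nasal"])
        out["fricative"] = int(not d["sonorant"] and d["continuant"])
        out["nasal"] = d["nasal"]
        out["liquid"] = int(d["sonorant"] and not d["nasal"])
        out["voiced"] = d["voiced"]
        for group, names in (
            ("place", ("radical", "dorsal", "coronal", "labial")),
            ("manner", ("plosive", "fricative", "liquid", "nasal")),
        ):
            n_set = sum(out[n] for n in names)
            if n_set != 1:
                raise ValueError(
                    f"inconsistent consonant {group} pattern: {n_set} flags fire "
                    f"for distinctive vector {tuple(int(x) for x in v)}"
                )
    elif phoneme_class == "vowel":
        out["close"] = d["high"]
        out["open"] = d["low"]
        out["mid"] = int(not d["high"] and not d["low"])
        if out["close"] and out["open"]:
            raise ValueError("vowel cannot be both high and low")
        out["round"] = d["round"]
        out["back"] = d["back"]
    else:
        raise ValueError(f"phoneme_class must be 'vowel' or 'consonant', got {phoneme_class!r}")
    return np.array([out[f] for f in IPA_FEATURES], dtype=np.int8)


@dataclass(frozen=True)
class PhonemeFeatureTable:
    """Inventory mapping each IPA symbol to its feature vectors.

    Attributes
    ----------
    distinctive : mapping symbol -> 12-dim binary vector (canonical order).
    ipa : mapping symbol -> 14-dim IPA class flag vector.
    phoneme_class : mapping symbol -> ``"vowel"`` or ``"consonant"``.
    absorption : mapping of non-canonical symbols to the canonical symbol
        that absorbs them (IPA-chart cells holding two symbols keep the
        first of the pair).
    """

    distinctive: Mapping[str, np.ndarray]
    ipa: Mapping[str, np.ndarray]
    phoneme_class: Mapping[str, PhonemeClass]
    absorption: Mapping[str, str] = field(default_factory=dict)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.distinctive)

    def canonical(self, symbol: str) -> str:
        """Resolve a symbol through the absorption map (identity if canonical)."""
        return self.absorption.get(symbol, symbol)

    def __contains__(self, symbol: str) -> bool:
        return self.canonical(symbol) in self.distinctive

    def decompose(self, symbol: str) -> np.ndarray:
        """Stored 12-dim distinctive vector of *symbol* (after absorption)."""
        sym = self.canonical(symbol)
        try:
            return self.distinctive[sym]
        except KeyError:
            raise UnknownPhonemeError(symbol) from None

    def ipa_flags(self, symbol: str) -> np.ndarray:
        """Stored 14-dim IPA class vector of *symbol* (after absorption)."""
        sym = self.canonical(symbol)
        try:
            return self.ipa[sym]
        except KeyError:
            raise UnknownPhonemeError(symbol) from None

    def klass(self, symbol: str) -> PhonemeClass:
        sym = self.canonical(symbol)
        try:
            return self.phoneme_class[sym]
        except KeyError:
            raise UnknownPhonemeError(symbol) from None

    def is_vowel(self, symbol: str) -> bool:
        return self.klass(symbol) == "vowel"

    def tokenize(
        self, word: str, policy: Literal["strict", "skip"] = "strict"
    ) -> list[str]:
        """Segment *word* into canonical inventory phonemes.

        Greedy longest-match against the inventory (plus absorbed variants,
        which are replaced by their canonical partner).  The input is NFC
        normalized first.  Characters with no match raise
        :class:`TokenizationError` under ``policy="strict"`` or are dropped
        with a logged warning under ``policy="skip"``.
        """
        if policy not in ("strict", "skip"):
            raise ValueError(f"policy must be 'strict' or 'skip', got {policy!r}")
        if not word:
            raise TokenizationError("cannot tokenize an empty string")
        word = unicodedata.normalize("NFC", word)
        keys = sorted(
            set(self.distinctive) | set(self.absorption), key=len, reverse=True
        )
        tokens: list[str] = []
        skipped: list[tuple[int, str]] = []
        i = 0
        while i < len(word):
            for key in keys:
                if word.startswith(key, i):
                    tokens.append(self.canonical(key))
                    i += len(key)
                    break
            else:
                if policy == "strict":
                    raise TokenizationError(
                        f"unknown character {word[i]!r} at position {i} in {word!r}"
                    )
                skipped.append((i, word[i]))
                i += 1
        if skipped:
            logger.warning(
                "tokenize(%r): skipped %d unknown character(s): %s",
                word,
                len(skipped),
                "".join(c for _, c in skipped),
            )
        return tokens


def _data_path(name: str) -> Path:
    return Path(str(resources.files("sonosym").joinpath("data", name)))


def load_absorption_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (variant, canonical) TSV absorption map."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["variant", "canonical"]:
        raise ChartParseError(
            f"absorption map must have columns variant/canonical, got {list(df.columns)}"
        )
    out = {}
    for _, row in df.iterrows():
        v = unicodedata.normalize("NFC", row["variant"])
        out[v] = unicodedata.normalize("NFC", row["canonical"])
    return out


def load_feature_table(
    path: str | Path, absorption_path: str | Path | None = None
) -> PhonemeFeatureTable:
    """Load and validate a phoneme feature chart.

    The chart is a UTF-8 TSV with a header, one row per symbol: the symbol,
    the 12 binary distinctive features in canonical order, and (optionally)
    explicit ``place``/``manner`` columns for consonants.  The phoneme class
    is derived from the *consonantal* flag.  IPA class flags are taken from
    the explicit columns when present, otherwise derived from the
    distinctive vector.

    Raises
    ------
    ChartParseError
        On a malformed row, non-binary cell, duplicate symbol, or empty
        chart, with the offending row named.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["symbol", *DISTINCTIVE_FEATURES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ChartParseError(f"chart is missing columns: {missing}")
    if len(df) == 0:
        raise ChartParseError("no symbols in chart")

    has_classes = "place" in df.columns and "manner" in df.columns
    distinctive: dict[str, np.ndarray] = {}
    ipa: dict[str, np.ndarray] = {}
    klass: dict[str, PhonemeClass] = {}
    for idx, row in df.iterrows():
        sym = unicodedata.normalize("NFC", row["symbol"])
        if not sym:
            raise ChartParseError(f"row {idx + 2}: empty symbol")
        if sym in distinctive:
            raise ChartParseError(f"row {idx + 2}: duplicate symbol {sym!r}")
        vals = []
        for feat in DISTINCTIVE_FEATURES:
            cell = row[feat].strip()
            if cell not in ("0", "1"):
                raise ChartParseError(
                    f"row {idx + 2} (symbol {sym!r}): non-binary cell {cell!r} "
                    f"in column {feat!r}"
                )
            vals.append(int(cell))
        vec = np.array(vals, dtype=np.int8)
        vec.setflags(write=False)
        cls: PhonemeClass = "consonant" if vec[2] else "vowel"

        iv = derive_ipa_from_distinctive(vec, cls)
        if has_classes and cls == "consonant":
            place, manner = row["place"].strip(), row["manner"].strip()
            explicit = dict.fromkeys(IPA_FEATURES, 0)
            if place not in ("radical", "dorsal", "coronal", "labial"):
                raise ChartParseError(f"row {idx + 2}: unknown place {place!r}")
            if manner not in ("plosive", "fricative", "liquid", "nasal"):
                raise ChartParseError(f"row {idx + 2}: unknown manner {manner!r}")
            explicit[place] = 1
            explicit[manner] = 1
            explicit["voiced"] = int(vec[11])
            iv = np.array([explicit[f] for f in IPA_FEATURES], dtype=np.int8)
        iv.setflags(write=False)

        distinctive[sym] = vec
        ipa[sym] = iv
        klass[sym] = cls

    # injectivity after absorption: each symbol is a unique point
    seen: dict[tuple, str] = {}
    for sym, vec in distinctive.items():
        key = tuple(int(x) for x in vec)
        if key in seen:
            raise ChartParseError(
                f"symbols {seen[key]!r} and {sym!r} share the distinctive vector {key}; "
                "absorb one into the other"
            )
        seen[key] = sym

    absorption: dict[str, str] = {}
    if absorption_path is not None:
        absorption = load_absorption_map(absorption_path)
        for variant, canon in absorption.items():
            if canon not in distinctive:
                raise ChartParseError(
                    f"absorption target {canon!r} for {variant!r} is not in the inventory"
                )
            if variant in distinctive:
                raise ChartParseError(
                    f"absorbed variant {variant!r} is itself an inventory symbol"
                )
    return PhonemeFeatureTable(distinctive, ipa, klass, absorption)


_DEFAULT_TABLE: PhonemeFeatureTable | None = None


def default_table() -> PhonemeFeatureTable:
    """The packaged inventory (loaded once and cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_feature_table(
            _data_path("feature_chart.tsv"), _data_path("absorption.tsv")
        )
    return _DEFAULT_TABLE


# thin functional aliases matching the operation-style API
def decompose_phoneme(table: PhonemeFeatureTable, symbol: str) -> np.ndarray:
    return table.decompose(symbol)


def ipa_flags(table: PhonemeFeatureTable, symbol: str) -> np.ndarray:
    return table.ipa_flags(symbol)


def tokenize_ipa(
    table: PhonemeFeatureTable, word: str, policy: Literal["strict", "skip"] = "strict"
) -> list[str]:
    return table.tokenize(word, policy=policy)
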