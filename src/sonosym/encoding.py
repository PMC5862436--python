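"""Word-level feature encoding.

An onomatopoeia is a sequence of phonemes; stacking the feature vectors of
its phonemes gives a binary matrix (rows = phonemes, columns = features),
and averaging across rows gives a fixed-length *profile* whose entries are
the relative weights of each feature in the word.  Words of any length are
thereby mapped into the same space, at the cost of discarding temporal
structure (phoneme order, reduplication, lengthening) — averaging is
permutation-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .phonology import (
    DISTINCTIVE_FEATURES,
    IPA_CONSONANT_FEATURES,
    IPA_FEATURES,
    IPA_ML_FEATURES,
    IPA_VOWEL_FEATURES,
    PhonemeFeatureTable,
)

Modality = Literal["A", "V", "AV"]
FeatureSystem = Literal["distinctive", "ipa"]
Subset = Literal["all", "consonant", "vowel"]

MODALITIES: tuple[str, ...] = ("A", "V", "AV")
MOVEMENTS: tuple[str, ...] = ("hit", "slide", "ring")
SHAPES: tuple[str, ...] = ("rounded", "spiky")
SIZES: tuple[str, ...] = ("big", "small")
SOUNDS: tuple[str, ...] = ("HF", "LF")


@dataclass(frozen=True)
class OnomatopoeiaRecord:
    """One transcribed response: who said what for which stimulus.

    Stimulus factors not manipulated in a modality are ``None``: audio-only
    stimuli carry no shape or size, video-only stimuli carry no sound
    frequency; audiovisual stimuli carry all factors.
    """

    speaker: str
    modality: Modality
    movement: str
    ipa: str
    shape: str | None = None
    size: str | None = None
    sound: str | None = None

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")
        if self.modality == "A":
            if self.shape is not None or self.size is not None:
                raise ValueError("audio records must have shape = size = None")
            if self.sound not in SOUNDS:
                raise ValueError("audio records need a sound frequency (HF/LF)")
        elif self.modality == "V":
            if self.sound is not None:
                raise ValueError("video records must have sound = None")
            if self.shape not in SHAPES or self.size not in SIZES:
                raise ValueError("video records need shape and size")
        else:  # AV
            if self.shape not in SHAPES or self.size not in SIZES or self.sound not in SOUNDS:
                raise ValueError("audiovisual records need shape, size and sound")


@dataclass(frozen=True)
class FeatureMatrix:
    """Binary phoneme × feature matrix for one word."""

    values: np.ndarray  # (n_phonemes, n_features), int8
    phonemes: tuple[str, ...]
    features: tuple[str, ...]
    system: FeatureSystem

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("feature matrix needs at least one phoneme row")
        if self.values.shape != (len(self.phonemes), len(self.features)):
            raise ValueError("matrix shape does not match phoneme/feature labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature matrix entries must be binary")


@dataclass(frozen=True)
class FeatureProfile:
    """Per-feature mean across a word's phonemes (values in [0, 1])."""

    values: np.ndarray
    features: tuple[str, ...]
    system: FeatureSystem
    subset: Subset | None = None
    n_phonemes: int = 0
    record: OnomatopoeiaRecord | None = field(default=None, compare=False)


def to_matrix(
    table: PhonemeFeatureTable,
    phonemes: Sequence[str],
    system: FeatureSystem = "distinctive",
) -> FeatureMatrix:
    """Stack the feature vectors of *phonemes* into a binary matrix."""
    if len(phonemes) == 0:
        raise ValueError("cannot build a feature matrix from zero phonemes")
    if system == "distinctive":
        rows = [table.decompose(p) for p in phonemes]
        features = DISTINCTIVE_FEATURES
    elif system == "ipa":
        rows = [table.ipa_flags(p) for p in phonemes]
        features = IPA_FEATURES
    else:
        raise ValueError(f"unknown feature system {system!r}")
    return FeatureMatrix(
        np.vstack(rows).astype(np.int8),
        tuple(table.canonical(p) for p in phonemes),
        features,
        system,
    )


def to_profile(matrix: FeatureMatrix) -> FeatureProfile:
    """Column means of the matrix: the word's feature weight vector."""
    return FeatureProfile(
        matrix.values.mean(axis=0),
        matrix.features,
        matrix.system,
        n_phonemes=matrix.values.shape[0],
    )


def _subset_columns(subset: Subset) -> tuple[str, ...]:
    if subset == "all":
        return IPA_ML_FEATURES
    if subset == "consonant":
        return IPA_CONSONANT_FEATURES
    if subset == "vowel":
        return IPA_VOWEL_FEATURES
    raise ValueError(f"unknown subset {subset!r}")


def subset_features(profile: FeatureProfile, subset: Subset) -> FeatureProfile:
    """Select the modelling columns of an IPA-system profile.

    ``all`` keeps the 13 modelling features (voicing excluded), ``consonant``
    the 8 place/manner columns, ``vowel`` the 5 height/round/back columns.
    Columns are selected from the all-phoneme average; a word with no
    phoneme of the class simply has zeros there.
    """
    if profile.system != "ipa":
        raise ValueError("feature subsets are defined on IPA-system profiles only")
    cols = _subset_columns(subset)
    idx = [profile.features.index(c) for c in cols]
    return replace(profile, values=profile.values[idx], features=cols, subset=subset)


def encode_record(
    table: PhonemeFeatureTable,
    record: OnomatopoeiaRecord,
    system: FeatureSystem = "ipa",
    subset: Subset | None = None,
    policy: Literal["strict", "skip"] = "strict",
    class_averaging: bool = False,
) -> FeatureProfile:
    """Tokenize, project and average one record into a feature profile.

    With ``class_averaging=True`` the consonant (vowel) subset is averaged
    over only the consonant (vowel) phonemes of the word instead of
    column-selecting the all-phoneme mean; a word with no phoneme of the
    class then falls back to zeros.
    """
    phonemes = table.tokenize(record.ipa, policy=policy)
    m = to_matrix(table, phonemes, system=system)
    if class_averaging and subset in ("consonant", "vowel"):
        want_vowel = subset == "vowel"
        mask = np.array([table.is_vowel(p) == want_vowel for p in m.phonemes])
        cols = _subset_columns(subset)
        idx = [m.features.index(c) for c in cols]
        if mask.any():
            values = m.values[mask][:, idx].mean(axis=0)
        else:
            values = np.zeros(len(cols))
        return FeatureProfile(
            values, cols, "ipa", subset=subset,
            n_phonemes=int(mask.sum()), record=record,
        )
    p = to_profile(m)
    if subset is not None:
        p = subset_features(p, subset)
    return replace(p, record=record)


def encode_corpus(
    table: PhonemeFeatureTable,
    records: Iterable[OnomatopoeiaRecord],
    system: FeatureSystem = "ipa",
    subset: Subset | None = None,
    policy: Literal["strict", "skip"] = "strict",
    class_averaging: bool = False,
) -> pd.DataFrame:
    """Encode a list of records into one tidy frame.

    Returns a DataFrame with the record metadata columns (speaker, modality,
    movement, shape, size, sound, ipa) followed by one column per feature.
    """
    rows = []
    feature_names: tuple[str, ...] | None = None
    for rec in records:
        prof = encode_record(
            table, rec, system=system, subset=subset,
            policy=policy, class_averaging=class_averaging,
        )
        feature_names = prof.features
        rows.append(
            {
                "speaker": rec.speaker,
                "modality": rec.modality,
                "movement": rec.movement,
                "shape": rec.shape,
                "size": rec.size,
                "sound": rec.sound,
                "ipa": rec.ipa,
                **dict(zip(prof.features, prof.values)),
            }
        )
    if not rows:
        raise ValueError("no records to encode")
    df = pd.DataFrame(rows)
    df.attrs["features"] = feature_names
    df.attrs["system"] = system
    df.attrs["subset"] = subset
    return df


META_COLUMNS: tuple[str, ...] = (
    "speaker", "modality", "movement", "shape", "size", "sound", "ipa",
)
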