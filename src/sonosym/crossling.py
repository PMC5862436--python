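"""Applying a trained movement decoder to cross-linguistic word lists.

A classifier trained on audiovisual onomatopoeias (all 13 modelling
features) can be applied to lists of conventional onomatopoeias collected
across languages, treating each orthographic form as if it were an IPA
transcription.  Per action, the proportion of languages classified as hit,
slide or ring gives a movement distribution, which can be compared to the
percentages reported by human raters.

The orthography-as-IPA step is a deliberate approximation: characters with
no inventory match are skipped, and forms that lose more than half their
characters are dropped entirely.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoding import fit_lda
from .encoding import MOVEMENTS, encode_corpus, subset_features, to_matrix, to_profile
from .phonology import PhonemeFeatureTable, default_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActionWordList:
    """Tokenized cross-linguistic forms grouped by action."""

    table: pd.DataFrame  # action, language, form, phonemes (list)
    n_dropped_forms: int
    n_dropped_actions: int


def ingest_wordlist(
    source: str | pd.DataFrame,
    table: PhonemeFeatureTable | None = None,
    min_languages: int = 10,
) -> ActionWordList:
    """Read and filter an action/language/form word list.

    Forms are tokenized with the skip policy (unmatched characters dropped);
    forms losing more than 50% of their characters are discarded, duplicate
    (action, language) rows keep the last occurrence, and actions attested
    in fewer than ``min_languages`` languages are excluded.
    """
    table = table or default_table()
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, sep="\t", dtype=str
    )
    required = {"action", "language", "form"}
    if missing := required - set(df.columns):
        raise ValueError(f"word list is missing columns: {sorted(missing)}")

    n_dup = df.duplicated(subset=["action", "language"]).sum()
    if n_dup:
        logger.warning("word list: %d duplicate (action, language) rows; keeping last", n_dup)
        df = df.drop_duplicates(subset=["action", "language"], keep="last")

    rows, dropped_forms = [], 0
    for _, row in df.iterrows():
        form = unicodedata.normalize("NFC", str(row["form"]))
        try:
            phonemes = table.tokenize(form, policy="skip")
        except Exception:
            phonemes = []
        if not phonemes or len(phonemes) < 0.5 * len(form):
            dropped_forms += 1
            continue
        rows.append(
            {"action": row["action"], "language": row["language"],
             "form": form, "phonemes": phonemes}
        )
    if dropped_forms:
        logger.warning("word list: dropped %d untokenizable form(s)", dropped_forms)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("word list is empty after tokenization filtering")

    counts = out.groupby("action")["language"].nunique()
    keep = counts[counts >= min_languages].index
    n_dropped_actions = int((counts < min_languages).sum())
    if n_dropped_actions:
        logger.warning(
            "word list: excluded %d action(s) below the %d-language floor",
            n_dropped_actions, min_languages,
        )
    out = out[out["action"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no action reaches the minimum language count")
    return ActionWordList(out, int(dropped_forms), n_dropped_actions)


def train_movement_classifier(
    records,
    table: PhonemeFeatureTable | None = None,
    modality: str = "AV",
    subset: str = "all",
):
    """Fit an LDA movement decoder on the full corpus of one modality."""
    table = table or default_table()
    recs = [r for r in records if r.modality == modality]
    df = encode_corpus(table, recs, system="ipa", subset=subset)
    feats = list(df.attrs["features"])
    return fit_lda(df[feats].to_numpy(dtype=float), df["movement"].to_numpy())


def classify_actions(
    model,
    words: ActionWordList,
    table: PhonemeFeatureTable | None = None,
    subset: str = "all",
) -> pd.DataFrame:
    """Per-action proportions of languages classified hit / slide / ring.

    Each form gets a hard class assignment from the trained decoder; the
    per-action distribution is the exact fraction of its languages falling
    in each movement.  Forms with an all-zero profile are still classified
    (the decoder falls back on its class priors) and counted in a logged
    warning.
    """
    table = table or default_table()
    X, n_zero = [], 0
    for phonemes in words.table["phonemes"]:
        prof = subset_features(to_profile(to_matrix(table, phonemes, system="ipa")), subset)
        if not prof.values.any():
            n_zero += 1
        X.append(prof.values)
    if n_zero:
        logger.warning("classify_actions: %d all-zero profile(s), classified by priors", n_zero)
    pred = model.predict(np.asarray(X, dtype=float))
    df = words.table.assign(predicted=pred)
    dist = (
        df.groupby("action")["predicted"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(MOVEMENTS), fill_value=0.0)
    )
    dist.columns.name = None
    return dist


def normalize_ratings(
    ratings: pd.DataFrame, average_before_normalize: bool = False
) -> pd.DataFrame:
    """Collapse per-rater percentages to per-action movement proportions.

    By default each rater × action row is renormalized to proportions
    before averaging over raters (raters need not write exact 100 totals);
    the alternative order averages raw percentages first.
    """
    cols = list(MOVEMENTS)
    df = ratings.copy()
    if missing := {"action", *cols} - set(df.columns):
        raise ValueError(f"ratings are missing columns: {sorted(missing)}")
    df[cols] = df[cols].astype(float)
    if average_before_normalize:
        mean = df.groupby("action")[cols].mean()
        return mean.div(mean.sum(axis=1), axis=0)
    totals = df[cols].sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a rater-action row has all-zero percentages")
    df[cols] = df[cols].div(totals, axis=0)
    return df.groupby("action")[cols].mean()


def compare_to_ratings(
    predicted: pd.DataFrame,
    ratings: pd.DataFrame,
    average_before_normalize: bool = False,
) -> dict:
    """Correlate model-derived and human movement distributions.

    Pearson r over all (action, movement) proportion cells jointly, plus a
    per-movement breakdown.  If either side is constant across cells the
    correlation is undefined and reported as 0 (p = 1).
    """
    human = normalize_ratings(ratings, average_before_normalize)
    pred_actions, human_actions = set(predicted.index), set(human.index)
    if pred_actions != human_actions:
        raise ValueError(
            "action sets differ; only in predictions: "
            f"{sorted(pred_actions - human_actions)}, only in ratings: "
            f"{sorted(human_actions - pred_actions)}"
        )
    human = human.loc[predicted.index, list(MOVEMENTS)]
    x = predicted[list(MOVEMENTS)].to_numpy(dtype=float).ravel()
    yv = human.to_numpy(dtype=float).ravel()

    def _safe_pearson(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0, 1.0
        r, p = sps.pearsonr(a, b)
        return float(r), float(p)

    r, p = _safe_pearson(x, yv)
    per_movement = {
        mov: _safe_pearson(
            predicted[mov].to_numpy(dtype=float), human[mov].to_numpy(dtype=float)
        )[0]
        for mov in MOVEMENTS
    }
    return {"r": r, "p": p, "n_cells": x.size, "per_movement": per_movement}
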