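"""Linear discriminant decoding of stimulus properties from word profiles.

The decoding engine asks how well the phonological profile of an
onomatopoeia predicts properties of the event it was coined for: the
movement type (hit / slide / ring, 3 classes), the object shape, the sound
frequency, or the shape × frequency compound (4 classes).

Design points that matter for validity:

* **Speaker-grouped cross-validation.** All words of one speaker fall on
  the same side of every train/test split, so the classifier can never
  exploit speaker idiosyncrasies to predict a speaker's held-out words.
* **Repetition.** Fold assignment is random, so the k-fold procedure is
  repeated many times with fresh folds; confusion matrices and scores are
  summarized by their median and inter-quartile range across repetitions.
* **Macro-averaged Matthews φ.** Performance is the unweighted mean over
  classes of the one-vs-rest Matthews correlation coefficient: +1 perfect,
  0 chance, −1 complete disagreement.
* **Cross-modality transfer** trains the k fold-classifiers in one sensory
  modality and applies each to the full corpus of another, averaging over
  the k classifiers before summarizing over repetitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .encoding import OnomatopoeiaRecord, Subset, encode_corpus
from .phonology import PhonemeFeatureTable, default_table

logger = logging.getLogger(__name__)

Target = Literal["movement", "shape", "sound", "shape_sound"]

#: covariance shrinkage used by every LDA fit; keeps collinear feature
#: subsets (e.g. the three vowel-height columns) numerically safe
LDA_SHRINKAGE = 1e-4


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def phi_binary(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of one one-vs-rest table.

    (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero margin
    makes the score undefined and returns 0, the value of chance-level
    classification.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def phi_macro(confusions: Sequence[ConfusionCounts]) -> float:
    """Unweighted mean of the per-class one-vs-rest φ values."""
    if len(confusions) < 2:
        raise ValueError("macro-averaging needs at least 2 classes")
    return float(np.mean([phi_binary(c) for c in confusions]))


def counts_from_confusion(matrix: np.ndarray) -> list[ConfusionCounts]:
    """One-vs-rest counts per class from a (true × predicted) count matrix."""
    m = np.asarray(matrix)
    total = int(m.sum())
    out = []
    for i in range(m.shape[0]):
        tp = int(m[i, i])
        fn = int(m[i].sum()) - tp
        fp = int(m[:, i].sum()) - tp
        out.append(ConfusionCounts(tp=tp, fp=fp, tn=total - tp - fn - fp, fn=fn))
    return out


def phi_from_confusion(matrix: np.ndarray) -> float:
    return phi_macro(counts_from_confusion(matrix))


def speaker_grouped_folds(
    speakers: Sequence[str], k: int, seed: int | np.random.Generator
) -> list[list[str]]:
    """Split distinct speakers into k disjoint groups of near-equal size."""
    uniq = sorted(set(speakers))
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(uniq):
        raise ValueError(f"cannot make {k} folds from {len(uniq)} speakers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = [uniq[i] for i in rng.permutation(len(uniq))]
    return [list(order[i::k]) for i in range(k)]


def fit_lda(X: np.ndarray, y: Sequence) -> LinearDiscriminantAnalysis:
    """Pooled-covariance linear discriminant with empirical class priors.

    The pooled covariance is shrunk by a small fixed coefficient so that
    fits survive collinear or constant feature columns.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes in the training set")
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"LDA needs >= 2 training items per class; short: {list(small)}")
    model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=LDA_SHRINKAGE)
    model.fit(np.asarray(X, dtype=float), y)
    return model


@dataclass(frozen=True)
class DecodingTask:
    """Specification of one decoding analysis."""

    target: Target = "movement"
    modality_train: str = "AV"
    modality_test: str = "AV"
    subset: Subset = "all"
    k: int = 10
    reps: int = 1000
    seed: int = 0
    aggregate_per_speaker: bool = False
    class_averaging: bool = False


@dataclass(frozen=True)
class DecodingResult:
    """Median/IQR summaries of confusion proportions and macro φ."""

    task: DecodingTask
    classes: tuple[str, ...]
    confusion_median: pd.DataFrame  # proportions, rows = true classes
    confusion_iqr: pd.DataFrame
    phi_median: float
    phi_iqr: float
    phi_mean: float
    phi_per_rep: np.ndarray = field(repr=False, default=None)


def _target_labels(df: pd.DataFrame, target: Target) -> pd.Series:
    if target == "shape_sound":
        if df["shape"].isna().any() or df["sound"].isna().any():
            raise ValueError("shape_sound decoding needs records with both factors (AV)")
        return df["shape"] + "-" + df["sound"]
    if df[target].isna().any():
        raise ValueError(f"target {target!r} is undefined for some records")
    return df[target]


def _design(
    records: Iterable[OnomatopoeiaRecord],
    modality: str,
    task: DecodingTask,
    table: PhonemeFeatureTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, speakers) for one modality under the task's feature subset."""
    recs = [r for r in records if r.modality == modality]
    if not recs:
        raise ValueError(f"no records in modality {modality!r}")
    df = encode_corpus(
        table, recs, system="ipa", subset=task.subset,
        class_averaging=task.class_averaging,
    )
    feats = list(df.attrs["features"])
    y = _target_labels(df, task.target)
    X = df[feats].to_numpy(dtype=float)
    speakers = df["speaker"].to_numpy()
    if task.aggregate_per_speaker:
        agg = df.assign(_y=y).groupby(["speaker", "_y"], observed=True)[feats].mean()
        X = agg.to_numpy(dtype=float)
        speakers = agg.index.get_level_values("speaker").to_numpy()
        y = agg.index.get_level_values("_y").to_series().reset_index(drop=True)
    return X, np.asarray(y), speakers


def _folds_with_all_classes(
    speakers: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator
) -> list[list[str]]:
    """Draw speaker folds whose training sides contain every class."""
    classes = np.unique(y)
    for attempt in range(50):
        folds = speaker_grouped_folds(speakers, k, rng)
        ok = True
        for fold in folds:
            train_mask = ~np.isin(speakers, fold)
            if len(np.unique(y[train_mask])) < len(classes):
                ok = False
                break
        if ok:
            if attempt > 0:
                logger.warning(
                    "fold draw retried %d time(s) to keep all classes in training",
                    attempt,
                )
            return folds
    raise ValueError("could not draw speaker folds with every class in training")


def _one_cv_repetition(
    X: np.ndarray,
    y: np.ndarray,
    speakers: np.ndarray,
    classes: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One grouped k-fold pass; returns the pooled count confusion matrix."""
    folds = _folds_with_all_classes(speakers, y, k, rng)
    cls_index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for fold in folds:
        test_mask = np.isin(speakers, fold)
        # speaker exclusivity: no speaker on both sides of the split
        assert set(speakers[test_mask]).isdisjoint(speakers[~test_mask])
        model = fit_lda(X[~test_mask], y[~test_mask])
        pred = model.predict(X[test_mask])
        for t, p in zip(y[test_mask], pred):
            counts[cls_index[t], cls_index[p]] += 1
    return counts


def _summarize(
    task: DecodingTask,
    classes: np.ndarray,
    conf_reps: np.ndarray,
    phi_reps: np.ndarray,
) -> DecodingResult:
    q25, q50, q75 = np.percentile(conf_reps, [25, 50, 75], axis=0)
    idx = list(classes)
    p25, p50, p75 = np.percentile(phi_reps, [25, 50, 75])
    return DecodingResult(
        task=task,
        classes=tuple(classes),
        confusion_median=pd.DataFrame(q50, index=idx, columns=idx),
        confusion_iqr=pd.DataFrame(q75 - q25, index=idx, columns=idx),
        phi_median=float(p50),
        phi_iqr=float(p75 - p25),
        phi_mean=float(phi_reps.mean()),
        phi_per_rep=phi_reps,
    )


def within_modality_decode(
    records: Iterable[OnomatopoeiaRecord],
    task: DecodingTask,
    table: PhonemeFeatureTable | None = None,
) -> DecodingResult:
    """Speaker-grouped k-fold CV within one modality, repeated ``task.reps`` times.

    Each repetition draws fresh speaker folds, pools the held-out
    predictions of the k folds into one count confusion matrix, and records
    the row-normalized proportions and the macro φ.  Repetitions are
    summarized by median and IQR.
    """
    if task.modality_train != task.modality_test:
        raise ValueError("within-modality task must have equal train and test modality")
    table = table or default_table()
    X, y, speakers = _design(records, task.modality_train, task, table)
    classes = np.unique(y)
    rng = np.random.default_rng(task.seed)
    conf_reps = np.empty((task.reps, len(classes), len(classes)))
    phi_reps = np.empty(task.reps)
    for rep in range(task.reps):
        counts = _one_cv_repetition(X, y, speakers, classes, task.k, rng)
        conf_reps[rep] = counts / counts.sum(axis=1, keepdims=True)
        phi_reps[rep] = phi_from_confusion(counts)
    return _summarize(task, classes, conf_reps, phi_reps)


def cross_modality_decode(
    records: Iterable[OnomatopoeiaRecord],
    task: DecodingTask,
    table: PhonemeFeatureTable | None = None,
) -> DecodingResult:
    """Train fold-classifiers in one modality, test on the full other modality.

    Per repetition, the k training-modality folds from the within-modality
    protocol yield k classifiers (each trained on k−1 folds); every
    classifier predicts the entire test-modality corpus.  The k confusion
    proportion matrices and φ values are averaged, then summarized by
    median/IQR over repetitions.
    """
    table = table or default_table()
    records = list(records)
    X_tr, y_tr, spk_tr = _design(records, task.modality_train, task, table)
    X_te, y_te, _ = _design(records, task.modality_test, task, table)
    classes = np.unique(y_tr)
    missing = set(classes) - set(np.unique(y_te))
    if missing:
        raise ValueError(f"classes absent from test modality: {sorted(missing)}")
    cls_index = {c: i for i, c in enumerate(classes)}
    rng = np.random.default_rng(task.seed)
    conf_reps = np.empty((task.reps, len(classes), len(classes)))
    phi_reps = np.empty(task.reps)
    for rep in range(task.reps):
        folds = _folds_with_all_classes(spk_tr, y_tr, task.k, rng)
        conf_folds = np.empty((task.k, len(classes), len(classes)))
        phi_folds = np.empty(task.k)
        for fi, fold in enumerate(folds):
            train_mask = ~np.isin(spk_tr, fold)
            model = fit_lda(X_tr[train_mask], y_tr[train_mask])
            pred = model.predict(X_te)
            counts = np.zeros((len(classes), len(classes)), dtype=int)
            for t, p in zip(y_te, pred):
                counts[cls_index[t], cls_index[p]] += 1
            conf_folds[fi] = counts / counts.sum(axis=1, keepdims=True)
            phi_folds[fi] = phi_from_confusion(counts)
        conf_reps[rep] = conf_folds.mean(axis=0)
        phi_reps[rep] = phi_folds.mean()
    return _summarize(task, classes, conf_reps, phi_reps)
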