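"""Per-feature screening statistics.

Three complementary views of how stimulus factors shape the phonology of
the corpus:

* a per-feature repeated-measures ANOVA screen with a Bonferroni-corrected
  threshold across all 26 phonological dimensions (12 distinctive + 14 IPA);
* condition-level deviation patterns: which IPA features sit far above or
  below the modality mean for each factor level (the +/−/0 maps);
* the feature × feature Pearson correlation matrix (phonological features
  live in overlapping articulatory/acoustic spaces and are not mutually
  exclusive — e.g. nasals are voiced, so the two features correlate).

Speakers enter the ANOVA as the repeated-measures unit: each test runs on
per-speaker condition-cell means, the classical reading of "subjects as a
random factor".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .encoding import OnomatopoeiaRecord, encode_corpus
from .phonology import (
    DISTINCTIVE_FEATURES,
    IPA_FEATURES,
    PhonemeFeatureTable,
    default_table,
)

logger = logging.getLogger(__name__)

#: factors manipulated within each sensory modality
MODALITY_FACTORS: dict[str, tuple[str, ...]] = {
    "A": ("movement", "sound"),
    "V": ("movement", "shape"),
    "AV": ("movement", "shape", "sound"),
}

#: total number of screened phonological dimensions (12 distinctive + 14 IPA)
N_SCREENED_FEATURES = len(DISTINCTIVE_FEATURES) + len(IPA_FEATURES)


class ConfigurationError(ValueError):
    """Raised when the requested analysis does not fit the data layout."""


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test level alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


@dataclass(frozen=True)
class AnovaScreen:
    """Tidy screen results plus the corrected significance threshold."""

    table: pd.DataFrame  # modality, system, feature, factor, p, significant
    alpha: float
    n_comparisons: int
    threshold: float


def _speaker_cell_means(
    df: pd.DataFrame, factors: Sequence[str], features: Sequence[str]
) -> pd.DataFrame:
    return (
        df.groupby(["speaker", *factors], observed=True)[list(features)]
        .mean()
        .reset_index()
    )


def run_anova_screen(
    records: Iterable[OnomatopoeiaRecord],
    table: PhonemeFeatureTable | None = None,
    alpha: float = 0.01,
    systems: Sequence[Literal["distinctive", "ipa"]] = ("distinctive", "ipa"),
) -> AnovaScreen:
    """One repeated-measures ANOVA per feature per modality.

    Within each modality the manipulated factors (movement plus sound and/or
    shape) enter jointly as within-subject factors on per-speaker cell
    means; main-effect p-values are reported per factor.  Significance is
    flagged at ``alpha / 26`` across all screened dimensions.
    """
    table = table or default_table()
    records = list(records)
    if len({r.speaker for r in records}) < 2:
        raise ConfigurationError("the ANOVA screen needs at least 2 speakers")

    rows = []
    for system in systems:
        features = DISTINCTIVE_FEATURES if system == "distinctive" else IPA_FEATURES
        df = encode_corpus(table, records, system=system)
        for modality, factors in MODALITY_FACTORS.items():
            sub = df[df["modality"] == modality]
            if sub.empty:
                continue
            for f in factors:
                if sub[f].nunique() < 2:
                    raise ConfigurationError(
                        f"factor {f!r} is constant within modality {modality!r}"
                    )
            cells = _speaker_cell_means(sub, factors, features)
            for feat in features:
                pvals = _rm_anova_pvalues(cells, feat, factors)
                for factor, p in pvals.items():
                    rows.append(
                        {
                            "modality": modality,
                            "system": system,
                            "feature": feat,
                            "factor": factor,
                            "p": p,
                        }
                    )
    out = pd.DataFrame(rows)
    threshold = bonferroni_threshold(alpha, N_SCREENED_FEATURES)
    out["significant"] = out["p"] < threshold
    return AnovaScreen(out, alpha, N_SCREENED_FEATURES, threshold)


def _rm_anova_pvalues(
    cells: pd.DataFrame, depvar: str, factors: Sequence[str]
) -> dict[str, float]:
    if cells[depvar].nunique() <= 1:
        # a feature never used (or always used identically) carries no test
        return {f: np.nan for f in factors}
    res = AnovaRM(
        cells, depvar=depvar, subject="speaker", within=list(factors),
        aggregate_func="mean",
    ).fit()
    tab = res.anova_table
    return {f: float(tab.loc[f, "Pr > F"]) for f in factors}


@dataclass(frozen=True)
class DeviationPattern:
    """+/−/0 map of condition-level feature deviations within a modality."""

    labels: pd.DataFrame  # rows = factor levels, columns = features
    z: pd.DataFrame
    k_sd: float
    sd_unit: str


def deviation_patterns(
    records: Iterable[OnomatopoeiaRecord],
    modality: str,
    factor: str,
    table: PhonemeFeatureTable | None = None,
    k_sd: float = 3.0,
    sd_unit: Literal["pooled_within", "modality"] = "pooled_within",
    system: Literal["distinctive", "ipa"] = "ipa",
) -> DeviationPattern:
    """Label features whose condition-level mean sits beyond ±k s.d.

    The analysis unit is the per-speaker condition-level mean profile.  Each
    feature's condition-level mean (over speakers) is centred on the
    modality-wide mean and scaled by a noise s.d.: with
    ``sd_unit="pooled_within"`` (default) the pooled s.d. of the speaker
    units around their level means — a signal-to-noise scaling under which
    strong planted effects exceed |z| = 3 — or, with ``sd_unit="modality"``,
    the raw s.d. over all speaker units.  Features with zero s.d. are
    labelled 0 with a warning.  ``k_sd=0`` degenerates to sign-of-deviation
    labelling.
    """
    table = table or default_table()
    features = DISTINCTIVE_FEATURES if system == "distinctive" else IPA_FEATURES
    df = encode_corpus(table, records, system=system)
    sub = df[df["modality"] == modality]
    if sub.empty:
        raise ConfigurationError(f"no records in modality {modality!r}")
    if factor not in MODALITY_FACTORS[modality]:
        raise ConfigurationError(f"factor {factor!r} not manipulated in {modality!r}")
    if sub[factor].nunique() < 2:
        raise ConfigurationError(f"factor {factor!r} is constant within {modality!r}")

    units = _speaker_cell_means(sub, [factor], features)
    level_mean = units.groupby(factor, observed=True)[list(features)].mean()
    modality_mean = units[list(features)].mean()
    if sd_unit == "pooled_within":
        resid = units[list(features)] - level_mean.loc[units[factor]].to_numpy()
        sd = resid.std(ddof=1)
    elif sd_unit == "modality":
        sd = units[list(features)].std(ddof=1)
    else:
        raise ValueError(f"unknown sd_unit {sd_unit!r}")

    zero = sd == 0
    if zero.any():
        logger.warning(
            "deviation_patterns: zero s.d. for feature(s) %s; labelled 0",
            list(sd.index[zero]),
        )
    z = (level_mean - modality_mean) / sd.replace(0, np.nan)
    labels = pd.DataFrame("0", index=z.index, columns=z.columns)
    labels[z > k_sd] = "+"
    labels[z < -k_sd] = "-"
    return DeviationPattern(labels, z, k_sd, sd_unit)


def feature_correlations(
    records: Iterable[OnomatopoeiaRecord],
    table: PhonemeFeatureTable | None = None,
    system: Literal["distinctive", "ipa"] = "distinctive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between feature columns of the word profiles.

    Returns ``(r, p)`` matrices, symmetric with unit diagonal.  Constant
    feature columns have undefined correlations, reported as NaN.
    """
    table = table or default_table()
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 records for feature correlations")
    features = DISTINCTIVE_FEATURES if system == "distinctive" else IPA_FEATURES
    df = encode_corpus(table, records, system=system)
    X = df[list(features)].to_numpy(dtype=float)
    k = len(features)
    r = np.eye(k)
    p = np.zeros((k, k))
    constant = X.std(axis=0) == 0
    for i in range(k):
        for jj in range(i + 1, k):
            if constant[i] or constant[jj]:
                r[i, jj] = r[jj, i] = np.nan
                p[i, jj] = p[jj, i] = np.nan
                continue
            rr, pp = sps.pearsonr(X[:, i], X[:, jj])
            r[i, jj] = r[jj, i] = rr
            p[i, jj] = p[jj, i] = pp
    if constant.any():
        logger.warning(
            "feature_correlations: constant column(s) %s reported as NaN",
            [features[i] for i in np.flatnonzero(constant)],
        )
    idx = list(features)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)
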