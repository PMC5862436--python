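# Methods

## Feature systems and the phoneme inventory

Two linked descriptions of each phoneme are used throughout.

The **distinctive-feature** system is a binary 12-vector in the fixed
order *(sonorant, syllabic, consonantal, continuant, nasal, high, low,
back, round, anterior, coronal, voiced)*. This order is canonical: all
serialization, matrices and profiles use it, so that e.g.
/f/ = (001100000100) reads the same everywhere.

The **IPA class** system carries 14 flags read off the IPA chart: four
consonant places (radical, dorsal, coronal, labial), four manners
(plosive, fricative, liquid, nasal), consonant voicing, three vowel
heights (open, mid, close), vowel roundness and backness. The
13-dimensional modelling space drops the voicing flag; its consonant
subset is the 8 place/manner columns and its vowel subset the 5
height/round/back columns.

The two systems are linked by wildcard patterns over distinctive
features, applied only within the phoneme's class:

| IPA class | pattern |
|---|---|
| labial | anterior ∧ ¬coronal |
| coronal (place) | coronal |
| dorsal | ¬anterior ∧ ¬coronal ∧ (high ∨ back) |
| radical | ¬anterior ∧ ¬coronal ∧ ¬high ∧ ¬back |
| plosive | ¬sonorant ∧ ¬continuant |
| fricative | ¬sonorant ∧ continuant |
| nasal (manner) | nasal |
| liquid | sonorant ∧ ¬nasal |
| close / open / mid | high / low / neither |
| round, back (vowel) | copied |

The packaged chart (`data/feature_chart.tsv`, 32 symbols: 24 consonants,
8 vowels) stores both descriptions explicitly, and the derivation is
checked against the stored flags exhaustively in the tests. The chart is
compiled from standard distinctive-feature and IPA chart assignments.
Two deliberate inventory choices:

* Glides /j/ and /w/ are marked +consonantal and fall in the liquid
  manner class. Classical feature theory would make them −consonantal;
  here the invariant *consonant ⇔ consonantal flag* is kept exact over
  the whole inventory, which the vowel/consonant feature subsetting
  relies on.
* IPA chart cells whose two symbols would collapse to the same feature
  point are **absorbed** into a single canonical symbol (the shipped
  `absorption.tsv` maps e.g. ɛ→e, ɔ→o, ɡ→g, ʀ→ʁ). Absorption keeps the
  symbol→feature-point map injective without adding feature dimensions.
  The map is data, not code: studies with richer transcriptions can ship
  their own pairs.

Tokenization is greedy longest-match over inventory symbols plus
absorbed variants, after NFC normalization. Unknown characters raise
(policy `strict`) or are dropped with an aggregated warning (`skip`,
used for orthographic material).

## Word encoding

A word of n phonemes is the n × d binary matrix of its phoneme vectors;
its profile is the column mean, so every profile value is an exact
rational k/n ∈ [0, 1]. Averaging discards phoneme order: reduplication,
lengthening and any temporal structure are invisible to every statistic
downstream. This is an explicit modelling choice, not an oversight.

Feature subsetting **column-selects** the all-phoneme mean by default: a
word's consonant-subset profile is the consonant columns of its overall
mean, so a vowel-only word has a legal all-zero consonant profile. The
alternative — re-averaging over only the phonemes of the class — is
available as `class_averaging=True`; with it, consonant proportions are
relative to the word's consonant count instead of its length. Both are
legitimate readings of "using only the consonant features"; column
selection is the default because it is a pure projection of one encoding
rather than a second encoding.

## Synthetic corpora

The generator emulates a three-block production experiment:

| block | stimuli | factors |
|---|---|---|
| A (audio) | 6 | 3 movements × 2 sound frequencies |
| V (video) | 12 | 2 shapes × 2 sizes × 3 movements |
| AV | 24 | all four factors |

One word per speaker × stimulus; 19 speakers by default → 798 words.

Words are sampled from CV skeletons (length law
{2: .15, 3: .35, 4: .30, 5: .15, 6: .05}; templates CV, CVC, CVCV,
CVCCV/CVCVC, CVCVCV) so every word contains both consonants and vowels.
The length/template law is arbitrary — the real corpus's law is not
published — and is exposed in the config.

Planted structure, with β interpolating between uniform (β = 0) and the
deterministic mapping (β = 1):

* consonant manner | movement: hit → plosive, slide → fricative,
  ring → liquid/nasal (½ each); `beta_manner` defaults to 0.7;
* vowel | condition: spiky shape or high-frequency sound → front
  unrounded vowels {i, e, a}; rounded shape or low-frequency sound →
  back rounded {u, o}; shape drives vowels in V, sound frequency in A;
  `beta_vowel` defaults to 0.7;
* audiovisual coupling (`av_coupling=True` by default): in the AV block
  the shape effect on vowels is suppressed and movement leaks into vowel
  choice (weight 0.3 of the planted component; hit → open, slide → close
  front, ring → back rounded vowels) — the multisensory regime in which
  movement is carried by both phoneme classes and shape is lost;
* speaker idiosyncrasy: per-speaker Gaussian log-preference offsets over
  manner classes and over individual vowels, scale `sigma_speaker`
  (default 0.5, logit units), applied multiplicatively and renormalized,
  so zero-probability classes stay zero;
* `v_code_permuted` (default off) gives the video block a deranged
  movement→manner code (hit→fricative-law, slide→ring-law, ring→hit-law),
  a construction for transfer analyses: a code unrelated across
  modalities should not transfer.

Phonemes are drawn uniformly within the selected class. The generator
returns the planted conditional distributions (`GroundTruth`) alongside
the records, and is byte-reproducible from its seed.

Defaults (β = 0.7, σ = 0.5) are meant as a realistic moderate-effect
regime: strong enough that planted manner features pass a 0.01/26
threshold with 19 speakers, weak enough that single words are often
ambiguous. What passing tests on such corpora shows is that the
*pipeline* recovers structure that is present at realistic effect sizes
and rejects it when absent; it does not show anything about real speech,
in which effects are graded, speaker strategies heterogeneous, and
phoneme choice correlated within words.

## ANOVA screen

Per feature and modality, a repeated-measures ANOVA on per-speaker
condition-cell means (statsmodels `AnovaRM`, cells aggregated by mean),
with the modality's manipulated factors as within-subject factors —
movement and sound in A, movement and shape in V, movement, shape and
sound in AV. Main-effect p-values only; object size is not a screened
factor. Significance is flagged at α/26 across the 12 + 14 dimensions
jointly (0.01/26 ≈ 3.8 × 10⁻⁴). Features with zero variance in a
modality yield no test and are reported as NaN. Exact p-values depend on
the unit-of-analysis convention; the screen's contract is the
significance *pattern*, not digit-level p-values.

## Deviation patterns

For one factor within one modality, the analysis unit is the per-speaker
condition-level mean profile. Each feature's level mean (over speakers)
is centred on the modality-wide mean and divided by a noise s.d., and
labelled `+` / `−` where |z| > k (default k = 3):

* `pooled_within` (default): the pooled s.d. of the speaker units around
  their level means. This is a signal-to-noise scaling; a level mean 3
  within-level s.d. away from the modality mean is a strong, consistent
  displacement.
* `modality`: the raw s.d. over all speaker units. Note that under this
  unit |z| cannot exceed ≈ √(L−1) for L factor levels (the level means
  are part of the population the s.d. is computed over), so with 2–3
  levels the ±3 criterion can never fire; the option exists for
  exploratory use with smaller k.

Zero-s.d. features are labelled `0` with a warning; k = 0 degenerates to
sign labelling.

## Decoding

LDA is scikit-learn's `LinearDiscriminantAnalysis` (lsqr solver) with the
pooled covariance shrunk by a fixed 10⁻⁴ toward its diagonal — enough to
survive exactly collinear columns (the three height flags sum to the
vowel proportion) without materially distorting the discriminant. Class
priors are training frequencies; prediction is argmax of the linear
discriminant.

Folds partition *speakers*, not words, into k groups differing by at
most one speaker (19 speakers, k = 10 → nine folds of 2 and one of 1).
Fold draws are redrawn (up to 50 times, with a warning) if any training
side would miss a class; a class rarer than that is a design problem the
caller must fix. Each repetition draws fresh folds from the task's
master seed; per repetition the k held-out prediction sets are pooled
into one count matrix, row-normalized to proportions, and scored by
macro φ computed from the pooled counts. Repetitions are summarized
cell-wise by median and IQR (mean also reported). φ with any zero margin
is 0 by convention — the score of chance-level classification.

Cross-modality transfer: per repetition, the k fold-classifiers of the
training modality (each fit on k−1 folds) all predict the complete test
modality corpus; their k proportion matrices and φ values are averaged,
and repetitions summarized by median/IQR. Applying the protocol with
train = test reproduces the within-modality result up to the
train-on-9/10 difference, a consistency check in the tests.

An optional robustness mode (`aggregate_per_speaker`) averages each
speaker's profiles within each target class before cross-validation, so
each speaker contributes one point per class.

## Cross-linguistic application

Forms are tokenized with the skip policy; forms losing more than half
their characters are dropped, duplicate (action, language) rows keep the
last occurrence, and actions attested in fewer than 10 languages are
excluded. The decoder (trained on the AV block, all 13 features) hard-
assigns each form; per-action distributions are exact language-count
fractions. Rater percentages are renormalized per rater × action before
averaging (the average-then-normalize order is a switch); agreement is
Pearson r over all (action × movement) cells jointly, with a
per-movement breakdown. A constant vector on either side makes r
undefined; it is reported as 0 with p = 1.

## Problem sizes in the shipped tests and acceptance script

Decoding repetitions are the main cost knob. The package default is
1000 repetitions, matching how such analyses are usually reported; the
test suite and `scripts/acceptance.py` use 10–50 repetitions and
corpora of 798 words, which puts the φ median's repetition noise well
inside the tolerances asserted (fold-to-fold IQR at these sizes is
≈ 0.01–0.04). The β-monotonicity check uses 20 seeds per β on the audio
block at 3 repetitions. The full suite runs in well under a minute on
one CPU; the acceptance script in ≈ 20 s.

## Known limitations

* Temporal structure (order, reduplication, length contrasts) is
  discarded by design; nothing downstream can see it.
* The inventory is compact (32 canonical symbols). Corpora with richer
  transcriptions need an extended chart; the loader validates any
  user-supplied chart and absorption map.
* Orthography-as-IPA is a crude reading for cross-linguistic lists;
  results there are indicative, not phonetically grounded, and no
  control for language relatedness is attempted.
* The ANOVA screen fits main effects only, on balanced designs; the
  mixed-model (random-intercept) alternative is not implemented.
* The synthetic generator plants class-conditional phoneme distributions
  with independent draws across a word's slots; real words have
  phonotactic dependencies it does not model.
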