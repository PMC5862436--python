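# sonosym

Phonological feature encoding and decoding of sound-symbolic words.

`sonosym` is a toolkit for studying how improvised onomatopoeias encode
properties of multisensory events — the kind of experiment in which
speakers watch and/or hear objects hitting, sliding or ringing and coin a
non-word for each stimulus. It is written for computational
psycholinguists and phoneticians who want a tested, reproducible pipeline
from IPA transcriptions to decoding statistics, without the study-specific
scripts such analyses usually live in.

## What it computes

**Encoding.** Each IPA phoneme is a binary vector of 12 distinctive
features (*sonorant, syllabic, consonantal, continuant, nasal, high, low,
back, round, anterior, coronal, voiced*) and, equivalently, a set of IPA
chart classes (consonant place and manner, voicing, vowel height,
roundness, backness). A word of n phonemes is the n × 12 binary matrix of
its phonemes; averaging across rows maps every word to a point of
[0, 1]¹², the relative weight of each feature in the word. For the
machine-learning feature space the IPA classes give 13 features (4 places,
4 manners, 3 heights, round, back), with consonant (8) and vowel (5)
subsets.

**Screening.** One repeated-measures ANOVA per feature and modality
(subjects as the repeated unit), Bonferroni-corrected across the 26
dimensions (p < 0.01/26 ≈ 0.00038); ±3 s.d. deviation maps per condition
level; the feature × feature Pearson correlation matrix.

**Decoding.** Linear discriminant analysis with speaker-grouped k-fold
cross-validation (all words of a speaker stay on one side of every
split), repeated with fresh folds and summarized as median ± IQR. The
score is the macro-averaged Matthews coefficient

φ = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

averaged with equal weight over one-vs-rest classes; +1 is perfect
decoding, 0 chance, −1 complete disagreement. Cross-modality transfer
trains the k fold-classifiers in one modality and applies each to the
full corpus of another.

**Application.** A trained audiovisual movement decoder can classify
cross-linguistic onomatopoeia lists (orthography read as IPA) and the
per-action movement distributions can be correlated with human ratings.

**Simulation.** Because transcribed corpora of this kind are rarely
redistributable, a generator produces synthetic corpora with the same
factorial design (19 speakers × 6 audio + 12 video + 24 audiovisual
stimuli = 798 words) and *planted* effects: hits pull plosives, slides
fricatives, rings liquids/nasals; spiky shapes and high-frequency sounds
pull front unrounded vowels, rounded shapes and low-frequency sounds back
rounded ones. Effect strengths, speaker idiosyncrasy and the audiovisual
coupling regime are tunable, so every downstream stage can be validated
against known ground truth.

## Worked example

```python
from sonosym import (SyntheticConfig, generate_corpus, DecodingTask,
                     within_modality_decode)

records, truth = generate_corpus(SyntheticConfig(seed=0))   # 798 records
task = DecodingTask(target="movement", modality_train="AV",
                    modality_test="AV", subset="consonant", reps=20, seed=1)
res = within_modality_decode(records, task)
print(res.phi_median, res.phi_iqr)
print(res.confusion_median.round(2))
```

prints

```
0.73 0.01
        hit  ring  slide
hit    0.87  0.09   0.04
ring   0.11  0.75   0.14
slide  0.06  0.11   0.84
```

i.e. movement type is recovered from consonant features alone at
φ ≈ 0.73, with 75–87% of each movement's words on the confusion
diagonal. Running the same task with `subset="vowel"` drops φ to ≈ 0.29
in the audiovisual block and to chance in the unisensory blocks — the
planted division of labor (consonants carry movement, vowels carry
shape/frequency) is recovered by the decoder. The `examples/` directory
holds one short script per capability (encoding, simulation, screening,
decoding, transfer, cross-linguistic application), each printing and
explaining its numbers.

A thin CLI wraps the same stages for shell use:

```bash
sonosym simulate --seed 0 --out-dir run/
sonosym decode --corpus run/corpus.tsv --modality AV --subset consonant \
    --reps 100 --out-dir run/
```

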