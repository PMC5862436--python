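"""Classify cross-linguistic onomatopoeias with an AV-trained decoder.

Trains the movement classifier on the audiovisual block of a synthetic
corpus, applies it to a synthetic multi-language word list (orthographic
forms treated as IPA), and compares the per-action movement distributions
with synthetic human ratings.
"""

from sonosym import (
    SyntheticConfig,
    classify_actions,
    compare_to_ratings,
    generate_corpus,
    generate_wordlist,
    ingest_wordlist,
    train_movement_classifier,
)

records, _ = generate_corpus(SyntheticConfig(seed=0))
model = train_movement_classifier(records, modality="AV", subset="all")

wordlist, ratings = generate_wordlist(seed=1)
words = ingest_wordlist(wordlist)
dist = classify_actions(model, words)

print("fraction of languages classified as hit / slide / ring per action:")
print(dist.round(2).to_string())

comp = compare_to_ratings(dist, ratings)
print(f"\nagreement with human ratings: r = {comp['r']:.2f} "
      f"(p = {comp['p']:.1e}, {comp['n_cells']} cells)")
print(
    "\nSimple actions (crash, doorbell) concentrate in one movement column;"
    "\ncomposite actions (falling or wet strikes) spread across columns, and"
    "\nthe spread matches what raters report."
)
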