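"""Generate a synthetic onomatopoeia corpus with planted structure.

Builds the default cohort — 19 speakers × (6 audio + 12 video + 24
audiovisual stimuli) — in which consonant manner encodes movement type and
vowel backness/roundness encodes shape or sound frequency.
"""

from sonosym import SyntheticConfig, generate_corpus
from sonosym.io import modality_counts

cfg = SyntheticConfig(seed=0)
records, truth = generate_corpus(cfg)

print(f"{len(records)} records: {modality_counts(records)}")
print("\nfirst three records:")
for r in records[:3]:
    print(f"  {r.speaker} {r.modality:2s} {r.movement:5s} "
          f"shape={r.shape} sound={r.sound} -> {r.ipa}")

print("\nplanted manner distribution given movement (any modality):")
print(truth.manner.loc["A"].round(3))
print(
    "\nAt beta_manner=0.7 each movement pulls 77.5% of consonants from its"
    "\nsignature manner (hit→plosive, slide→fricative, ring→liquid/nasal);"
    "\nthe rest are uniform noise, plus per-speaker preference offsets."
)
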