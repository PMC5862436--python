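"""Encode a single onomatopoeia into phonological feature space.

Tokenizes the IPA string "fuŋ" (a word coined for an object sliding on a
plane), stacks the 12-dim distinctive-feature vectors of its phonemes into
a matrix, and averages across phonemes to the word's feature profile.
"""

import numpy as np

from sonosym import DISTINCTIVE_FEATURES, default_table, to_matrix, to_profile

table = default_table()
phonemes = table.tokenize("fuŋ")
print(f"tokens: {phonemes}")

matrix = to_matrix(table, phonemes, system="distinctive")
for ph, row in zip(matrix.phonemes, matrix.values):
    print(f"/{ph}/ = ({''.join(map(str, row))})")

profile = to_profile(matrix)
print("\nword profile (mean across phonemes):")
for name, value in zip(DISTINCTIVE_FEATURES, profile.values):
    if value > 0:
        print(f"  {name:12s} {value:.3f}")
print(
    "\nEach value is the fraction of the word's phonemes carrying that"
    "\nfeature; e.g. consonantal = 2/3 because /f/ and /ŋ/ are consonants"
    "\nwhile /u/ is a vowel."
)
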