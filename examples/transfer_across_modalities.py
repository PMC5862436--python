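"""Test whether a movement code learned in one modality transfers to another.

Classifiers are trained on the fold structure of one modality and applied
to the full corpus of another.  With the default generator all blocks share
one movement→manner code, so transfer succeeds everywhere; switching
``v_code_permuted`` gives the video block an unrelated code, and transfer
to/from video collapses while audio ↔ audiovisual transfer survives.
"""

from sonosym import DecodingTask, SyntheticConfig, cross_modality_decode, generate_corpus

for permuted in (False, True):
    cfg = SyntheticConfig(v_code_permuted=permuted, seed=0)
    records, _ = generate_corpus(cfg)
    label = "permuted video code" if permuted else "shared code"
    print(f"--- {label} ---")
    for train, test in (("A", "AV"), ("AV", "A"), ("A", "V"), ("AV", "V")):
        task = DecodingTask(target="movement", modality_train=train,
                            modality_test=test, subset="all", reps=10, seed=2)
        res = cross_modality_decode(records, task)
        print(f"  {train:2s} -> {test:2s}: phi = {res.phi_median:+.2f}")
    print()
print("phi near 0 (or below) means the training modality's sound-symbolic"
      "\ncode carries no information about the test modality's.")
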