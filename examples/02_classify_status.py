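"""Train the hotspot-windowed status classifier and classify new notes.

Only text within a few words of a tobacco keyword stem ("smok", "cig",
"tobac", "nicoti") reaches the SVM; notes without any such hotspot are
assigned 'unknown' by rule, without ever consulting the model.
"""

from smokereg import (
    ClinicalNote,
    SynthConfig,
    TrainConfig,
    fit,
    generate,
    note_window_text,
    predict,
)

train = generate(SynthConfig(n_notes=400, seed=42))
model = fit(train, TrainConfig(seed=0))
print(f"Trained on {len(train)} notes; vocabulary size {len(model.feature_space.vocabulary)}.")

examples = [
    ClinicalNote("a", "SOCIAL HISTORY:\nHe is a former smoker who quit in 1998."),
    ClinicalNote("b", "SOCIAL HISTORY:\nSmokes 1 ppd. Counseled on cessation."),
    ClinicalNote("c", "SOCIAL HISTORY:\nDenies tobacco use. Never smoker."),
    ClinicalNote("d", "IMPRESSIONS:\nBP 120/80. Lipid panel within normal limits."),
]
for note in examples:
    window = note_window_text(note, model.train_config.hotspot)
    pred = predict(model, note)
    how = "no-hotspot rule" if pred.via_hotspot_rule else "SVM"
    print(f"\n{note.text.splitlines()[-1]}")
    print(f"  hotspot window: {window!r}")
    print(f"  -> {pred.status.value}  (via {how})")

# The last note has no tobacco hotspot, so it is 'unknown' by construction:
# the classifier never sees text it has no lexical reason to trust.
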