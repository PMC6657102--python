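"""Evaluate predictions against gold labels on a held-out synthetic split.

The report gives one-vs-rest precision/recall/F1 per class, micro-F1
(identical to accuracy for single-label data), and an 'ever smoker' merge
where confusions among the three smoker classes no longer count as errors.
"""

from smokereg import (
    ConfusionMatrix,
    Corpus,
    SynthConfig,
    TrainConfig,
    fit,
    generate,
    per_class_report,
    predict,
)

corpus = generate(SynthConfig(n_notes=500, seed=42))
train_notes, test_notes = corpus.notes[:400], corpus.notes[400:]
train = Corpus(
    notes=train_notes,
    annotations={n.note_id: corpus.annotations[n.note_id] for n in train_notes},
)
model = fit(train, TrainConfig(seed=0))

gold = [corpus.annotations[n.note_id].status for n in test_notes]
pred = [predict(model, n).status for n in test_notes]
report = per_class_report(ConfusionMatrix.from_pairs(gold, pred))

print(f"Held-out notes: {len(test_notes)}   micro-F1: {report.micro_f1:.3f}")
print(f"{'class':<10}{'precision':>10}{'recall':>10}{'F1':>10}{'n':>6}")
for status, m in report.per_class.items():
    fmt = lambda v: "  n/a" if v is None else f"{v:10.3f}"
    print(f"{status.value:<10}{fmt(m.precision)}{fmt(m.recall)}{fmt(m.f1_score)}{m.n:>6}")

sens, spec = report.merged_ever
print(f"\nEver-smoker merge: sensitivity {sens:.3f}, specificity {spec:.3f}")
print("Merging former/current/smoker removes within-smoker confusions, so the")
print("merged sensitivity can only match or exceed any single smoker-class recall.")
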