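"""Generate a small labelled synthetic note corpus and look inside it.

The generator emits template-based clinical notes with gold smoking status,
pack-year values, and cessation dates embedded at known character spans, so
every downstream component can be tested against exact truth.
"""

from collections import Counter

from smokereg import SynthConfig, generate

corpus = generate(SynthConfig(n_notes=50, seed=42))

print(f"Generated {len(corpus)} notes.")
counts = Counter(g.status.value for g in corpus.annotations.values())
print("Gold status mix:", dict(sorted(counts.items())))

note = corpus.notes[0]
gold = corpus.annotations[note.note_id]
print(f"\n--- {note.note_id} (gold status: {gold.status.value}) ---")
print(note.text)

# Each behavior annotation carries the exact span of the sentence it came from.
if "pack_year_span" in gold.metadata:
    lo, hi = gold.metadata["pack_year_span"]
    print(f"\nGold pack-year evidence at [{lo}:{hi}]: {note.text[lo:hi]!r}")
else:
    print("\nThis note carries no pack-year evidence (as most real notes do not).")
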