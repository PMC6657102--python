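# smokereg

Build a **Smokers' Registry** from free-text clinical notes.

Tobacco exposure is one of the strongest predictors of cancer and
cardiopulmonary risk, yet in most electronic health records it lives in
unstructured narrative ("45 pack year history, quit 03/2010") rather than in
coded fields. `smokereg` is a small, fully deterministic NLP pipeline that
turns such notes into registry tables suitable for cohort identification,
lung-cancer-screening eligibility checks, and recruitment:

1. **Status classification.** Every note receives one of five smoking
   statuses — `never`, `former`, `current`, `smoker` (smoker, temporality
   unknown), or `unknown`. A linear SVM sees only *hotspot windows*: the
   ±5 words around any occurrence of the keyword stems `smok`, `cig`,
   `tobac`, `nicoti`, truncated at sentence boundaries. Notes with no
   hotspot are assigned `unknown` by rule and never reach the model.
2. **Behavior extraction**, gated to smoker-classified notes only:
   - *Pack-year history* via a tiered rule hierarchy: an explicit pack-year
     statement wins; otherwise packs/day (or cigarettes/day at 20 per pack)
     multiplied by years smoked gives a *computed* value; intensity or
     duration alone gives a *partial* finding.
   - *Cessation dates*, which must share a sentence with a quit cue
     ("quit", "stopped smoking", …). Each date carries a precision
     (day/month/year); vague decades ("the late 1980s") and ranges are
     rejected rather than guessed.
3. **Registry assembly**: a de-identified population table for prevalence
   and eligibility queries, a contact table with identifiers for
   recruitment, and a patient-level aggregation (most recent status,
   maximum pack-years).

The package also ships an evaluation module (per-class precision/recall/F1,
micro-F1, sensitivity/specificity, an "ever smoker" merge, and 2×2
presence/absence evaluation of extraction) and a deterministic synthetic
note generator that embeds gold labels and evidence spans, so the entire
pipeline can be developed and tested without access to protected health
information.

## Worked example

Train on a synthetic corpus and classify a few notes
(`examples/02_classify_status.py`):

```python
from smokereg import ClinicalNote, SynthConfig, TrainConfig, fit, generate, predict

train = generate(SynthConfig(n_notes=400, seed=42))
model = fit(train, TrainConfig(seed=0))
print(predict(model, ClinicalNote("a", "He is a former smoker who quit in 1998.")).status)
```

Output (abridged) of the example script:

```
Trained on 400 notes; vocabulary size 93.

He is a former smoker who quit in 1998.
  hotspot window: 'He is a former smoker who quit in 1998'
  -> former  (via SVM)

Smokes 1 ppd. Counseled on cessation.
  hotspot window: 'Smokes 1 ppd'
  -> current  (via SVM)

BP 120/80. Lipid panel within normal limits.
  hotspot window: None
  -> unknown  (via no-hotspot rule)
```

Behavior extraction (`examples/03_extract_behaviors.py`):

```
  '45 pack year smoking history.'
    kind=complete  pack_years=45.0
  'Smokes 2 packs per day for 15 years.'
    kind=computed  pack_years=30.0  ppd=2.0  years=15.0
  'Smokes 10 cigarettes a day for 10 years.'
    kind=computed  pack_years=5.0  cpd=10.0  years=10.0
  'Smokes about half a pack per day.'
    kind=partial   ppd=0.5

  'Quit smoking 03/15/2010.'               -> 2010-03-15 (precision: day)
  'Patient stopped smoking March 2008.'    -> 2008-03-01 (precision: month)
  'She quit tobacco in 1995.'              -> 1995-01-01 (precision: year)
  'Quit in the late 1980s.'                -> no finding
  'Labs drawn 03/15/2010. Quit previously.' -> no finding
```

End-to-end evaluation on a held-out synthetic split
(`examples/05_evaluate.py`):

```
Held-out notes: 100   micro-F1: 0.990
class      precision    recall        F1     n
never          0.941     1.000     0.970    16
former         1.000     1.000     1.000    16
current        1.000     1.000     1.000    17
smoker         1.000     0.667     0.800     3
unknown        1.000     1.000     1.000    48

Ever-smoker merge: sensitivity 0.972, specificity 1.000
```

All five scripts in `examples/` run in a few seconds each:
`python examples/01_generate_corpus.py`, etc.

## Command-line interface

```bash
smokereg synth   --n 500 --seed 7 --out corpus.jsonl
smokereg train   --notes corpus.jsonl --model model.json --seed 0
smokereg run     --notes corpus.jsonl --model model.json --out-dir out/
smokereg evaluate --gold corpus.jsonl --pred out/predictions.jsonl --report report.json
```

`run` writes `predictions.jsonl`, the three registry CSVs, and a
`manifest.json` recording input hashes and the configuration used. Exit
codes: 1 usage error, 2 data error, 3 internal error.

## Repository layout

- `src/smokereg/` — the library (`corpus`, `hotspots`, `classifier`,
  `extraction`, `metrics`, `registry`, `synth`, `cli`) and versioned data
  files (stopword list, extraction rules, note templates).
- `examples/` — five short narrative scripts, one per capability.
- `docs/methods.md` — model, parameters, generator design, and limitations.
- `tests/` — the full suite, including `tests/test_acceptance.py`.
- `scripts/acceptance.py` — the reproduction script described above.
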