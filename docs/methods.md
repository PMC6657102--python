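# Methods

This document describes the model behind `smokereg`, the parameters it
exposes and their defaults, the design of the synthetic note generator, and
the numerical and engineering choices that make every result reproducible.

## 1. Status classification

### Hotspot windows

Clinical notes are long and mostly off-topic: a whole-document
bag-of-words drowns the one smoking sentence in vitals, medication lists,
and assessments. The classifier therefore sees only *hotspot windows*.
A hotspot is any substring occurrence of a tobacco keyword stem —
`smok`, `cig`, `tobac`, `nicoti` by default (`hotspots.DEFAULT_STEMS`;
a six-stem legacy set is available via `HotspotConfig.legacy()`). Around
the token containing each hotspot, a window of ±`window_size` words
(default 5) is taken, truncated at sentence boundaries so evidence never
leaks across sentences. Sentences are split on `.`, `!`, `?`, and
newlines; tokens are maximal `[0-9a-z]+` runs of the lowercased text.

Multiple windows from one note are joined with the reserved token
`xxwindowboundaryxx`, which is excluded from the vocabulary, so windows
never form cross-window bigram-like artifacts in the count space.

Notes with **no hotspot receive `unknown` by rule** and never reach the
model. This is both an efficiency device and a calibration device: the
majority of notes say nothing about tobacco, and a discriminative model
should not be asked to have an opinion about them.

### Learner

- Unigram counts over the window text; vocabulary fixed at fit time,
  sorted, frozen (`FeatureSpace`).
- Stopwords from the versioned list `data/stopwords_en_v1.txt`, **minus
  the negations** `neither, never, no, nor, not` — "never smoker" vs
  "smoker" hinges on exactly these words.
- Linear support-vector classifier (scikit-learn `LinearSVC`), linear
  kernel, `C = 1.0`, `class_weight="balanced"` (the status distribution is
  heavily skewed toward `unknown` and `never`), `max_iter = 10000`.
- The fixed class order `never < former < current < smoker (temporality
  unknown) < unknown` is canonical (`STATUS_ORDER`); prediction takes the
  argmax of the decision scores
  with first-wins tie-breaking in that order, so results are deterministic
  even at exact ties.

Two determinism measures go beyond seeding: training rows are **sorted by
note id** before fitting (liblinear is sample-order-sensitive, so this
makes training invariant to corpus permutation), and the model is trained
on integer class indices so `classes_` is always in canonical order.
Models serialize to a JSON archive (`smokereg-status-model-v1`) holding the
vocabulary, weights, stopword-list hash, and training configuration;
save → load → predict is bit-identical.

`cross_validate` builds per-class round-robin folds from a seeded
permutation (`numpy.random.default_rng(config.seed)`), so every fold holds
(nearly) the class mix of the whole corpus.

## 2. Behavior extraction

Extraction runs **only on smoker-classified notes** (`former`, `current`,
`smoker`); the gate lives in `registry.run_pipeline`. Rules are regular
expressions in the versioned file `data/rules_v1.json`. Quantities may be
digits, decimals, simple fractions, or the words one–ten / "half" /
"a" / "an".

### Pack-years (tiered, short-circuiting)

1. **pack years** stated explicitly → `kind="complete"`.
2. **packs/day AND years smoked** → `kind="computed"`,
   `pack_years = round(ppd × years, 1)`.
3. **cigarettes/day AND years smoked** → `kind="computed"` with
   `ppd = cpd / 20` (`CIGARETTES_PER_PACK = 20`).
4. any single component → `kind="partial"` (still clinically useful:
   "smokes 1 ppd" identifies a current smoker's intensity).

Within a tier the earliest match in document order wins; a higher tier
always beats a lower one. The finding records the contributing source
span(s) for provenance.

### Cessation dates

A date is accepted only if it shares a sentence with a cessation cue
("quit", "stopped", "cessation", "gave up", "ex-smoker since", …) and
parses as an anchored calendar expression: `MM/DD/YYYY`, `Month DD, YYYY`,
`Month YYYY`, `MM/YYYY`, `YYYY`, or `'YY`. Each finding carries a
**precision** (`day` / `month` / `year`); month- and year-precision dates
are stored as the first day of the period, and the precision field — not
the stored day — is authoritative. Two-digit years pivot at 30
(00–29 → 2000s, else 1900s). Decades ("the 1980s"), ranges
("1995 to 1998"), and bare numbers that are actually durations
("quit 10 years ago") are **rejected rather than guessed**: a registry
with a missing quit date is recoverable; one with a fabricated quit date
is not.

## 3. Evaluation

- Per-class one-vs-rest precision/recall/F1; `sensitivity` is recall and
  `specificity` is `tn / (tn + fp)` of the one-vs-rest 2×2.
- **micro-F1**: pooled TP is the confusion-matrix trace; pooled FP and FN
  both equal the off-diagonal total, so micro-F1 is exactly accuracy for
  single-label data. The test suite asserts this identity against 10,000
  random matrices and cross-checks per-class values against
  scikit-learn's implementations.
- Undefined rates (0/0) are reported as `None`, never silently as 0.
- **Ever-smoker merge** pools `former`/`current`/`smoker` into one
  category, turning within-smoker confusions into correct calls — the
  operative question for a screening registry is *ever* exposure.
- `two_by_two_eval` gives presence/absence sensitivity/specificity for the
  extraction steps.

## 4. Synthetic corpus generator

The generator (`synth.py`, templates in `data/templates_v1.json`, template
bank version 1) emulates outpatient notes with VITALS / SOCIAL HISTORY /
HEALTH SUMMARY / IMPRESSIONS sections. Defaults model a realistic EHR
mix and are **fixed design parameters, not tuning knobs**:

- `status_mix = (0.23, 0.135, 0.14, 0.015, 0.48)` for never / former /
  current / smoker / unknown — about half of notes say nothing about
  tobacco, and explicit "smoker, temporality unknown" wording is rare.
- Among smoker notes, 30% carry a determinable pack-year statement and a
  further 10% a partial one (so partial findings are ~25% of all pack-year
  evidence); 40% of former-smoker notes carry a cessation date, spanning
  six surface formats; visit dates fall in one calendar week
  (2016-03-28 … 04-04); ~10% of patients contribute a repeat note.
- Distractor material includes non-cessation dates, a "Smoke detector…"
  hotspot-bearing but status-neutral sentence, and vague cessation
  phrases that must extract to nothing.

Randomness comes from `random.Random(seed)` (Mersenne Twister — stable
across platforms and Python versions, unlike `hash`-based schemes). Status
and filler choices are random draws, but cessation formats and pack-year
sub-categories are assigned by **deterministic cycling**, which guarantees
that a default-size corpus (500 notes) exercises every template category
(`template_coverage_report` verifies this). Every behavior sentence's gold
values and character span are recorded in the annotation metadata, giving
an exact oracle for extraction.

**What the generator does not emulate:** misspellings, OCR noise,
abbreviation ambiguity, relative quit dates ("quit 3 months ago"),
negation scattered across sentences, and the full lexical diversity of
real notes. Templated text is far easier to classify than real notes, so
held-out micro-F1 near 1.0 on synthetic data is a *correctness* check of
the pipeline, not a clinical performance estimate.

## 5. Numerical and engineering choices

- All derived seeds stay below 2³¹; every random source in the acceptance
  script derives from its `--seed`.
- Pack-year values round to 1 decimal; metric values are exact floats,
  rounded only at display.
- scikit-learn supplies the learner; scikit-learn metrics are used only as
  a *test oracle* against this package's own metric implementations.
- `datetime.date` (stdlib) backs dates; the separate precision field
  avoids the false day-level precision a bare date would imply.
- The CLI writes a `manifest.json` with the SHA-256 of each input and the
  configuration hash, so any output can be traced to its exact inputs.

## 6. Limitations

- Cessation cues have no negation guard. "Denies quitting" yields no date
  only because that sentence contains no date; a sentence like "did not
  quit until 2005" would still yield 2005 — a known sharp edge.
- Relative temporal expressions ("quit ten years ago") are out of scope;
  resolving them requires a reliable note date and introduces a silent
  error mode the registry cannot audit.
- Substring hotspot stems over-trigger on rare words ("smokescreen");
  the classifier, not the stem list, is responsible for such cases.
- Status is assigned per note; patient-level aggregation uses simple
  recency/maximum rules rather than probabilistic reconciliation.
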