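"""Deterministic generator of labelled, semi-structured synthetic clinical notes.

Real smoking-challenge and hospital corpora are restricted-access, so the
package ships a generator that emulates their structure: semi-structured
visit notes with ``VITALS`` / ``SOCIAL HISTORY`` / ``HEALTH SUMMARY`` /
``IMPRESSIONS`` sections, smoking sentences in varied phrasings, complete
and partial consumption quantities, quit dates in every supported format
(plus unparseable decade phrases), and distractor numerics and service
dates (lab panels, follow-up dates) that exercise the false-positive paths.

Default conditions mirror the emulated hospital corpus: the status mix is
the five-class distribution observed there (never 23%, former 13.5%,
current 14%, temporality-unknown 1.5%, no-information 48%), visit dates
fall in the one-week window the notes were drawn from, and roughly a
quarter of determinable pack-year mentions are recorded as intensity +
duration rather than an explicit pack-year figure.

The generator uses ``random.Random`` (Mersenne Twister), which is fully
specified and portable, so a given seed yields a byte-identical corpus on
any platform.  Every note carries a full gold annotation, including the
character span of each embedded behavior sentence: running the extractor
directly on a gold span must reproduce the embedded quantity exactly, which
is the end-to-end oracle the tests rely on.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field
from importlib import resources

from .corpus import ClinicalNote, Corpus, GoldAnnotation, SmokingStatus

TEMPLATE_BANK_VERSION = "1"

#: five-class mix emulating the hospital test corpus (never, former,
#: current, smoker, unknown)
DEFAULT_STATUS_MIX = (0.23, 0.135, 0.14, 0.015, 0.48)

_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
]

_CESSATION_FORMATS = (
    "slash_day", "short_slash_day", "month_day_year", "month_year", "year",
    "vague_decade",
)
_DETERMINABLE_CATEGORIES = ("complete", "computed_ppd", "computed_cpd")
_PARTIAL_CATEGORIES = ("partial_ppd", "partial_cpd", "partial_years")

_VERBS_PRESENT = {"smokes": ["smokes", "currently smokes"], "smoked": ["has smoked"]}
_VERBS_PAST = {"smokes": ["smoked", "previously smoked"], "smoked": ["smoked", "had smoked"]}
_VERBS_NEUTRAL = {"smokes": ["reports", "admits to"], "smoked": ["smoked"]}

_PACK_YEAR_POOL = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 60.0]
_PPD_POOL = [0.5, 1.0, 1.5, 2.0, 3.0]
_CPD_POOL = [5.0, 10.0, 15.0, 20.0, 30.0, 40.0]
_YEARS_POOL = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0]

#: the template categories the bank must exercise at realistic corpus sizes
REQUIRED_CATEGORIES = frozenset(
    {
        "behavior:complete",
        "behavior:computed_ppd",
        "behavior:computed_cpd",
        "behavior:partial_ppd",
        "behavior:partial_cpd",
        "behavior:partial_years",
        "cessation:slash_day",
        "cessation:short_slash_day",
        "cessation:month_day_year",
        "cessation:month_year",
        "cessation:year",
        "cessation:vague_decade",
        "distractor:date",
        "unknown:hotspot",
        "unknown:no_hotspot",
    }
)


def load_templates(version: str = TEMPLATE_BANK_VERSION) -> dict:
    name = f"templates_v{version}.json"
    raw = resources.files("smokereg.data").joinpath(name).read_text("utf-8")
    return json.loads(raw)


@dataclass(frozen=True)
class SynthConfig:
    """Generator conditions; defaults emulate the source corpus (see module docs)."""

    n_notes: int = 500
    seed: int = 0
    status_mix: tuple[float, float, float, float, float] = DEFAULT_STATUS_MIX
    p_pack_year_complete: float = 0.3   # determinable: explicit or computable
    p_pack_year_partial: float = 0.1    # one quantity only
    p_cessation_date: float = 0.4       # among former smokers
    p_distractor: float = 0.5           # date-bearing distractor sentences
    p_hotspot_unknown: float = 0.3      # unknowns that still contain a hotspot
    template_bank_version: str = TEMPLATE_BANK_VERSION

    def __post_init__(self) -> None:
        if self.n_notes < 0:
            raise ValueError("n_notes must be non-negative")
        if len(self.status_mix) != 5:
            raise ValueError("status_mix must have five entries")
        if any(not 0.0 <= p <= 1.0 for p in self.status_mix):
            raise ValueError("status_mix entries must be probabilities")
        if abs(sum(self.status_mix) - 1.0) > 1e-9:
            raise ValueError(f"status_mix must sum to 1 (got {sum(self.status_mix)})")
        for name in (
            "p_pack_year_complete", "p_pack_year_partial", "p_cessation_date",
            "p_distractor", "p_hotspot_unknown",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_pack_year_complete + self.p_pack_year_partial > 1.0:
            raise ValueError("pack-year probabilities must sum to <= 1")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


class _NoteBuilder:
    """Accumulates note text while tracking character spans of added lines."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._len = 0

    def line(self, text: str) -> tuple[int, int]:
        start = self._len
        self._parts.append(text + "\n")
        self._len += len(text) + 1
        return (start, start + len(text))

    def blank(self) -> None:
        self.line("")

    @property
    def text(self) -> str:
        return "".join(self._parts)


def _render_cessation(fmt: str, rng: random.Random, bank: dict):
    """Returns (sentence, gold date or None, precision or None)."""
    year = rng.randint(1970, 2015)
    month = rng.randint(1, 12)
    day = rng.randint(1, 28)
    tmpl = bank["cessation"][fmt]
    if fmt == "slash_day":
        text = tmpl.format(mm=f"{month:02d}", dd=f"{day:02d}", yyyy=year)
        return text, _dt.date(year, month, day), "day"
    if fmt == "short_slash_day":
        text = tmpl.format(m=month, d=day, yy=f"{year % 100:02d}")
        return text, _dt.date(year, month, day), "day"
    if fmt == "month_day_year":
        text = tmpl.format(month=_MONTH_NAMES[month - 1], d=day, yyyy=year)
        return text, _dt.date(year, month, day), "day"
    if fmt == "month_year":
        text = tmpl.format(month=_MONTH_NAMES[month - 1], yyyy=year)
        return text, _dt.date(year, month, 1), "month"
    if fmt == "year":
        text = tmpl.format(yyyy=year)
        return text, _dt.date(year, 1, 1), "year"
    if fmt == "vague_decade":
        text = tmpl.format(decade=rng.choice([1960, 1970, 1980, 1990]))
        return text, None, None
    raise ValueError(f"unknown cessation format {fmt!r}")


def _render_behavior(category: str, rng: random.Random, bank: dict, status: SmokingStatus):
    """Returns (sentence, gold value bundle, kind)."""
    verbs = {
        SmokingStatus.CURRENT: _VERBS_PRESENT,
        SmokingStatus.FORMER: _VERBS_PAST,
        SmokingStatus.SMOKER: _VERBS_NEUTRAL,
    }[status]
    tmpl = rng.choice(bank["behavior"][category])
    fields = {
        "smokes": rng.choice(verbs["smokes"]),
        "smoked": rng.choice(verbs["smoked"]),
    }
    values: dict[str, float] = dict(tmpl.get("const", {}))
    if "{v}" in tmpl["text"]:
        values["pack_years"] = rng.choice(_PACK_YEAR_POOL)
        fields["v"] = _fmt_num(values["pack_years"])
    if "{i}" in tmpl["text"]:
        values["packs_per_day"] = rng.choice(_PPD_POOL)
        fields["i"] = _fmt_num(values["packs_per_day"])
    if "{c}" in tmpl["text"]:
        values["cigarettes_per_day"] = rng.choice(_CPD_POOL)
        fields["c"] = _fmt_num(values["cigarettes_per_day"])
    if "{y}" in tmpl["text"]:
        values["years_smoked"] = rng.choice(_YEARS_POOL)
        fields["y"] = _fmt_num(values["years_smoked"])
    text = tmpl["text"].format(**fields)
    text = text[0].upper() + text[1:]
    if category == "complete":
        kind = "complete"
    elif category.startswith("computed"):
        kind = "computed"
        ppd = values.get("packs_per_day")
        if ppd is None:
            ppd = values["cigarettes_per_day"] / 20.0
        values["pack_years"] = round(ppd * values["years_smoked"], 1)
    else:
        kind = "partial"
    return text, values, kind


def generate(config: SynthConfig = SynthConfig()) -> Corpus:
    """Generate ``config.n_notes`` labelled synthetic notes."""
    rng = random.Random(config.seed)
    bank = load_templates(config.template_bank_version)
    statuses = list(SmokingStatus)

    notes: list[ClinicalNote] = []
    annotations: dict[str, GoldAnnotation] = {}
    patient_counter = 0
    prev_patient: str | None = None
    # formats and tier sub-categories cycle deterministically, so every
    # template class is exercised as soon as enough events occur
    n_determinable = n_partial = n_cessation = 0

    for i in range(config.n_notes):
        status = rng.choices(statuses, weights=config.status_mix, k=1)[0]
        categories: list[str] = [f"status:{status.value}"]
        b = _NoteBuilder()

        # patient and visit date: notes drawn from a single week; ~10% of
        # notes belong to the same patient as the previous one
        if prev_patient is not None and rng.random() < 0.10:
            patient_id = prev_patient
        else:
            patient_counter += 1
            patient_id = f"patient-{patient_counter:05d}"
        prev_patient = patient_id
        visit_date = _dt.date(2016, 3, 28) + _dt.timedelta(days=rng.randint(0, 7))

        b.line("VITALS:")
        b.line(
            f"BP {rng.randint(105, 150)}/{rng.randint(60, 95)}. "
            f"HR {rng.randint(55, 100)}. Temp {rng.choice(['97.9', '98.2', '98.6', '99.1'])}."
        )
        b.blank()
        b.line("SOCIAL HISTORY:")

        pack_values: dict[str, float] | None = None
        pack_kind: str | None = None
        pack_span: tuple[int, int] | None = None
        cess_date: _dt.date | None = None
        cess_precision: str | None = None
        cess_span: tuple[int, int] | None = None
        cess_vague = False
        meta: dict[str, object] = {}

        if status == SmokingStatus.UNKNOWN:
            if rng.random() < config.p_hotspot_unknown:
                b.line(rng.choice(bank["status_sentences"]["unknown_hotspot"]) + ".")
                categories.append("unknown:hotspot")
            else:
                b.line(rng.choice(bank["no_info_social"]) + ".")
                categories.append("unknown:no_hotspot")
        elif status == SmokingStatus.NEVER:
            b.line(rng.choice(bank["status_sentences"]["never"]) + ".")
        else:
            b.line(rng.choice(bank["status_sentences"][status.value]) + ".")
            u = rng.random()
            if u < config.p_pack_year_complete:
                category = _DETERMINABLE_CATEGORIES[n_determinable % 3]
                n_determinable += 1
            elif u < config.p_pack_year_complete + config.p_pack_year_partial:
                category = _PARTIAL_CATEGORIES[n_partial % 3]
                n_partial += 1
            else:
                category = None
            if category is not None:
                sentence, pack_values, pack_kind = _render_behavior(
                    category, rng, bank, status
                )
                pack_span = b.line(sentence + ".")
                categories.append(f"behavior:{category}")
            if status == SmokingStatus.FORMER and rng.random() < config.p_cessation_date:
                fmt = _CESSATION_FORMATS[n_cessation % len(_CESSATION_FORMATS)]
                n_cessation += 1
                sentence, cess_date, cess_precision = _render_cessation(fmt, rng, bank)
                span = b.line(sentence + ".")
                categories.append(f"cessation:{fmt}")
                if cess_date is None:
                    cess_vague = True
                else:
                    cess_span = span

        b.blank()
        b.line("HEALTH SUMMARY:")
        b.line(rng.choice(bank["fillers"]["health_summary"]) + ".")
        b.blank()
        b.line("IMPRESSIONS:")
        b.line(rng.choice(bank["fillers"]["impressions"]) + ".")
        if rng.random() < config.p_distractor:
            tmpl = rng.choice(bank["distractor_dates"])
            y, m, d = rng.randint(2010, 2016), rng.randint(1, 12), rng.randint(1, 28)
            b.line(
                tmpl.format(
                    mm=f"{m:02d}", dd=f"{d:02d}", yyyy=y, m=m, d=d,
                    yy=f"{y % 100:02d}", month=_MONTH_NAMES[m - 1],
                )
                + "."
            )
            categories.append("distractor:date")

        note_id = f"note-{i:05d}"
        note = ClinicalNote(
            note_id=note_id,
            text=b.text,
            visit_date=visit_date,
            patient_id=patient_id,
        )
        notes.append(note)

        meta["categories"] = categories
        if pack_span is not None:
            meta["pack_year_span"] = list(pack_span)
            meta["pack_year_kind"] = pack_kind
        if cess_span is not None:
            meta["cessation_span"] = list(cess_span)
        if cess_vague:
            meta["cessation_vague"] = True
        annotations[note_id] = GoldAnnotation(
            note_id=note_id,
            status=status,
            has_pack_year_info=pack_values is not None,
            pack_year_values=pack_values,
            cessation_date=cess_date,
            cessation_precision=cess_precision,
            metadata=meta,
        )

    return Corpus(notes=notes, annotations=annotations)


def template_coverage_report(config: SynthConfig = SynthConfig()) -> dict:
    """Counts of exercised template categories at the configured size.

    ``missing`` lists required categories (extraction tiers, date formats,
    distractors, both unknown paths) that the generated corpus does not
    exercise; ``covered`` is true when that list is empty.
    """
    corpus = generate(config)
    counts: dict[str, int] = {}
    for gold in corpus.annotations.values():
        for cat in gold.metadata.get("categories", []):
            counts[cat] = counts.get(cat, 0) + 1
    missing = sorted(REQUIRED_CATEGORIES - set(counts))
    return {"counts": dict(sorted(counts.items())), "missing": missing, "covered": not missing}
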