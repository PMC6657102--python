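"""Rule-based extraction of pack-year history and cessation dates.

Pack-year history in clinical notes is recorded in many shapes, so the
extractor evaluates rule tiers in a fixed order: complete pack-year
expressions first, then packs per day, cigarettes per day, and finally
years smoked.  A complete pack-year match short-circuits everything below
it.  When an intensity (packs/day or cigarettes/day) and a duration (years
smoked) are both present, the pack-year value is computed as
``packs_per_day x years_smoked`` with cigarettes converted at 20 per pack
(the standard US pack size) and rounded to one decimal.  Anything less is a
*partial* finding.

Cessation dates are only returned when a date expression is anchored to a
cessation cue ("quit", "stopped", ...) within the same sentence — this is
what keeps lab-panel and service dates out of the registry.  Vague decade
or range expressions ("quit in the late 1980s") are rejected by contract:
every returned date is unambiguous, at day, month, or year precision.

The patterns live in a versioned plain-text rule file shipped with the
package (``data/rules_v1.json``); they can be replaced without code
changes.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .hotspots import segment_sentences

#: cigarettes per pack used to convert cigarettes/day to packs/day
CIGARETTES_PER_PACK = 20.0

# numeric sub-pattern: digits with optional decimal, or a small bounded
# vocabulary of word numbers ("a pack a day" -> 1; "half a pack" -> 0.5)
_NUM = r"(?:\d+(?:\.\d+)?|one|two|three|four|five|six|seven|eight|nine|ten|half|an?)"

_WORD_NUMBERS = {
    "one": 1.0, "two": 2.0, "three": 3.0, "four": 4.0, "five": 5.0,
    "six": 6.0, "seven": 7.0, "eight": 8.0, "nine": 9.0, "ten": 10.0,
    "half": 0.5, "a": 1.0, "an": 1.0,
}

_TIER_ORDER = ("pack_years", "packs_per_day", "cigarettes_per_day", "years_smoked")


def parse_quantity(token: str) -> float:
    """Numeric value of a matched quantity token (digits or word form)."""
    token = token.strip().lower()
    if token in _WORD_NUMBERS:
        return _WORD_NUMBERS[token]
    return float(token)


@dataclass(frozen=True)
class RuleSet:
    """Ordered, versioned extraction patterns.

    ``tiers`` maps each quantity name to its compiled patterns, evaluated in
    order; ``cessation_cues`` are the compiled cue patterns that anchor a
    quit date.
    """

    version: str
    tiers: dict[str, tuple[re.Pattern, ...]]
    cessation_cues: tuple[re.Pattern, ...]

    def __post_init__(self) -> None:
        missing = [t for t in _TIER_ORDER if t not in self.tiers]
        if missing:
            raise ValueError(f"rule set missing tier(s): {missing}")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "RuleSet":
        """Load a rule file; the shipped version-1 rules by default."""
        if path is None:
            raw = resources.files("smokereg.data").joinpath("rules_v1.json").read_text("utf-8")
        else:
            raw = Path(path).read_text(encoding="utf-8")
        obj = json.loads(raw)
        tiers = {}
        for name, patterns in obj["tiers"].items():
            compiled = []
            for p in patterns:
                pat = re.compile(p.replace("{NUM}", _NUM), re.IGNORECASE)
                if "value" not in pat.groupindex:
                    raise ValueError(f"tier {name}: pattern lacks 'value' group: {p}")
                compiled.append(pat)
            tiers[name] = tuple(compiled)
        cues = tuple(re.compile(p, re.IGNORECASE) for p in obj["cessation_cues"])
        return cls(version=str(obj["version"]), tiers=tiers, cessation_cues=cues)


@dataclass(frozen=True)
class PackYearFinding:
    """A complete, computed, or partial consumption finding.

    ``kind`` is ``complete`` (pack years read directly from the text),
    ``computed`` (pack years derived from intensity x duration), or
    ``partial`` (some quantities found but pack years not determinable).
    Spans are 0-based half-open intervals into the source text.
    """

    kind: str
    source_span: tuple[int, int]
    source_text: str
    pack_years: Optional[float] = None
    packs_per_day: Optional[float] = None
    cigarettes_per_day: Optional[float] = None
    years_smoked: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("complete", "computed", "partial"):
            raise ValueError(f"bad finding kind: {self.kind!r}")
        if self.kind == "complete" and self.pack_years is None:
            raise ValueError("complete finding requires pack_years")
        if self.kind == "computed":
            if self.pack_years is None or self.years_smoked is None:
                raise ValueError("computed finding requires pack_years and years_smoked")
            if self.packs_per_day is None and self.cigarettes_per_day is None:
                raise ValueError("computed finding requires an intensity quantity")
        if self.kind == "partial":
            if self.pack_years is not None:
                raise ValueError("partial finding must not carry pack_years")
            if all(
                v is None
                for v in (self.packs_per_day, self.cigarettes_per_day, self.years_smoked)
            ):
                raise ValueError("partial finding requires at least one quantity")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "pack_years": self.pack_years,
            "packs_per_day": self.packs_per_day,
            "cigarettes_per_day": self.cigarettes_per_day,
            "years_smoked": self.years_smoked,
            "source_span": list(self.source_span),
            "source_text": self.source_text,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "PackYearFinding":
        return cls(
            kind=obj["kind"],
            pack_years=obj.get("pack_years"),
            packs_per_day=obj.get("packs_per_day"),
            cigarettes_per_day=obj.get("cigarettes_per_day"),
            years_smoked=obj.get("years_smoked"),
            source_span=tuple(obj["source_span"]),
            source_text=obj["source_text"],
        )


@dataclass(frozen=True)
class CessationFinding:
    """A normalized quit date.  YEAR/MONTH precision uses Jan-1 / day-1 placeholders."""

    date: _dt.date
    precision: str  # day | month | year
    source_span: tuple[int, int]
    source_text: str

    def __post_init__(self) -> None:
        if self.precision not in ("day", "month", "year"):
            raise ValueError(f"bad precision: {self.precision!r}")
        if self.precision == "year" and (self.date.month, self.date.day) != (1, 1):
            raise ValueError("year precision requires month/day placeholders of 1")
        if self.precision == "month" and self.date.day != 1:
            raise ValueError("month precision requires day placeholder of 1")

    def to_dict(self) -> dict:
        return {
            "date": self.date.isoformat(),
            "precision": self.precision,
            "source_span": list(self.source_span),
            "source_text": self.source_text,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "CessationFinding":
        return cls(
            date=_dt.date.fromisoformat(obj["date"]),
            precision=obj["precision"],
            source_span=tuple(obj["source_span"]),
            source_text=obj["source_text"],
        )


# ---------------------------------------------------------------------------
# pack years


def _first_match(text: str, patterns) -> Optional[re.Match]:
    """Earliest match in document order across an ordered pattern list."""
    best: Optional[re.Match] = None
    for pat in patterns:
        m = pat.search(text)
        if m and (best is None or m.start() < best.start()):
            best = m
    return best


def extract_pack_years(text: str, rules: RuleSet | None = None) -> Optional[PackYearFinding]:
    """Tiered pack-year extraction; see module docstring for the tier logic."""
    if rules is None:
        rules = RuleSet.load()

    m = _first_match(text, rules.tiers["pack_years"])
    if m is not None:
        # complete pack years found: no further tiers are evaluated
        return PackYearFinding(
            kind="complete",
            pack_years=parse_quantity(m.group("value")),
            source_span=(m.start(), m.end()),
            source_text=text[m.start() : m.end()],
        )

    ppd_m = _first_match(text, rules.tiers["packs_per_day"])
    cpd_m = None if ppd_m is not None else _first_match(text, rules.tiers["cigarettes_per_day"])
    yrs_m = _first_match(text, rules.tiers["years_smoked"])

    ppd = parse_quantity(ppd_m.group("value")) if ppd_m else None
    cpd = parse_quantity(cpd_m.group("value")) if cpd_m else None
    yrs = parse_quantity(yrs_m.group("value")) if yrs_m else None

    matches = [m for m in (ppd_m, cpd_m, yrs_m) if m is not None]
    if not matches:
        return None
    span = (min(m.start() for m in matches), max(m.end() for m in matches))

    intensity_ppd = ppd if ppd is not None else (cpd / CIGARETTES_PER_PACK if cpd is not None else None)
    if intensity_ppd is not None and yrs is not None:
        return PackYearFinding(
            kind="computed",
            pack_years=round(intensity_ppd * yrs, 1),
            packs_per_day=ppd,
            cigarettes_per_day=cpd,
            years_smoked=yrs,
            source_span=span,
            source_text=text[span[0] : span[1]],
        )
    return PackYearFinding(
        kind="partial",
        packs_per_day=ppd,
        cigarettes_per_day=cpd,
        years_smoked=yrs,
        source_span=span,
        source_text=text[span[0] : span[1]],
    )


# ---------------------------------------------------------------------------
# dates

_MONTHS = {
    "jan": 1, "january": 1, "feb": 2, "february": 2, "mar": 3, "march": 3,
    "apr": 4, "april": 4, "may": 5, "jun": 6, "june": 6, "jul": 7, "july": 7,
    "aug": 8, "august": 8, "sep": 9, "sept": 9, "september": 9,
    "oct": 10, "october": 10, "nov": 11, "november": 11, "dec": 12, "december": 12,
}
_MONTH_ALT = "|".join(sorted(_MONTHS, key=len, reverse=True))

# full-expression date forms for normalize_date (anchored with fullmatch)
_RE_SLASH = re.compile(r"(\d{1,2})/(\d{1,2})/(\d{2}|\d{4})")
_RE_MONTH_DAY_YEAR = re.compile(
    rf"(?P<mon>{_MONTH_ALT})\.?\s+(?P<day>\d{{1,2}})(?:st|nd|rd|th)?,?\s+(?P<year>\d{{4}})",
    re.IGNORECASE,
)
_RE_MONTH_YEAR = re.compile(
    rf"(?P<mon>{_MONTH_ALT})\.?,?\s+(?P<year>\d{{4}})", re.IGNORECASE
)
_RE_NUM_MONTH_YEAR = re.compile(r"(\d{1,2})/(\d{4})")
_RE_YEAR = re.compile(r"(19|20)\d{2}")
_RE_APOS_YY = re.compile(r"[’']?(\d{2})")
_RE_DECADE = re.compile(r"(?:the\s+)?(?:early|mid|late)?\s*(?:(?:19|20)\d0|[’']?\d0)s\b", re.IGNORECASE)
_RE_RANGE = re.compile(r"(?:19|20)\d{2}\s*(?:-|–|to)\s*(?:19|20)\d{2}", re.IGNORECASE)


def _pivot_year(two_digit: int) -> int:
    """Two-digit year pivot: 00-29 resolve to the 2000s, 30-99 to the 1900s."""
    return 2000 + two_digit if two_digit <= 29 else 1900 + two_digit


def normalize_date(expression: str) -> Optional[tuple[_dt.date, str]]:
    """Parse a date expression to ``(date, precision)``; ``None`` on failure.

    Accepts ``MM/DD/YYYY``, ``M/D/YY``, ``Month DD, YYYY``, ``Month YYYY``,
    ``MM/YYYY``, bare ``YYYY``, and two-digit years (``'95`` / ``95``,
    pivoted at 29).  Decades, seasons, and ranges fail by contract.
    """
    expr = expression.strip()
    expr = re.sub(r"^(?:in|on|since)\s+", "", expr, flags=re.IGNORECASE).strip()
    if _RE_DECADE.fullmatch(expr) or _RE_RANGE.fullmatch(expr):
        return None

    m = _RE_SLASH.fullmatch(expr)
    if m:
        mon, day, year = int(m.group(1)), int(m.group(2)), m.group(3)
        y = _pivot_year(int(year)) if len(year) == 2 else int(year)
        try:
            return _dt.date(y, mon, day), "day"
        except ValueError:
            return None
    m = _RE_MONTH_DAY_YEAR.fullmatch(expr)
    if m:
        try:
            return (
                _dt.date(int(m.group("year")), _MONTHS[m.group("mon").lower()], int(m.group("day"))),
                "day",
            )
        except ValueError:
            return None
    m = _RE_MONTH_YEAR.fullmatch(expr)
    if m:
        return _dt.date(int(m.group("year")), _MONTHS[m.group("mon").lower()], 1), "month"
    m = _RE_NUM_MONTH_YEAR.fullmatch(expr)
    if m:
        mon = int(m.group(1))
        if 1 <= mon <= 12:
            return _dt.date(int(m.group(2)), mon, 1), "month"
        return None
    m = _RE_YEAR.fullmatch(expr)
    if m:
        return _dt.date(int(m.group()), 1, 1), "year"
    m = _RE_APOS_YY.fullmatch(expr)
    if m:
        return _dt.date(_pivot_year(int(m.group(1))), 1, 1), "year"
    return None


def render_date(date: _dt.date, precision: str) -> str:
    """Render a normalized date so it re-parses to the same value."""
    if precision == "day":
        return f"{date.month:02d}/{date.day:02d}/{date.year:04d}"
    if precision == "month":
        names = [
            "January", "February", "March", "April", "May", "June", "July",
            "August", "September", "October", "November", "December",
        ]
        return f"{names[date.month - 1]} {date.year:04d}"
    if precision == "year":
        return f"{date.year:04d}"
    raise ValueError(f"bad precision: {precision!r}")


# date *candidates* inside running text, in priority order (most specific
# first); 'reject' kinds mark expressions that must never yield a date
_CANDIDATE_PATTERNS: tuple[tuple[str, re.Pattern], ...] = (
    ("decade", re.compile(r"\b(?:19|20)\d0s\b|[’']\d0s\b", re.IGNORECASE)),
    ("range", re.compile(r"\b(?:19|20)\d{2}\s*(?:-|–|to)\s*(?:19|20)\d{2}\b", re.IGNORECASE)),
    ("slash", re.compile(r"\b\d{1,2}/\d{1,2}/(?:\d{4}|\d{2})\b")),
    ("month_day_year", _RE_MONTH_DAY_YEAR),
    ("month_year", _RE_MONTH_YEAR),
    ("num_month_year", re.compile(r"\b\d{1,2}/\d{4}\b")),
    ("year", re.compile(r"(?<![-–/\d])\b(?:19|20)\d{2}\b(?!s)(?!\s*(?:-|–|to)\s*(?:19|20)\d{2})")),
    ("apos_yy", re.compile(r"[’'](\d{2})\b(?!\s*(?:years?|yrs?))")),
    ("in_yy", re.compile(r"\bin\s+(\d{2})\b(?![\d/])(?!\s*(?:years?|yrs?))", re.IGNORECASE)),
)

_REJECT_KINDS = {"decade", "range"}


def _date_candidates(text: str) -> list[tuple[int, int, str, str]]:
    """All date-like spans in ``text``: (start, end, kind, expression).

    Overlapping candidates keep only the highest-priority (earliest listed)
    pattern; results are sorted by position.
    """
    found: list[tuple[int, int, str, str]] = []
    taken: list[tuple[int, int]] = []
    for kind, pat in _CANDIDATE_PATTERNS:
        for m in pat.finditer(text):
            lo, hi = m.start(), m.end()
            if any(not (hi <= t_lo or lo >= t_hi) for t_lo, t_hi in taken):
                continue
            if kind in ("apos_yy", "in_yy"):
                expr = m.group(1)
                lo = m.start(1)
            else:
                expr = m.group()
            found.append((lo, hi, kind, expr))
            taken.append((lo, hi))
    found.sort(key=lambda c: c[0])
    return found


def extract_cessation_date(
    text: str,
    rules: RuleSet | None = None,
    note_date: _dt.date | None = None,
) -> Optional[CessationFinding]:
    """First cessation date anchored to a quit cue within one sentence.

    A date with no cessation cue in its sentence is never returned; a cue
    whose only date expressions are vague (decades, ranges) yields nothing.
    ``note_date`` is accepted for interface symmetry (relative expressions
    such as "quit 10 years ago" are out of contract and never resolved).
    """
    if rules is None:
        rules = RuleSet.load()
    for sent in segment_sentences(text):
        cue = None
        for pat in rules.cessation_cues:
            m = pat.search(sent.text)
            if m and (cue is None or m.start() < cue.start()):
                cue = m
        if cue is None:
            continue
        candidates = _date_candidates(sent.text)
        if not candidates:
            continue
        # prefer the first candidate at/after the cue, else the first at all
        after = [c for c in candidates if c[0] >= cue.end()]
        ordered = after + [c for c in candidates if c not in after]
        for lo, hi, kind, expr in ordered:
            if kind in _REJECT_KINDS:
                continue
            if kind == "apos_yy" or kind == "in_yy":
                parsed = (
                    (_dt.date(_pivot_year(int(expr)), 1, 1), "year")
                    if expr.isdigit()
                    else None
                )
            else:
                parsed = normalize_date(expr)
            if parsed is not None:
                date, precision = parsed
                abs_lo, abs_hi = sent.span[0] + lo, sent.span[0] + hi
                return CessationFinding(
                    date=date,
                    precision=precision,
                    source_span=(abs_lo, abs_hi),
                    source_text=text[abs_lo:abs_hi],
                )
    return None
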