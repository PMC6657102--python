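"""Hotspot detection and bounded context-window extraction.

A *hotspot* is a word stem (e.g. ``smok``) whose occurrence marks text
likely to describe tobacco use.  Classification never sees a whole note:
only a bounded window of context around each hotspot, with all windows of a
note appended together.  Notes without any hotspot are handled upstream by
a rule (labelled *unknown* without classification).

Stem matching is substring-anywhere, so inflections and compounds
("smoking", "nonsmoker", "cigarette") all hit.  Windows in *words* mode
never cross a sentence boundary; *chars* mode is a plain character clamp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .corpus import ClinicalNote

#: reserved marker placed between appended windows; never enters the
#: feature vocabulary (see classifier.FeatureSpace)
BOUNDARY_TOKEN = "xxwindowboundaryxx"

#: the four stems of the best-performing configuration
DEFAULT_STEMS = ("smok", "cig", "tobac", "nicoti")
#: the original six-stem set of the character-window baseline
LEGACY_STEMS = ("smok", "cig", "tobac", "packs", "tob", "nicotine")


@dataclass(frozen=True)
class HotspotConfig:
    """Hotspot stems plus window geometry.

    ``mode`` is ``"words"`` (± ``window_size`` word tokens, truncated at
    sentence boundaries; the hotspot token itself is the centre and does
    not count toward the size) or ``"chars"`` (± ``window_size``
    characters, no sentence constraint).
    """

    stems: tuple[str, ...] = DEFAULT_STEMS
    mode: str = "words"
    window_size: int = 5

    def __post_init__(self) -> None:
        if not self.stems:
            raise ValueError("stems must be non-empty")
        if any(s != s.lower() or not s for s in self.stems):
            raise ValueError("stems must be non-empty lowercase strings")
        if self.mode not in ("words", "chars"):
            raise ValueError(f"mode must be 'words' or 'chars', got {self.mode!r}")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")

    @classmethod
    def legacy(cls) -> "HotspotConfig":
        """Six stems, ±100 characters: the original baseline geometry."""
        return cls(stems=LEGACY_STEMS, mode="chars", window_size=100)


@dataclass(frozen=True)
class Sentence:
    text: str
    span: tuple[int, int]  # 0-based half-open, in note coordinates


@dataclass(frozen=True)
class HotspotMatch:
    stem: str
    span: tuple[int, int]  # 0-based half-open character interval


@dataclass(frozen=True)
class HotspotWindow:
    note_id: str
    stem: str
    match_span: tuple[int, int]
    window_text: str
    window_span: tuple[int, int]
    sentence_index: int

    def __post_init__(self) -> None:
        if not self.window_text:
            raise ValueError("window_text must be non-empty")


_SENTENCE_DELIM = re.compile(r"[.!?\n]+")
_TOKEN = re.compile(r"[0-9a-z]+")


def segment_sentences(text: str) -> list[Sentence]:
    """Deterministic segmentation on terminal punctuation and newlines.

    Section-header lines (e.g. ``SOCIAL HISTORY:``) end at their newline and
    therefore always form their own sentence.  Returns sentences with
    0-based half-open spans; spans are disjoint and ordered.
    """
    sentences: list[Sentence] = []
    pos = 0
    for m in list(_SENTENCE_DELIM.finditer(text)) + [None]:
        end = m.start() if m is not None else len(text)
        raw = text[pos:end]
        stripped = raw.strip()
        if stripped:
            start = pos + (len(raw) - len(raw.lstrip()))
            sentences.append(Sentence(text=stripped, span=(start, start + len(stripped))))
        pos = m.end() if m is not None else end
    return sentences


def tokenize(text: str) -> list[str]:
    """Lowercase tokens: maximal runs of alphanumeric characters."""
    return _TOKEN.findall(text.lower())


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """As :func:`tokenize` but with 0-based half-open source spans."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(text.lower())]


def find_hotspots(note: ClinicalNote, config: HotspotConfig = HotspotConfig()) -> list[HotspotMatch]:
    """All stem occurrences in the note, case-insensitive, ordered by position."""
    lowered = note.text.lower()
    matches: list[HotspotMatch] = []
    for stem in config.stems:
        start = 0
        while True:
            i = lowered.find(stem, start)
            if i < 0:
                break
            matches.append(HotspotMatch(stem=stem, span=(i, i + len(stem))))
            start = i + 1
    matches.sort(key=lambda m: (m.span[0], m.span[1], m.stem))
    return matches


def _sentence_index_of(sentences: list[Sentence], pos: int) -> int:
    for i, s in enumerate(sentences):
        if s.span[0] <= pos < s.span[1]:
            return i
    # position falls in delimiter text; attribute to the nearest following
    # sentence, else the last one
    for i, s in enumerate(sentences):
        if s.span[0] > pos:
            return i
    return len(sentences) - 1


def extract_window(
    note: ClinicalNote, match: HotspotMatch, config: HotspotConfig = HotspotConfig()
) -> HotspotWindow:
    """Bounded context window around one hotspot match."""
    text = note.text
    lo, hi = match.span
    if not (0 <= lo < hi <= len(text)):
        raise ValueError(f"match span {match.span} outside note text (len {len(text)})")

    if config.mode == "chars":
        w_lo = max(0, lo - config.window_size)
        w_hi = min(len(text), hi + config.window_size)
        sentences = segment_sentences(text)
        sent_idx = _sentence_index_of(sentences, lo) if sentences else 0
        return HotspotWindow(
            note_id=note.note_id,
            stem=match.stem,
            match_span=match.span,
            window_text=text[w_lo:w_hi],
            window_span=(w_lo, w_hi),
            sentence_index=sent_idx,
        )

    # words mode: ±k tokens around the token containing the match, within
    # the enclosing sentence
    sentences = segment_sentences(text)
    sent_idx = _sentence_index_of(sentences, lo)
    sent = sentences[sent_idx]
    s_lo = sent.span[0]
    toks = tokenize_with_spans(sent.text)  # spans relative to sentence
    centre = None
    for i, (_, t_lo, t_hi) in enumerate(toks):
        if t_lo <= lo - s_lo < t_hi:
            centre = i
            break
    if centre is None:
        # match in punctuation (cannot happen for alphanumeric stems); fall
        # back to the whole sentence
        first, last = 0, len(toks) - 1
    else:
        first = max(0, centre - config.window_size)
        last = min(len(toks) - 1, centre + config.window_size)
    w_lo = s_lo + toks[first][1]
    w_hi = s_lo + toks[last][2]
    return HotspotWindow(
        note_id=note.note_id,
        stem=match.stem,
        match_span=match.span,
        window_text=text[w_lo:w_hi],
        window_span=(w_lo, w_hi),
        sentence_index=sent_idx,
    )


def extract_windows(
    note: ClinicalNote, config: HotspotConfig = HotspotConfig()
) -> list[HotspotWindow]:
    """One window per hotspot occurrence, in document order."""
    return [extract_window(note, m, config) for m in find_hotspots(note, config)]


def note_window_text(
    note: ClinicalNote, config: HotspotConfig = HotspotConfig()
) -> Optional[str]:
    """All hotspot windows of the note appended in document order.

    Windows are separated by :data:`BOUNDARY_TOKEN`; overlapping windows are
    emitted independently (duplicated text allowed).  Returns ``None`` when
    the note contains no hotspot — such notes bypass the classifier and are
    labelled *unknown* by rule.
    """
    windows = extract_windows(note, config)
    if not windows:
        return None
    return f" {BOUNDARY_TOKEN} ".join(w.window_text for w in windows)
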