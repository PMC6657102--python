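"""Domain types and corpus I/O for clinical notes, gold annotations, and predictions.

The native interchange format is JSON-lines (one UTF-8 JSON object per
line).  A note record carries ``note_id``, ``text``, and optionally
``patient_id``, ``visit_date`` (ISO ``YYYY-MM-DD``) and a ``gold`` object
with the manual annotation.  Unrecognised fields are preserved in a
``metadata`` bag so round-trips are lossless.

A reader for the 2006 i2b2 smoking-challenge XML record format
(``ROOT/RECORD/SMOKING+TEXT``) is provided for users who hold that
restricted-access corpus; nothing in the package requires it.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class SmokingStatus(enum.Enum):
    """Five-way smoking status.

    ``SMOKER`` means a smoking history is documented but current-vs-former
    temporality is unknown; ``UNKNOWN`` means the note carries no smoking
    status information at all.  The declaration order is the canonical
    deterministic tie-break order used throughout the package.
    """

    NEVER = "never"
    FORMER = "former"
    CURRENT = "current"
    SMOKER = "smoker"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "SmokingStatus":
        """Parse one of the five class strings, case-insensitively."""
        try:
            return cls(value.strip().lower())
        except ValueError:
            raise ValueError(
                f"not a smoking status: {value!r} "
                f"(expected one of {[m.value for m in cls]})"
            ) from None


#: canonical class order (tie-break order for the classifier)
STATUS_ORDER: tuple[SmokingStatus, ...] = tuple(SmokingStatus)

#: statuses that establish a positive smoking history and gate extraction
SMOKER_STATUSES: frozenset[SmokingStatus] = frozenset(
    {SmokingStatus.FORMER, SmokingStatus.CURRENT, SmokingStatus.SMOKER}
)

# i2b2 2006 smoking-challenge label strings -> package statuses.
# The challenge labels the former-smoker class "past smoker".
_I2B2_STATUS_MAP = {
    "NON-SMOKER": SmokingStatus.NEVER,
    "NEVER SMOKER": SmokingStatus.NEVER,
    "PAST SMOKER": SmokingStatus.FORMER,
    "PAST": SmokingStatus.FORMER,
    "FORMER SMOKER": SmokingStatus.FORMER,
    "CURRENT SMOKER": SmokingStatus.CURRENT,
    "SMOKER": SmokingStatus.SMOKER,
    "UNKNOWN": SmokingStatus.UNKNOWN,
}


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text clinical note."""

    note_id: str
    text: str
    visit_date: _dt.date | None = None
    patient_id: str | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be non-empty")
        if not self.text.strip():
            raise ValueError(f"note {self.note_id!r}: text empty after stripping")


@dataclass(frozen=True)
class GoldAnnotation:
    """Manual note-level annotation: status plus behavior truth.

    ``pack_year_values`` is a numeric bundle over the quantity names
    ``pack_years``, ``packs_per_day``, ``cigarettes_per_day``,
    ``years_smoked`` (any subset).  ``cessation_date`` is the quit date with
    its precision (``day``/``month``/``year``).
    """

    note_id: str
    status: SmokingStatus
    has_pack_year_info: bool = False
    pack_year_values: Mapping[str, float] | None = None
    cessation_date: _dt.date | None = None
    cessation_precision: str | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status in (SmokingStatus.NEVER, SmokingStatus.UNKNOWN):
            if self.has_pack_year_info or self.cessation_date is not None:
                raise ValueError(
                    f"note {self.note_id!r}: {self.status.value} status cannot "
                    "carry pack-year or cessation annotations"
                )


@dataclass
class Corpus:
    """A set of notes plus a (possibly partial) gold-annotation map."""

    notes: list[ClinicalNote]
    annotations: dict[str, GoldAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.note_id for n in self.notes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate note_id(s): {dup}")
        missing = set(self.annotations) - set(ids)
        if missing:
            raise ValueError(f"annotations for unknown note_id(s): {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.notes)

    def __iter__(self):
        return iter(self.notes)

    def get_note(self, note_id: str) -> ClinicalNote:
        for n in self.notes:
            if n.note_id == note_id:
                return n
        raise KeyError(note_id)


# ---------------------------------------------------------------------------
# JSONL serialisation

_NOTE_FIELDS = {"note_id", "text", "visit_date", "patient_id", "gold"}


def _parse_date(value: str | None, where: str) -> _dt.date | None:
    if value is None:
        return None
    try:
        return _dt.date.fromisoformat(value)
    except ValueError:
        raise ValueError(f"{where}: bad ISO date {value!r}") from None


def _gold_from_dict(note_id: str, obj: Mapping[str, object]) -> GoldAnnotation:
    known = {
        "status",
        "has_pack_year_info",
        "pack_year_values",
        "cessation_date",
        "cessation_precision",
    }
    meta = {k: v for k, v in obj.items() if k not in known}
    return GoldAnnotation(
        note_id=note_id,
        status=SmokingStatus.parse(str(obj["status"])),
        has_pack_year_info=bool(obj.get("has_pack_year_info", False)),
        pack_year_values=dict(obj["pack_year_values"])  # type: ignore[arg-type]
        if obj.get("pack_year_values")
        else None,
        cessation_date=_parse_date(obj.get("cessation_date"), f"note {note_id}"),  # type: ignore[arg-type]
        cessation_precision=obj.get("cessation_precision"),  # type: ignore[arg-type]
        metadata=meta,
    )


def _gold_to_dict(g: GoldAnnotation) -> dict:
    out: dict = {"status": g.status.value, "has_pack_year_info": g.has_pack_year_info}
    if g.pack_year_values is not None:
        out["pack_year_values"] = dict(g.pack_year_values)
    if g.cessation_date is not None:
        out["cessation_date"] = g.cessation_date.isoformat()
        out["cessation_precision"] = g.cessation_precision
    out.update(g.metadata)
    return out


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus from ``path`` in the named dialect (``jsonl`` or ``i2b2_xml``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "i2b2_xml":
        return _read_i2b2_xml(path)
    raise ValueError(f"unknown corpus format: {format!r}")


def _read_jsonl(path: Path) -> Corpus:
    notes: list[ClinicalNote] = []
    annotations: dict[str, GoldAnnotation] = {}
    with path.open(encoding="utf-8") as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"record {idx}: invalid JSON ({exc})") from None
            for required in ("note_id", "text"):
                if required not in obj:
                    raise ValueError(f"record {idx}: missing field {required!r}")
            meta = {k: v for k, v in obj.items() if k not in _NOTE_FIELDS}
            try:
                note = ClinicalNote(
                    note_id=str(obj["note_id"]),
                    text=obj["text"],
                    visit_date=_parse_date(obj.get("visit_date"), f"record {idx}"),
                    patient_id=obj.get("patient_id"),
                    metadata=meta,
                )
            except ValueError as exc:
                raise ValueError(f"record {idx}: {exc}") from None
            notes.append(note)
            if obj.get("gold"):
                annotations[note.note_id] = _gold_from_dict(note.note_id, obj["gold"])
    return Corpus(notes=notes, annotations=annotations)


def _read_i2b2_xml(path: Path) -> Corpus:
    from lxml import etree

    tree = etree.parse(str(path))
    notes: list[ClinicalNote] = []
    annotations: dict[str, GoldAnnotation] = {}
    for idx, record in enumerate(tree.findall(".//RECORD")):
        note_id = record.get("ID")
        if note_id is None:
            raise ValueError(f"record {idx}: RECORD element lacks ID attribute")
        smoking = record.find("SMOKING")
        text_el = record.find("TEXT")
        if text_el is None or not (text_el.text or "").strip():
            raise ValueError(f"record {idx} (ID={note_id}): empty or missing TEXT")
        notes.append(ClinicalNote(note_id=note_id, text=text_el.text))
        if smoking is not None:
            raw = (smoking.get("STATUS") or "").strip().upper()
            status = _I2B2_STATUS_MAP.get(raw)
            if status is None:
                raise ValueError(
                    f"record {idx} (ID={note_id}): unknown i2b2 status {raw!r}"
                )
            annotations[note_id] = GoldAnnotation(note_id=note_id, status=status)
    return Corpus(notes=notes, annotations=annotations)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus to JSONL, one object per note, gold inline."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for note in corpus.notes:
            obj: dict = {"note_id": note.note_id, "text": note.text}
            if note.visit_date is not None:
                obj["visit_date"] = note.visit_date.isoformat()
            if note.patient_id is not None:
                obj["patient_id"] = note.patient_id
            obj.update(note.metadata)
            gold = corpus.annotations.get(note.note_id)
            if gold is not None:
                obj["gold"] = _gold_to_dict(gold)
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def write_predictions(corpus: Corpus, predictions: Iterable, path: str | Path) -> None:
    """Write prediction records (with any findings) to JSONL.

    Each prediction must reference a note in ``corpus``.  The output is
    round-trippable by :func:`read_predictions`.
    """
    path = Path(path)
    known = {n.note_id for n in corpus.notes}
    preds = list(predictions)
    for p in preds:
        if p.note_id not in known:
            raise ValueError(f"prediction for unknown note_id {p.note_id!r}")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# smokereg predictions v1\n")
        for p in preds:
            fh.write(json.dumps(p.to_dict(), ensure_ascii=False) + "\n")


def read_predictions(path: str | Path) -> list:
    """Read back a predictions JSONL file written by :func:`write_predictions`."""
    from .classifier import StatusPrediction

    path = Path(path)
    out = []
    with path.open(encoding="utf-8") as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"record {idx}: invalid JSON ({exc})") from None
            out.append(StatusPrediction.from_dict(obj))
    return out
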