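"""The end-to-end pipeline: classify every note, gate behavior extraction on
smoker statuses, and assemble the registry tables.

Extraction is *only* applied to notes classified former / current /
temporality-unknown smoker.  Notes classified never-smoker or unknown are
never touched by the extraction rules — this gating is what keeps blood
panels and service dates in non-smoker notes from producing false pack-year
or quit-date findings.

The registry is delivered as two tables derived row-for-row from the same
records: a de-identified *population* table (no patient identifiers, usable
for population assessment) and an identified *contact* table (patient ids
retained, for clinical follow-up under appropriate governance).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import extraction as _extraction
from .classifier import StatusModel, StatusPrediction, predict
from .corpus import SMOKER_STATUSES, ClinicalNote, Corpus, SmokingStatus
from .extraction import CessationFinding, PackYearFinding, RuleSet


@dataclass(frozen=True)
class RegistryRecord:
    """One smoker-classified note's contribution to the registry."""

    patient_id: Optional[str]
    note_id: str
    status: SmokingStatus
    pack_year_finding: Optional[PackYearFinding] = None
    cessation_finding: Optional[CessationFinding] = None
    note_date: Optional[_dt.date] = None
    provenance: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.status not in SMOKER_STATUSES:
            raise ValueError(
                f"registry records require a smoker status, got {self.status.value!r}"
            )


@dataclass
class RegistryTables:
    """De-identified population table + identified contact table."""

    population_table: pd.DataFrame
    contact_table: pd.DataFrame

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pop = out_dir / "population_table.csv"
        contact = out_dir / "contact_table.csv"
        self.population_table.to_csv(pop, index=False)
        self.contact_table.to_csv(contact, index=False)
        return pop, contact


def run_pipeline(
    corpus: Corpus,
    model: StatusModel,
    rules: RuleSet | None = None,
) -> tuple[list[StatusPrediction], list[RegistryRecord]]:
    """Classify every note; extract behaviors from smoker-classified notes only.

    Returns one prediction per note (with findings attached where
    extraction ran) and one :class:`RegistryRecord` per smoker-classified
    note.
    """
    if rules is None:
        rules = RuleSet.load()
    predictions: list[StatusPrediction] = []
    records: list[RegistryRecord] = []
    for note in corpus.notes:
        pred = predict(model, note)
        if pred.status in SMOKER_STATUSES:
            # extraction is reachable only from this branch (the gate)
            pack = _extraction.extract_pack_years(note.text, rules)
            cess = _extraction.extract_cessation_date(
                note.text, rules, note_date=note.visit_date
            )
            pred = pred.with_findings(pack_year_finding=pack, cessation_finding=cess)
            provenance = tuple(
                f.source_span for f in (pack, cess) if f is not None
            )
            records.append(
                RegistryRecord(
                    patient_id=note.patient_id,
                    note_id=note.note_id,
                    status=pred.status,
                    pack_year_finding=pack,
                    cessation_finding=cess,
                    note_date=note.visit_date,
                    provenance=provenance,
                )
            )
        predictions.append(pred)
    return predictions, records


_POPULATION_COLUMNS = [
    "status", "pack_year_kind", "pack_years", "packs_per_day",
    "cigarettes_per_day", "years_smoked", "cessation_date",
    "cessation_precision", "note_date",
]


def _record_fields(rec: RegistryRecord) -> dict:
    pack = rec.pack_year_finding
    cess = rec.cessation_finding
    return {
        "status": rec.status.value,
        "pack_year_kind": pack.kind if pack else None,
        "pack_years": pack.pack_years if pack else None,
        "packs_per_day": pack.packs_per_day if pack else None,
        "cigarettes_per_day": pack.cigarettes_per_day if pack else None,
        "years_smoked": pack.years_smoked if pack else None,
        "cessation_date": cess.date.isoformat() if cess else None,
        "cessation_precision": cess.precision if cess else None,
        "note_date": rec.note_date.isoformat() if rec.note_date else None,
    }


def build_registry_tables(records: list[RegistryRecord]) -> RegistryTables:
    """Assemble the two registry tables; empty input gives header-only tables."""
    pop_rows = [_record_fields(r) for r in records]
    contact_rows = [
        {"patient_id": r.patient_id, "note_id": r.note_id, **_record_fields(r)}
        for r in records
    ]
    population = pd.DataFrame(pop_rows, columns=_POPULATION_COLUMNS)
    contact = pd.DataFrame(
        contact_rows, columns=["patient_id", "note_id"] + _POPULATION_COLUMNS
    )
    return RegistryTables(population_table=population, contact_table=contact)


def aggregate_patients(records: list[RegistryRecord]) -> pd.DataFrame:
    """Patient-level registry rows from note-level records.

    A registry is patient-wise while the pipeline is note-wise: when a
    patient has several smoker-classified notes, the most recent note's
    status is kept (ties broken by note id) and the maximum pack-year value
    across notes is retained, along with the most recent cessation finding.
    """
    by_patient: dict[str, list[RegistryRecord]] = {}
    for rec in records:
        key = rec.patient_id if rec.patient_id is not None else f"(note {rec.note_id})"
        by_patient.setdefault(key, []).append(rec)
    rows = []
    for patient_id in sorted(by_patient):
        recs = sorted(
            by_patient[patient_id],
            key=lambda r: (r.note_date or _dt.date.min, r.note_id),
        )
        latest = recs[-1]
        pack_years = [
            r.pack_year_finding.pack_years
            for r in recs
            if r.pack_year_finding and r.pack_year_finding.pack_years is not None
        ]
        cess = [r.cessation_finding for r in recs if r.cessation_finding]
        rows.append(
            {
                "patient_id": patient_id,
                "status": latest.status.value,
                "n_notes": len(recs),
                "pack_years": max(pack_years) if pack_years else None,
                "cessation_date": cess[-1].date.isoformat() if cess else None,
                "cessation_precision": cess[-1].precision if cess else None,
                "latest_note_date": latest.note_date.isoformat()
                if latest.note_date
                else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "status", "n_notes", "pack_years",
            "cessation_date", "cessation_precision", "latest_note_date",
        ],
    )
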