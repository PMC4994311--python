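"""Canonical EMR event model with temporal-window retrieval.

The store holds five entity types — patients, encounters, prescriptions,
in-facility medication administrations and toxicology screens — indexed by
patient and time. All timestamps are timezone-aware and normalized to UTC;
a "day" is exactly 86,400 seconds, and every windowed query uses the
half-open convention ``[t_start, t_end)`` so that events at the evaluation
instant are excluded from any "previous N days" lookback.

File formats: a JSONL event log (one object per line, discriminated by a
``kind`` field) and a directory of per-entity CSV files. Unknown enum values
are rejected rather than coerced, so surveillance denominators can never be
silently corrupted by malformed input.
"""

from __future__ import annotations

import csv
import json
from bisect import bisect_left
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date, datetime, timedelta, timezone
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Union

SECONDS_PER_DAY = 86_400

__all__ = [
    "SECONDS_PER_DAY",
    "FacilityType",
    "Disposition",
    "DrugClass",
    "Analyte",
    "EventKind",
    "LogFormat",
    "Patient",
    "Encounter",
    "Prescription",
    "MedicationAdministration",
    "ToxScreen",
    "EventStore",
    "EventLogError",
    "ValidationError",
    "parse_timestamp",
    "format_timestamp",
    "days_between",
    "load_event_log",
    "write_event_log",
    "query_window",
]


class EventLogError(ValueError):
    """Malformed record in an event-log file (names the line/row and field)."""


class ValidationError(ValueError):
    """Cross-reference or invariant violation in an assembled store."""


class FacilityType(str, Enum):
    ED = "ED"
    URGENT_CARE = "URGENT_CARE"
    INPATIENT = "INPATIENT"
    OUTPATIENT = "OUTPATIENT"
    PHONE = "PHONE"
    OTHER = "OTHER"


class Disposition(str, Enum):
    DISCHARGED = "DISCHARGED"
    ADMITTED = "ADMITTED"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class DrugClass(str, Enum):
    OPIOID = "OPIOID"
    BENZODIAZEPINE = "BENZODIAZEPINE"
    OTHER = "OTHER"  # permitted for administrations only, never prescriptions


class Analyte(str, Enum):
    BLOOD_ALCOHOL = "BLOOD_ALCOHOL"
    COCAINE = "COCAINE"
    MARIJUANA = "MARIJUANA"


class EventKind(str, Enum):
    PATIENT = "patient"
    ENCOUNTER = "encounter"
    PRESCRIPTION = "prescription"
    MED_ADMIN = "med_admin"
    TOX_SCREEN = "tox_screen"


class LogFormat(str, Enum):
    JSONL = "JSONL"
    CSV_DIR = "CSV_DIR"


# ---------------------------------------------------------------------------
# time handling


def parse_timestamp(value: str) -> datetime:
    """Parse an ISO-8601 timestamp and normalize it to UTC.

    Naive timestamps are interpreted as UTC.
    """
    dt = datetime.fromisoformat(value)
    if dt.tzinfo is None:
        return dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def format_timestamp(dt: datetime) -> str:
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc).isoformat().replace("+00:00", "Z")


def parse_date(value: str) -> date:
    return date.fromisoformat(value)


def days_between(earlier: datetime, later: datetime) -> float:
    """Elapsed time from ``earlier`` to ``later`` in 86,400-second days."""
    return (later - earlier).total_seconds() / SECONDS_PER_DAY


# ---------------------------------------------------------------------------
# entities


@dataclass(frozen=True)
class Patient:
    patient_id: str
    date_of_birth: date


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    patient_id: str
    start_at: datetime
    facility_type: FacilityType
    disposition: Disposition
    is_overdose_presentation: bool = False


@dataclass(frozen=True)
class Prescription:
    rx_id: str
    patient_id: str
    encounter_id: str
    written_at: datetime
    drug_class: DrugClass
    duration_days: Optional[float]  # days of supply; None flagged as warning
    prescriber_id: str
    drug_name: Optional[str] = None


@dataclass(frozen=True)
class MedicationAdministration:
    patient_id: str
    encounter_id: str
    administered_at: datetime
    drug_class: DrugClass


@dataclass(frozen=True)
class ToxScreen:
    patient_id: str
    collected_at: datetime
    analyte: Analyte
    positive: bool


Event = Union[Encounter, Prescription, MedicationAdministration, ToxScreen]

_TIME_ATTR = {
    EventKind.ENCOUNTER: "start_at",
    EventKind.PRESCRIPTION: "written_at",
    EventKind.MED_ADMIN: "administered_at",
    EventKind.TOX_SCREEN: "collected_at",
}


def event_time(kind: EventKind, event: Event) -> datetime:
    return getattr(event, _TIME_ATTR[kind])


# ---------------------------------------------------------------------------
# store


@dataclass
class EventStore:
    """Validated, patient/time-indexed collection of EMR events."""

    patients: dict[str, Patient] = field(default_factory=dict)
    encounters: dict[str, Encounter] = field(default_factory=dict)
    prescriptions: dict[str, Prescription] = field(default_factory=dict)
    med_admins: list[MedicationAdministration] = field(default_factory=list)
    tox_screens: list[ToxScreen] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    _index: dict[tuple[str, EventKind], tuple[list[datetime], list[Event]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    # -- construction -------------------------------------------------------

    @classmethod
    def build(
        cls,
        patients: list[Patient],
        encounters: list[Encounter] = (),
        prescriptions: list[Prescription] = (),
        med_admins: list[MedicationAdministration] = (),
        tox_screens: list[ToxScreen] = (),
    ) -> "EventStore":
        store = cls()
        for p in patients:
            if p.patient_id in store.patients:
                raise ValidationError(f"duplicate patient_id {p.patient_id!r}")
            store.patients[p.patient_id] = p
        for e in encounters:
            if e.encounter_id in store.encounters:
                raise ValidationError(f"duplicate encounter_id {e.encounter_id!r}")
            store.encounters[e.encounter_id] = e
        for rx in prescriptions:
            if rx.rx_id in store.prescriptions:
                raise ValidationError(f"duplicate rx_id {rx.rx_id!r}")
            store.prescriptions[rx.rx_id] = rx
        store.med_admins = list(med_admins)
        store.tox_screens = list(tox_screens)
        store.validate()
        store._reindex()
        return store

    def validate(self) -> None:
        """Check every cross-reference and invariant; raise on violation.

        Missing prescription durations are recorded as warnings, not errors:
        the early-refill evaluator skips such prescriptions.
        """
        errs: list[str] = []
        for e in self.encounters.values():
            if e.patient_id not in self.patients:
                errs.append(
                    f"encounter {e.encounter_id}: unknown patient_id {e.patient_id!r}"
                )
            if e.disposition is Disposition.ADMITTED and e.facility_type not in (
                FacilityType.ED,
                FacilityType.URGENT_CARE,
            ):
                errs.append(
                    f"encounter {e.encounter_id}: disposition ADMITTED only valid "
                    f"for ED/URGENT_CARE, got {e.facility_type.value}"
                )
        for rx in self.prescriptions.values():
            if rx.patient_id not in self.patients:
                errs.append(f"prescription {rx.rx_id}: unknown patient_id {rx.patient_id!r}")
            enc = self.encounters.get(rx.encounter_id)
            if enc is None:
                errs.append(
                    f"prescription {rx.rx_id}: unknown encounter_id {rx.encounter_id!r}"
                )
            elif rx.written_at < enc.start_at:
                errs.append(
                    f"prescription {rx.rx_id}: written_at precedes encounter start"
                )
            if rx.drug_class is DrugClass.OTHER:
                errs.append(
                    f"prescription {rx.rx_id}: drug_class must be OPIOID or BENZODIAZEPINE"
                )
            if rx.duration_days is not None and rx.duration_days <= 0:
                errs.append(f"prescription {rx.rx_id}: duration_days must be > 0")
            if rx.duration_days is None:
                self.warnings.append(f"prescription {rx.rx_id}: missing duration_days")
        for i, ma in enumerate(self.med_admins):
            if ma.patient_id not in self.patients:
                errs.append(f"med_admin #{i}: unknown patient_id {ma.patient_id!r}")
            enc = self.encounters.get(ma.encounter_id)
            if enc is None:
                errs.append(f"med_admin #{i}: unknown encounter_id {ma.encounter_id!r}")
            elif ma.administered_at < enc.start_at:
                errs.append(f"med_admin #{i}: administered_at precedes encounter start")
        for i, ts in enumerate(self.tox_screens):
            if ts.patient_id not in self.patients:
                errs.append(f"tox_screen #{i}: unknown patient_id {ts.patient_id!r}")
        # date_of_birth never after any of the patient's events
        first_event: dict[str, datetime] = {}
        for kind in _TIME_ATTR:
            for ev in self._iter_kind(kind):
                t = event_time(kind, ev)
                pid = ev.patient_id
                if pid in self.patients and (pid not in first_event or t < first_event[pid]):
                    first_event[pid] = t
        for pid, t in first_event.items():
            dob = self.patients[pid].date_of_birth
            if datetime(dob.year, dob.month, dob.day, tzinfo=timezone.utc) > t:
                errs.append(f"patient {pid}: date_of_birth after first event")
        if errs:
            raise ValidationError("; ".join(errs))

    def _iter_kind(self, kind: EventKind) -> Iterator[Event]:
        if kind is EventKind.ENCOUNTER:
            yield from self.encounters.values()
        elif kind is EventKind.PRESCRIPTION:
            yield from self.prescriptions.values()
        elif kind is EventKind.MED_ADMIN:
            yield from self.med_admins
        elif kind is EventKind.TOX_SCREEN:
            yield from self.tox_screens

    def _reindex(self) -> None:
        self._index = {}
        buckets: dict[tuple[str, EventKind], list[tuple[datetime, int, Event]]] = {}
        for kind in _TIME_ATTR:
            for seq, ev in enumerate(self._iter_kind(kind)):
                buckets.setdefault((ev.patient_id, kind), []).append(
                    (event_time(kind, ev), seq, ev)
                )
        for key, items in buckets.items():
            items.sort(key=lambda x: (x[0], x[1]))
            self._index[key] = ([t for t, _, _ in items], [e for _, _, e in items])

    # -- queries ------------------------------------------------------------

    def patient_events(self, patient_id: str, kind: EventKind) -> list[Event]:
        """All events of one kind for a patient, in non-decreasing time order."""
        entry = self._index.get((patient_id, kind))
        return list(entry[1]) if entry else []

    def query_window(
        self,
        patient_id: str,
        kind: EventKind,
        t_start: datetime,
        t_end: datetime,
    ) -> list[Event]:
        """Events of ``kind`` for a patient with timestamp in ``[t_start, t_end)``.

        Unknown patients yield an empty list. Events are returned time-ordered.
        """
        if t_start > t_end:
            raise ValueError("t_start must not be after t_end")
        entry = self._index.get((patient_id, EventKind(kind)))
        if not entry:
            return []
        times, events = entry
        lo = bisect_left(times, t_start)
        hi = bisect_left(times, t_end)
        return events[lo:hi]

    def counts(self) -> tuple[int, int, int, int, int]:
        return (
            len(self.patients),
            len(self.encounters),
            len(self.prescriptions),
            len(self.med_admins),
            len(self.tox_screens),
        )


def query_window(
    store: EventStore,
    patient_id: str,
    kind: EventKind,
    t_start: datetime,
    t_end: datetime,
) -> list[Event]:
    return store.query_window(patient_id, kind, t_start, t_end)


# ---------------------------------------------------------------------------
# (de)serialization


def _parse_bool(raw: object, where: str, fieldname: str) -> bool:
    if isinstance(raw, bool):
        return raw
    if isinstance(raw, str) and raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    raise EventLogError(f"{where}: field {fieldname!r} is not a boolean: {raw!r}")


def _parse_enum(enum_cls, raw: object, where: str, fieldname: str):
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise EventLogError(
            f"{where}: field {fieldname!r} has unknown value {raw!r} "
            f"(allowed: {allowed})"
        ) from None


def _req(rec: dict, key: str, where: str) -> object:
    if key not in rec or rec[key] in (None, ""):
        raise EventLogError(f"{where}: missing required field {key!r}")
    return rec[key]


def _record_to_entity(kind: EventKind, rec: dict, where: str):
    try:
        if kind is EventKind.PATIENT:
            return Patient(
                patient_id=str(_req(rec, "patient_id", where)),
                date_of_birth=parse_date(str(_req(rec, "date_of_birth", where))),
            )
        if kind is EventKind.ENCOUNTER:
            return Encounter(
                encounter_id=str(_req(rec, "encounter_id", where)),
                patient_id=str(_req(rec, "patient_id", where)),
                start_at=parse_timestamp(str(_req(rec, "start_at", where))),
                facility_type=_parse_enum(
                    FacilityType, _req(rec, "facility_type", where), where, "facility_type"
                ),
                disposition=_parse_enum(
                    Disposition, _req(rec, "disposition", where), where, "disposition"
                ),
                is_overdose_presentation=_parse_bool(
                    rec.get("is_overdose_presentation", False),
                    where,
                    "is_overdose_presentation",
                ),
            )
        if kind is EventKind.PRESCRIPTION:
            raw_dur = rec.get("duration_days")
            duration = None if raw_dur in (None, "") else float(raw_dur)
            return Prescription(
                rx_id=str(_req(rec, "rx_id", where)),
                patient_id=str(_req(rec, "patient_id", where)),
                encounter_id=str(_req(rec, "encounter_id", where)),
                written_at=parse_timestamp(str(_req(rec, "written_at", where))),
                drug_class=_parse_enum(
                    DrugClass, _req(rec, "drug_class", where), where, "drug_class"
                ),
                duration_days=duration,
                prescriber_id=str(_req(rec, "prescriber_id", where)),
                drug_name=rec.get("drug_name") or None,
            )
        if kind is EventKind.MED_ADMIN:
            return MedicationAdministration(
                patient_id=str(_req(rec, "patient_id", where)),
                encounter_id=str(_req(rec, "encounter_id", where)),
                administered_at=parse_timestamp(str(_req(rec, "administered_at", where))),
                drug_class=_parse_enum(
                    DrugClass, _req(rec, "drug_class", where), where, "drug_class"
                ),
            )
        if kind is EventKind.TOX_SCREEN:
            return ToxScreen(
                patient_id=str(_req(rec, "patient_id", where)),
                collected_at=parse_timestamp(str(_req(rec, "collected_at", where))),
                analyte=_parse_enum(Analyte, _req(rec, "analyte", where), where, "analyte"),
                positive=_parse_bool(_req(rec, "positive", where), where, "positive"),
            )
    except EventLogError:
        raise
    except (ValueError, TypeError) as exc:
        raise EventLogError(f"{where}: {exc}") from exc
    raise AssertionError(f"unhandled kind {kind}")


def _entity_to_record(kind: EventKind, entity) -> dict:
    if kind is EventKind.PATIENT:
        return {
            "patient_id": entity.patient_id,
            "date_of_birth": entity.date_of_birth.isoformat(),
        }
    if kind is EventKind.ENCOUNTER:
        return {
            "encounter_id": entity.encounter_id,
            "patient_id": entity.patient_id,
            "start_at": format_timestamp(entity.start_at),
            "facility_type": entity.facility_type.value,
            "disposition": entity.disposition.value,
            "is_overdose_presentation": entity.is_overdose_presentation,
        }
    if kind is EventKind.PRESCRIPTION:
        return {
            "rx_id": entity.rx_id,
            "patient_id": entity.patient_id,
            "encounter_id": entity.encounter_id,
            "written_at": format_timestamp(entity.written_at),
            "drug_class": entity.drug_class.value,
            "duration_days": entity.duration_days,
            "prescriber_id": entity.prescriber_id,
            "drug_name": entity.drug_name,
        }
    if kind is EventKind.MED_ADMIN:
        return {
            "patient_id": entity.patient_id,
            "encounter_id": entity.encounter_id,
            "administered_at": format_timestamp(entity.administered_at),
            "drug_class": entity.drug_class.value,
        }
    if kind is EventKind.TOX_SCREEN:
        return {
            "patient_id": entity.patient_id,
            "collected_at": format_timestamp(entity.collected_at),
            "analyte": entity.analyte.value,
            "positive": entity.positive,
        }
    raise AssertionError(f"unhandled kind {kind}")


def _sorted_entities(store: EventStore) -> list[tuple[EventKind, Event]]:
    """Deterministic serialization order: patients, then events by time/id."""
    out: list[tuple[EventKind, Event]] = []
    out += [(EventKind.PATIENT, p) for _, p in sorted(store.patients.items())]
    out += [
        (EventKind.ENCOUNTER, e)
        for e in sorted(store.encounters.values(), key=lambda e: (e.start_at, e.encounter_id))
    ]
    out += [
        (EventKind.PRESCRIPTION, rx)
        for rx in sorted(store.prescriptions.values(), key=lambda r: (r.written_at, r.rx_id))
    ]
    out += [
        (EventKind.MED_ADMIN, m)
        for m in sorted(
            store.med_admins, key=lambda m: (m.administered_at, m.encounter_id, m.drug_class.value)
        )
    ]
    out += [
        (EventKind.TOX_SCREEN, t)
        for t in sorted(
            store.tox_screens, key=lambda t: (t.collected_at, t.patient_id, t.analyte.value)
        )
    ]
    return out


_CSV_FILES = {
    EventKind.PATIENT: "patients.csv",
    EventKind.ENCOUNTER: "encounters.csv",
    EventKind.PRESCRIPTION: "prescriptions.csv",
    EventKind.MED_ADMIN: "med_admins.csv",
    EventKind.TOX_SCREEN: "tox_screens.csv",
}

_CSV_COLUMNS = {
    EventKind.PATIENT: ["patient_id", "date_of_birth"],
    EventKind.ENCOUNTER: [
        "encounter_id",
        "patient_id",
        "start_at",
        "facility_type",
        "disposition",
        "is_overdose_presentation",
    ],
    EventKind.PRESCRIPTION: [
        "rx_id",
        "patient_id",
        "encounter_id",
        "written_at",
        "drug_class",
        "duration_days",
        "prescriber_id",
        "drug_name",
    ],
    EventKind.MED_ADMIN: ["patient_id", "encounter_id", "administered_at", "drug_class"],
    EventKind.TOX_SCREEN: ["patient_id", "collected_at", "analyte", "positive"],
}


def load_event_log(path: Union[str, Path], format: Union[LogFormat, str] = LogFormat.JSONL) -> EventStore:
    """Read and validate an event log (JSONL file or CSV directory)."""
    fmt = LogFormat(format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    groups: dict[EventKind, list] = {k: [] for k in EventKind}
    if fmt is LogFormat.JSONL:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                where = f"{path.name} line {lineno}"
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise EventLogError(f"{where}: invalid JSON ({exc.msg})") from exc
                if not isinstance(rec, dict):
                    raise EventLogError(f"{where}: record is not an object")
                kind = _parse_enum(EventKind, rec.get("kind"), where, "kind")
                groups[kind].append(_record_to_entity(kind, rec, where))
    else:
        for kind, fname in _CSV_FILES.items():
            fpath = path / fname
            if not fpath.exists():
                continue
            with open(fpath, newline="", encoding="utf-8") as fh:
                for rowno, row in enumerate(csv.DictReader(fh), start=2):
                    where = f"{fname} row {rowno}"
                    groups[kind].append(_record_to_entity(kind, row, where))
    return EventStore.build(
        patients=groups[EventKind.PATIENT],
        encounters=groups[EventKind.ENCOUNTER],
        prescriptions=groups[EventKind.PRESCRIPTION],
        med_admins=groups[EventKind.MED_ADMIN],
        tox_screens=groups[EventKind.TOX_SCREEN],
    )


def write_event_log(
    store: EventStore, path: Union[str, Path], format: Union[LogFormat, str] = LogFormat.JSONL
) -> None:
    """Serialize a store; ``load_event_log`` of the output reproduces it."""
    fmt = LogFormat(format)
    path = Path(path)
    entities = _sorted_entities(store)
    if fmt is LogFormat.JSONL:
        with open(path, "w", encoding="utf-8") as fh:
            for kind, entity in entities:
                rec = {"kind": kind.value}
                rec.update(_entity_to_record(kind, entity))
                fh.write(json.dumps(rec, separators=(",", ":")) + "\n")
    else:
        path.mkdir(parents=True, exist_ok=True)
        writers: dict[EventKind, csv.DictWriter] = {}
        handles = []
        try:
            for kind, fname in _CSV_FILES.items():
                fh = open(path / fname, "w", newline="", encoding="utf-8")
                handles.append(fh)
                w = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS[kind])
                w.writeheader()
                writers[kind] = w
            for kind, entity in entities:
                rec = _entity_to_record(kind, entity)
                rec = {k: ("" if v is None else v) for k, v in rec.items()}
                writers[kind].writerow(rec)
        finally:
            for fh in handles:
                fh.close()
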