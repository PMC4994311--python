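"""Aggregate an alert log into prescribing-encounter surveillance statistics.

A *prescribing encounter* is any encounter in which at least one opioid or
benzodiazepine prescription was initiated. The rule evaluates once per
prescription; this module unions the criteria met across an encounter's
prescriptions and tabulates, per surveillance period:

* prescribing encounters by patient age band (<18, 18-64, >=65 at the
  encounter date), facility bucket (ED/Urgent Care; Inpatient Discharge;
  Outpatient including phone calls; Other) and drug-class bucket
  (opioid only / benzodiazepine only / both);
* the distribution of the number of criteria met (0-5) and each criterion's
  prevalence, with per-analyte sub-rows for the toxicology criterion
  (sub-rows may overlap — one patient can screen positive for several
  analytes — so they need not sum to the parent row);
* alert rates: among prescribing encounters, among all in-period encounters
  (phone encounters excluded from that denominator, since phone contacts are
  not reliably documented as encounters), and per facility bucket.

All percentages are computed as round-half-up(100*count/denominator, 2 dp).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from .event_store import (
    Analyte,
    DrugClass,
    EventStore,
    FacilityType,
    format_timestamp,
)
from .triggers import CRITERIA_ORDER, Criterion
from .engine import AlertLog

__all__ = [
    "AgeBand",
    "FacilityBucket",
    "DrugClassBucket",
    "EncounterSummary",
    "SurveillanceReport",
    "ReportFormat",
    "age_band",
    "facility_bucket",
    "format_percent",
    "collect_prescribing_encounters",
    "build_report",
    "export_report",
]


class AgeBand(str, Enum):
    UNDER_18 = "UNDER_18"
    AGE_18_64 = "18_64"
    AGE_65_PLUS = "65_PLUS"


class FacilityBucket(str, Enum):
    ED_URGENT_CARE = "ED_URGENT_CARE"
    INPATIENT_DISCHARGE = "INPATIENT_DISCHARGE"
    OUTPATIENT_INCL_PHONE = "OUTPATIENT_INCL_PHONE"
    OTHER = "OTHER"


class DrugClassBucket(str, Enum):
    OPIOID_ONLY = "OPIOID_ONLY"
    BENZO_ONLY = "BENZO_ONLY"
    BOTH = "BOTH"


class ReportFormat(str, Enum):
    JSON = "JSON"
    CSV = "CSV"
    TEXT_TABLE = "TEXT_TABLE"


_FACILITY_TO_BUCKET = {
    FacilityType.ED: FacilityBucket.ED_URGENT_CARE,
    FacilityType.URGENT_CARE: FacilityBucket.ED_URGENT_CARE,
    FacilityType.INPATIENT: FacilityBucket.INPATIENT_DISCHARGE,
    FacilityType.OUTPATIENT: FacilityBucket.OUTPATIENT_INCL_PHONE,
    FacilityType.PHONE: FacilityBucket.OUTPATIENT_INCL_PHONE,
    FacilityType.OTHER: FacilityBucket.OTHER,
}


def facility_bucket(facility: FacilityType) -> FacilityBucket:
    return _FACILITY_TO_BUCKET[FacilityType(facility)]


def age_band(date_of_birth: date, at: datetime) -> AgeBand:
    """Age band at a given instant, using completed calendar years."""
    years = at.year - date_of_birth.year - (
        (at.month, at.day) < (date_of_birth.month, date_of_birth.day)
    )
    if years < 18:
        return AgeBand.UNDER_18
    if years < 65:
        return AgeBand.AGE_18_64
    return AgeBand.AGE_65_PLUS


def format_percent(count: int, denom: int) -> str:
    """Percentage as a 2-dp string, rounding half-up (e.g. 3.7475 -> "3.75")."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= count):
        raise ValueError("count must be non-negative")
    pct = Decimal(count) * 100 / Decimal(denom)
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _pct_or_zero(count: int, denom: int) -> str:
    return format_percent(count, denom) if denom > 0 else "0.00"


_ANALYTE_FLAG = {
    Analyte.BLOOD_ALCOHOL: "BAC",
    Analyte.COCAINE: "COCAINE",
    Analyte.MARIJUANA: "MARIJUANA",
}


@dataclass(frozen=True)
class EncounterSummary:
    """One prescribing encounter with criteria unioned over its prescriptions."""

    encounter_id: str
    patient_age_band: AgeBand
    facility_bucket: FacilityBucket
    drug_class_bucket: DrugClassBucket
    criteria_met: frozenset = frozenset()
    analyte_flags: frozenset = frozenset()  # subset of {"BAC","COCAINE","MARIJUANA"}
    rx_ids: tuple = ()

    @property
    def n_criteria(self) -> int:
        return len(self.criteria_met)


def collect_prescribing_encounters(
    alert_log: AlertLog, store: EventStore
) -> list[EncounterSummary]:
    """One summary per distinct encounter in the log.

    criteria_met is the union of met criteria across the encounter's alert
    records; age is computed at the encounter start. Order follows first
    appearance in the log.
    """
    by_encounter: dict[str, list] = {}
    order: list[str] = []
    for record in alert_log:
        if record.encounter_id not in by_encounter:
            by_encounter[record.encounter_id] = []
            order.append(record.encounter_id)
        by_encounter[record.encounter_id].append(record)

    summaries = []
    for eid in order:
        records = by_encounter[eid]
        encounter = store.encounters.get(eid)
        if encounter is None:
            raise ValueError(f"alert log references unknown encounter {eid!r}")
        patient = store.patients[encounter.patient_id]
        criteria: set[Criterion] = set()
        analytes: set[str] = set()
        classes: set[DrugClass] = set()
        rx_ids = []
        for r in records:
            rx_ids.append(r.rx_id)
            classes.add(r.drug_class)
            for d in r.trigger_result.details:
                if not d.met:
                    continue
                criteria.add(d.criterion)
                if d.criterion is Criterion.TOX_SCREEN:
                    for ev in d.evidence:
                        analytes.add(_ANALYTE_FLAG[Analyte(ev["analyte"])])
        if classes == {DrugClass.OPIOID, DrugClass.BENZODIAZEPINE}:
            bucket = DrugClassBucket.BOTH
        elif classes == {DrugClass.BENZODIAZEPINE}:
            bucket = DrugClassBucket.BENZO_ONLY
        else:
            bucket = DrugClassBucket.OPIOID_ONLY
        summaries.append(
            EncounterSummary(
                encounter_id=eid,
                patient_age_band=age_band(patient.date_of_birth, encounter.start_at),
                facility_bucket=facility_bucket(encounter.facility_type),
                drug_class_bucket=bucket,
                criteria_met=frozenset(criteria),
                analyte_flags=frozenset(analytes),
                rx_ids=tuple(rx_ids),
            )
        )
    return summaries


@dataclass
class SurveillanceReport:
    """Aggregate surveillance statistics over one period.

    Counts are exact; every ``*_pct`` entry is the round-half-up 2-dp
    percentage of the matching count over its denominator (prescribing
    encounters unless stated otherwise). Rates that need a full encounter
    denominator are None when the report was built without a backing store.
    """

    n_prescribing_encounters: int
    n_prescriptions: Optional[int]
    age_counts: dict
    age_pct: dict
    facility_counts: dict
    facility_pct: dict
    drug_class_counts: dict
    drug_class_pct: dict
    criteria_count_distribution: dict  # {0..5: count}
    criteria_count_pct: dict
    criterion_counts: dict  # {criterion: encounters meeting it}
    criterion_pct: dict
    analyte_counts: dict  # {"BAC","COCAINE","MARIJUANA": count}; rows may overlap
    analyte_pct: dict
    n_alert_encounters: int
    n_alert_prescriptions: Optional[int]
    alert_rate_prescribing_encounters_pct: str
    n_all_encounters: Optional[int] = None  # in-period, phone excluded
    alert_rate_all_encounters_pct: Optional[str] = None
    per_facility_alert_rate_pct: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "n_prescribing_encounters": self.n_prescribing_encounters,
            "n_prescriptions": self.n_prescriptions,
            "age_counts": dict(self.age_counts),
            "age_pct": dict(self.age_pct),
            "facility_counts": dict(self.facility_counts),
            "facility_pct": dict(self.facility_pct),
            "drug_class_counts": dict(self.drug_class_counts),
            "drug_class_pct": dict(self.drug_class_pct),
            "criteria_count_distribution": {
                str(k): v for k, v in self.criteria_count_distribution.items()
            },
            "criteria_count_pct": {str(k): v for k, v in self.criteria_count_pct.items()},
            "criterion_counts": dict(self.criterion_counts),
            "criterion_pct": dict(self.criterion_pct),
            "analyte_counts": dict(self.analyte_counts),
            "analyte_pct": dict(self.analyte_pct),
            "n_alert_encounters": self.n_alert_encounters,
            "n_alert_prescriptions": self.n_alert_prescriptions,
            "alert_rate_prescribing_encounters_pct": self.alert_rate_prescribing_encounters_pct,
            "n_all_encounters": self.n_all_encounters,
            "alert_rate_all_encounters_pct": self.alert_rate_all_encounters_pct,
            "per_facility_alert_rate_pct": (
                dict(self.per_facility_alert_rate_pct)
                if self.per_facility_alert_rate_pct is not None
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurveillanceReport":
        d = dict(d)
        d["criteria_count_distribution"] = {
            int(k): v for k, v in d["criteria_count_distribution"].items()
        }
        d["criteria_count_pct"] = {int(k): v for k, v in d["criteria_count_pct"].items()}
        return cls(**d)


def build_report(
    summaries: list[EncounterSummary],
    store: Optional[EventStore] = None,
    period: Optional[tuple[datetime, datetime]] = None,
    n_prescriptions: Optional[int] = None,
    n_alert_prescriptions: Optional[int] = None,
) -> SurveillanceReport:
    """Compute the full surveillance table from encounter summaries.

    With ``store`` and ``period`` supplied, also computes the alert rate among
    all in-period encounters (phone encounters excluded from the denominator)
    and per-facility alert rates; otherwise those fields are None.
    """
    n = len(summaries)
    age_counts = {b.value: 0 for b in AgeBand}
    fac_counts = {b.value: 0 for b in FacilityBucket}
    class_counts = {b.value: 0 for b in DrugClassBucket}
    dist = {k: 0 for k in range(6)}
    crit_counts = {c.value: 0 for c in CRITERIA_ORDER}
    analyte_counts = {"BAC": 0, "COCAINE": 0, "MARIJUANA": 0}
    flagged_by_bucket = {b.value: 0 for b in FacilityBucket}
    n_alert = 0
    for s in summaries:
        age_counts[s.patient_age_band.value] += 1
        fac_counts[s.facility_bucket.value] += 1
        class_counts[s.drug_class_bucket.value] += 1
        k = s.n_criteria
        if k > 5:
            raise ValueError(f"encounter {s.encounter_id}: more than 5 criteria")
        dist[k] += 1
        for c in s.criteria_met:
            crit_counts[Criterion(c).value] += 1
        for a in s.analyte_flags:
            analyte_counts[a] += 1
        if k >= 1:
            n_alert += 1
            flagged_by_bucket[s.facility_bucket.value] += 1

    if n_prescriptions is None:
        total_rx = sum(len(s.rx_ids) for s in summaries)
        n_prescriptions = total_rx if total_rx else None

    report = SurveillanceReport(
        n_prescribing_encounters=n,
        n_prescriptions=n_prescriptions,
        age_counts=age_counts,
        age_pct={b: _pct_or_zero(c, n) for b, c in age_counts.items()},
        facility_counts=fac_counts,
        facility_pct={b: _pct_or_zero(c, n) for b, c in fac_counts.items()},
        drug_class_counts=class_counts,
        drug_class_pct={b: _pct_or_zero(c, n) for b, c in class_counts.items()},
        criteria_count_distribution=dist,
        criteria_count_pct={k: _pct_or_zero(c, n) for k, c in dist.items()},
        criterion_counts=crit_counts,
        criterion_pct={c: _pct_or_zero(v, n) for c, v in crit_counts.items()},
        analyte_counts=analyte_counts,
        analyte_pct={a: _pct_or_zero(c, n) for a, c in analyte_counts.items()},
        n_alert_encounters=n_alert,
        n_alert_prescriptions=n_alert_prescriptions,
        alert_rate_prescribing_encounters_pct=_pct_or_zero(n_alert, n),
    )

    if store is not None and period is not None:
        start, end = period
        in_period = [
            e
            for e in store.encounters.values()
            if start <= e.start_at < end and e.facility_type is not FacilityType.PHONE
        ]
        all_by_bucket = {b.value: 0 for b in FacilityBucket}
        for e in in_period:
            all_by_bucket[facility_bucket(e.facility_type).value] += 1
        report.n_all_encounters = len(in_period)
        report.alert_rate_all_encounters_pct = _pct_or_zero(n_alert, len(in_period))
        report.per_facility_alert_rate_pct = {
            b: _pct_or_zero(flagged_by_bucket[b], all_by_bucket[b])
            for b in all_by_bucket
        }
    return report


# ---------------------------------------------------------------------------
# export


_AGE_LABEL = {"UNDER_18": "<18", "18_64": "18-64", "65_PLUS": ">=65"}
_FAC_LABEL = {
    "ED_URGENT_CARE": "ED/Urgent Care",
    "INPATIENT_DISCHARGE": "Inpatient Discharge",
    "OUTPATIENT_INCL_PHONE": "Outpatient including phone calls",
    "OTHER": "Other",
}
_CLASS_LABEL = {"OPIOID_ONLY": "Opioid", "BENZO_ONLY": "Benzodiazepine", "BOTH": "Both"}
_CRIT_LABEL = {
    "EARLY_REFILL": "Prescription with supply remaining above threshold",
    "ED_UC_ONSITE": "2+ visits with onsite administration",
    "RX_HISTORY": "3+ prescriptions in past 30 days",
    "TOX_SCREEN": "Positive tox screen",
    "OVERDOSE": "Previous presentation for overdose",
}
_ANALYTE_LABEL = {"BAC": "BAC", "COCAINE": "Cocaine", "MARIJUANA": "Marijuana"}


def _report_rows(report: SurveillanceReport) -> list[tuple[str, str, object, str]]:
    rows: list[tuple[str, str, object, str]] = []
    rows.append(("Totals", "Prescribing encounters", report.n_prescribing_encounters, ""))
    rows.append(("Totals", "Prescriptions", report.n_prescriptions, ""))
    for b in AgeBand:
        rows.append(
            ("Age of patient", _AGE_LABEL[b.value], report.age_counts[b.value],
             report.age_pct[b.value])
        )
    for b in FacilityBucket:
        rows.append(
            ("Facility type", _FAC_LABEL[b.value], report.facility_counts[b.value],
             report.facility_pct[b.value])
        )
    for b in DrugClassBucket:
        rows.append(
            ("Class of drug", _CLASS_LABEL[b.value], report.drug_class_counts[b.value],
             report.drug_class_pct[b.value])
        )
    for k in range(6):
        rows.append(
            ("Number of criteria met", str(k), report.criteria_count_distribution[k],
             report.criteria_count_pct[k])
        )
    crit_rows = ["EARLY_REFILL", "ED_UC_ONSITE", "RX_HISTORY", "TOX_SCREEN"]
    for c in crit_rows:
        rows.append(
            ("Criteria met", _CRIT_LABEL[c], report.criterion_counts[c],
             report.criterion_pct[c])
        )
        if c == "TOX_SCREEN":
            for a in ("BAC", "COCAINE", "MARIJUANA"):
                rows.append(
                    ("Criteria met", f"  {_ANALYTE_LABEL[a]}", report.analyte_counts[a],
                     report.analyte_pct[a])
                )
    rows.append(
        ("Criteria met", _CRIT_LABEL["OVERDOSE"], report.criterion_counts["OVERDOSE"],
         report.criterion_pct["OVERDOSE"])
    )
    rows.append(
        ("Alert rate", "Among prescribing encounters", report.n_alert_encounters,
         report.alert_rate_prescribing_encounters_pct)
    )
    if report.alert_rate_all_encounters_pct is not None:
        rows.append(
            ("Alert rate", "Among all encounters (phone excluded)",
             report.n_alert_encounters, report.alert_rate_all_encounters_pct)
        )
        for b in FacilityBucket:
            rows.append(
                ("Alert rate by facility", _FAC_LABEL[b.value], "",
                 report.per_facility_alert_rate_pct[b.value])
            )
    return rows


def export_report(
    report: SurveillanceReport,
    path: Union[str, Path],
    format: Union[ReportFormat, str] = ReportFormat.JSON,
) -> None:
    """Write the report as loss-free JSON, a CSV of rows, or a text table."""
    fmt = ReportFormat(format)
    path = Path(path)
    if fmt is ReportFormat.JSON:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2)
            fh.write("\n")
        return
    rows = _report_rows(report)
    if fmt is ReportFormat.CSV:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["section", "characteristic", "count", "percent"])
            w.writerows(rows)
        return
    width = max(len(f"{sec}: {label}") for sec, label, _, _ in rows) + 2
    lines = ["Characteristics of Controlled Substance Prescribing Encounters", "=" * 72]
    last_sec = None
    for sec, label, count, pct in rows:
        if sec != last_sec:
            lines.append(sec)
            last_sec = sec
        cell = f"{count}" if pct == "" else f"{count} ({pct} %)" if count != "" else f"{pct} %"
        lines.append(f"  {label:<{width}}{cell}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
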