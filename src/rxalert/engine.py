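"""Alert engine: executes the rule at every opioid/benzodiazepine prescription.

The rule runs once per prescription initiation, at the instant the
prescription is written — the point where the prescriber has chosen the drug
but before dosing and signing are complete. In LIVE mode a fired record
carries a rendered alert payload listing only the criteria the patient
actually meets, with a continue/cancel choice; in SILENT mode the evaluation
is identical but nothing is rendered, so a whole period can be surveilled
without interrupting prescribers. Trigger outcomes are mode-independent.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from .event_store import (
    DrugClass,
    EventStore,
    FacilityType,
    Prescription,
    format_timestamp,
    parse_timestamp,
)
from .triggers import (
    CRITERIA_ORDER,
    Criterion,
    TriggerConfig,
    TriggerDetail,
    TriggerResult,
    evaluate_triggers,
)

__all__ = [
    "Mode",
    "AlertRecord",
    "AlertLog",
    "process_prescription",
    "run_surveillance",
    "render_alert_text",
]


class Mode(str, Enum):
    SILENT = "SILENT"
    LIVE = "LIVE"


_CRITERION_LABEL = {
    Criterion.EARLY_REFILL: "Current prescription with supply remaining (early refill)",
    Criterion.ED_UC_ONSITE: "ED/Urgent Care visits with onsite opioid treatment",
    Criterion.RX_HISTORY: "Opioid/benzodiazepine prescriptions in previous 30 days",
    Criterion.OVERDOSE: "Previous presentation for overdose",
    Criterion.TOX_SCREEN: "Positive screen for blood alcohol, cocaine, or marijuana",
}


@dataclass(frozen=True)
class AlertRecord:
    """One rule evaluation at one prescription initiation."""

    rx_id: str
    patient_id: str
    encounter_id: str
    prescriber_id: str
    evaluated_at: datetime
    facility_type: FacilityType
    drug_class: DrugClass
    trigger_result: TriggerResult
    fired: bool
    mode: Mode
    payload: Optional[str] = None
    prescriber_response: Optional[str] = None  # unfilled in silent mode

    def __post_init__(self) -> None:
        if self.fired != (self.trigger_result.n_criteria_met >= 1):
            raise ValueError("fired must equal (n_criteria_met >= 1)")


@dataclass
class AlertLog:
    """Ordered alert records for a surveillance period."""

    records: list[AlertRecord]
    period_start: datetime
    period_end: datetime

    def __post_init__(self) -> None:
        for r in self.records:
            if not (self.period_start <= r.evaluated_at < self.period_end):
                raise ValueError(
                    f"record {r.rx_id} evaluated_at outside period bounds"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_fired(self) -> int:
        return sum(r.fired for r in self.records)

    # -- serialization -------------------------------------------------------

    def to_jsonl(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            header = {
                "kind": "alert_log",
                "period_start": format_timestamp(self.period_start),
                "period_end": format_timestamp(self.period_end),
            }
            fh.write(json.dumps(header, separators=(",", ":")) + "\n")
            for r in self.records:
                fh.write(json.dumps(_record_to_json(r), separators=(",", ":")) + "\n")

    @classmethod
    def from_jsonl(cls, path: Union[str, Path]) -> "AlertLog":
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            records = [_record_from_json(json.loads(line)) for line in fh if line.strip()]
        return cls(
            records=records,
            period_start=parse_timestamp(header["period_start"]),
            period_end=parse_timestamp(header["period_end"]),
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        cols = [
            "rx_id",
            "patient_id",
            "encounter_id",
            "prescriber_id",
            "evaluated_at",
            "facility_type",
            "drug_class",
            "fired",
            "n_criteria_met",
            "mode",
        ] + [c.value for c in CRITERIA_ORDER]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for r in self.records:
                w.writerow(
                    [
                        r.rx_id,
                        r.patient_id,
                        r.encounter_id,
                        r.prescriber_id,
                        format_timestamp(r.evaluated_at),
                        r.facility_type.value,
                        r.drug_class.value,
                        r.fired,
                        r.trigger_result.n_criteria_met,
                        r.mode.value,
                    ]
                    + [r.trigger_result.detail(c).met for c in CRITERIA_ORDER]
                )


def _record_to_json(r: AlertRecord) -> dict:
    return {
        "rx_id": r.rx_id,
        "patient_id": r.patient_id,
        "encounter_id": r.encounter_id,
        "prescriber_id": r.prescriber_id,
        "evaluated_at": format_timestamp(r.evaluated_at),
        "facility_type": r.facility_type.value,
        "drug_class": r.drug_class.value,
        "fired": r.fired,
        "mode": r.mode.value,
        "n_criteria_met": r.trigger_result.n_criteria_met,
        "triggers": [
            {
                "criterion": d.criterion.value,
                "met": d.met,
                "evidence": list(d.evidence),
                "warnings": list(d.warnings),
            }
            for d in r.trigger_result.details
        ],
        "payload": r.payload,
    }


def _record_from_json(rec: dict) -> AlertRecord:
    details = tuple(
        TriggerDetail(
            criterion=Criterion(d["criterion"]),
            met=d["met"],
            evidence=tuple(d["evidence"]),
            warnings=tuple(d.get("warnings", ())),
        )
        for d in rec["triggers"]
    )
    tr = TriggerResult(details=details, evaluated_at=parse_timestamp(rec["evaluated_at"]))
    return AlertRecord(
        rx_id=rec["rx_id"],
        patient_id=rec["patient_id"],
        encounter_id=rec["encounter_id"],
        prescriber_id=rec["prescriber_id"],
        evaluated_at=parse_timestamp(rec["evaluated_at"]),
        facility_type=FacilityType(rec["facility_type"]),
        drug_class=DrugClass(rec["drug_class"]),
        trigger_result=tr,
        fired=rec["fired"],
        mode=Mode(rec["mode"]),
        payload=rec.get("payload"),
    )


def render_alert_text(record: AlertRecord) -> str:
    """Render the interruptive alert payload for a fired record.

    Shows one block per met criterion (canonical order) with its evidence
    quantities; unmet criteria never appear. Ends with the two dispositions
    the prescriber must choose between.
    """
    if not record.fired:
        raise ValueError("render_alert_text requires a fired record")
    lines = [
        "CONTROLLED SUBSTANCE RISK ALERT",
        f"Patient {record.patient_id} meets "
        f"{record.trigger_result.n_criteria_met} risk criteria:",
        "",
    ]
    for detail in record.trigger_result.details:
        if not detail.met:
            continue
        lines.append(f"* {_CRITERION_LABEL[detail.criterion]}")
        for ev in detail.evidence:
            if detail.criterion is Criterion.EARLY_REFILL:
                lines.append(
                    f"    - {ev['rx_id']}: {ev['remaining_fraction'] * 100:.0f}% of "
                    f"{ev['duration_days']:g}-day supply remaining"
                )
            elif detail.criterion is Criterion.ED_UC_ONSITE:
                lines.append(f"    - visit {ev['encounter_id']} ({ev['facility_type']})")
            elif detail.criterion is Criterion.RX_HISTORY:
                lines.append(f"    - {ev['rx_id']} ({ev['drug_class']}) {ev['written_at']}")
            elif detail.criterion is Criterion.OVERDOSE:
                lines.append(f"    - overdose presentation {ev['encounter_id']}")
            elif detail.criterion is Criterion.TOX_SCREEN:
                lines.append(f"    - positive {ev['analyte']} ({ev['collected_at']})")
    lines += ["", "[ Continue prescription ]    [ Cancel prescription ]"]
    return "\n".join(lines)


def process_prescription(
    store: EventStore,
    rx: Prescription,
    config: TriggerConfig,
    mode: Union[Mode, str] = Mode.SILENT,
) -> AlertRecord:
    """Evaluate the rule for one prescription initiation.

    The alert fires when at least one criterion is met. SILENT mode logs the
    evaluation without rendering a payload; LIVE mode attaches the rendered
    alert text to fired records. The trigger result itself is identical in
    both modes.
    """
    mode = Mode(mode)
    result = evaluate_triggers(store, rx, config)
    fired = result.n_criteria_met >= 1
    encounter = store.encounters[rx.encounter_id]
    record = AlertRecord(
        rx_id=rx.rx_id,
        patient_id=rx.patient_id,
        encounter_id=rx.encounter_id,
        prescriber_id=rx.prescriber_id,
        evaluated_at=rx.written_at,
        facility_type=encounter.facility_type,
        drug_class=rx.drug_class,
        trigger_result=result,
        fired=fired,
        mode=mode,
    )
    if mode is Mode.LIVE and fired:
        record = dataclasses.replace(record, payload=render_alert_text(record))
    return record


def run_surveillance(
    store: EventStore,
    period: tuple[datetime, datetime],
    config: TriggerConfig,
    mode: Union[Mode, str] = Mode.SILENT,
) -> AlertLog:
    """Run the rule over every prescription initiated in ``[start, end)``.

    Produces exactly one record per opioid/benzodiazepine prescription whose
    written_at falls in the period; the log is a pure function of
    (store, period, config) and is sorted by evaluation time.
    """
    start, end = period
    if start > end:
        raise ValueError("period start must not be after period end")
    in_period = [
        rx
        for rx in store.prescriptions.values()
        if start <= rx.written_at < end
        and rx.drug_class in (DrugClass.OPIOID, DrugClass.BENZODIAZEPINE)
    ]
    in_period.sort(key=lambda rx: (rx.written_at, rx.rx_id))
    records = [process_prescription(store, rx, config, mode) for rx in in_period]
    return AlertLog(records=records, period_start=start, period_end=end)
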