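"""The five risk triggers evaluated at every opioid/benzodiazepine prescription.

Each trigger is an objective, EMR-searchable indicator of risk for misuse,
abuse, or diversion of controlled substances:

1. EARLY_REFILL — a current prescription with more than a threshold fraction
   of its days-of-supply still expected to remain (default > 50 %; the
   initial silent-surveillance profile used > 30 %).
2. ED_UC_ONSITE — at least ``min_ed_uc_visits`` ED or urgent-care visits with
   onsite opioid administration, not counting visits that led to admission,
   within the previous 30 days (default 2+; initially 3+).
3. RX_HISTORY — at least ``min_prescriptions`` opioid or benzodiazepine
   prescriptions within the previous 30 days (default 3+).
4. OVERDOSE — any previous overdose presentation on record (lifetime).
5. TOX_SCREEN — any positive blood-alcohol, cocaine, or marijuana screen on
   record (lifetime).

All evaluators are pure functions of (store, evaluation time, config). The
"previous W days" window is ``[t_eval − W days, t_eval)``: closed below, open
above, so events at the evaluation instant never count toward a lookback.
The index prescription is always excluded from its own EARLY_REFILL and
RX_HISTORY evidence, and the index encounter from the ED_UC_ONSITE count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml

from .event_store import (
    DrugClass,
    Disposition,
    EventKind,
    EventStore,
    FacilityType,
    Prescription,
    days_between,
)

__all__ = [
    "Criterion",
    "CRITERIA_ORDER",
    "TriggerConfig",
    "INITIAL_TRIGGER_CONFIG",
    "TriggerDetail",
    "TriggerResult",
    "eval_early_refill",
    "eval_ed_uc_onsite",
    "eval_rx_history",
    "eval_overdose_history",
    "eval_tox_screen",
    "evaluate_triggers",
]


class Criterion(str, Enum):
    EARLY_REFILL = "EARLY_REFILL"
    ED_UC_ONSITE = "ED_UC_ONSITE"
    RX_HISTORY = "RX_HISTORY"
    OVERDOSE = "OVERDOSE"
    TOX_SCREEN = "TOX_SCREEN"


#: Canonical presentation order (the order the final triggers are listed).
CRITERIA_ORDER: tuple[Criterion, ...] = (
    Criterion.EARLY_REFILL,
    Criterion.ED_UC_ONSITE,
    Criterion.RX_HISTORY,
    Criterion.OVERDOSE,
    Criterion.TOX_SCREEN,
)


@dataclass(frozen=True)
class TriggerConfig:
    """Tunable thresholds and window lengths for the five triggers.

    Defaults are the final published thresholds; ``INITIAL_TRIGGER_CONFIG``
    holds the pre-tuning profile (>30 % remaining, 3+ ED/UC visits).
    """

    remaining_fraction_threshold: float = 0.50
    min_ed_uc_visits: int = 2
    ed_uc_window_days: float = 30.0
    min_prescriptions: int = 3
    rx_window_days: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 < self.remaining_fraction_threshold < 1.0):
            raise ValueError("remaining_fraction_threshold must be in (0, 1)")
        if self.min_ed_uc_visits < 1 or self.min_prescriptions < 1:
            raise ValueError("minimum counts must be positive integers")
        if self.ed_uc_window_days <= 0 or self.rx_window_days <= 0:
            raise ValueError("window lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "TriggerConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown trigger config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "TriggerConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


INITIAL_TRIGGER_CONFIG = TriggerConfig(remaining_fraction_threshold=0.30, min_ed_uc_visits=3)


@dataclass(frozen=True)
class TriggerDetail:
    """Outcome of one criterion: met flag plus supporting evidence.

    ``evidence`` lists contributing event identifiers with the per-criterion
    quantities (remaining fraction, visit/prescription identifiers, analytes).
    ``met`` is true only with non-empty evidence.
    """

    criterion: Criterion
    met: bool
    evidence: tuple[dict, ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.met and not self.evidence:
            raise ValueError("met=True requires non-empty evidence")


@dataclass(frozen=True)
class TriggerResult:
    """All five criterion outcomes for one prescription-initiation evaluation."""

    details: tuple[TriggerDetail, ...]
    evaluated_at: datetime

    def __post_init__(self) -> None:
        got = tuple(d.criterion for d in self.details)
        if got != CRITERIA_ORDER:
            raise ValueError(f"details must cover the five criteria in order, got {got}")

    @property
    def n_criteria_met(self) -> int:
        return sum(d.met for d in self.details)

    def detail(self, criterion: Criterion) -> TriggerDetail:
        return self.details[CRITERIA_ORDER.index(Criterion(criterion))]

    @property
    def met_criteria(self) -> tuple[Criterion, ...]:
        return tuple(d.criterion for d in self.details if d.met)


def _window_start(t_eval: datetime, window_days: float) -> datetime:
    return t_eval - timedelta(days=window_days)


def eval_early_refill(
    store: EventStore,
    patient_id: str,
    t_eval: datetime,
    config: TriggerConfig,
    index_rx_id: Optional[str] = None,
) -> TriggerDetail:
    """Current prescription with more than the threshold fraction remaining.

    A prior prescription of either class qualifies when, at ``t_eval``,
    ``0 <= elapsed < duration_days`` and
    ``1 - elapsed / duration_days > remaining_fraction_threshold`` (strict).
    Prescriptions without a usable days-of-supply are skipped with a warning.
    """
    evidence: list[dict] = []
    warnings: list[str] = []
    for rx in store.patient_events(patient_id, EventKind.PRESCRIPTION):
        if index_rx_id is not None and rx.rx_id == index_rx_id:
            continue
        elapsed = days_between(rx.written_at, t_eval)
        if elapsed < 0:
            continue
        if rx.duration_days is None or rx.duration_days <= 0:
            warnings.append(f"prescription {rx.rx_id} skipped: missing/zero duration")
            continue
        if elapsed >= rx.duration_days:
            continue
        remaining = 1.0 - elapsed / rx.duration_days
        # strict inequality, with a tolerance that absorbs binary-representation
        # noise (1 - 7/10 = 0.30000000000000004 must not beat a 0.30 threshold)
        if remaining > config.remaining_fraction_threshold + 1e-12:
            evidence.append(
                {
                    "rx_id": rx.rx_id,
                    "drug_class": rx.drug_class.value,
                    "duration_days": rx.duration_days,
                    "elapsed_days": elapsed,
                    "remaining_fraction": remaining,
                }
            )
    return TriggerDetail(
        Criterion.EARLY_REFILL, bool(evidence), tuple(evidence), tuple(warnings)
    )


def eval_ed_uc_onsite(
    store: EventStore,
    patient_id: str,
    t_eval: datetime,
    config: TriggerConfig,
    index_encounter_id: Optional[str] = None,
) -> TriggerDetail:
    """ED/urgent-care visits with onsite opioid treatment in the lookback window.

    Counts distinct ED or urgent-care encounters that did not lead to
    admission, started within ``[t_eval − window, t_eval)``, and had at least
    one opioid administered onsite. The index encounter never counts.
    """
    t0 = _window_start(t_eval, config.ed_uc_window_days)
    admin_encounters = {
        ma.encounter_id
        for ma in store.patient_events(patient_id, EventKind.MED_ADMIN)
        if ma.drug_class is DrugClass.OPIOID
    }
    evidence = []
    for enc in store.query_window(patient_id, EventKind.ENCOUNTER, t0, t_eval):
        if index_encounter_id is not None and enc.encounter_id == index_encounter_id:
            continue
        if enc.facility_type not in (FacilityType.ED, FacilityType.URGENT_CARE):
            continue
        if enc.disposition is Disposition.ADMITTED:
            continue
        if enc.encounter_id not in admin_encounters:
            continue
        evidence.append(
            {
                "encounter_id": enc.encounter_id,
                "facility_type": enc.facility_type.value,
                "start_at": enc.start_at.isoformat(),
            }
        )
    met = len(evidence) >= config.min_ed_uc_visits
    return TriggerDetail(
        Criterion.ED_UC_ONSITE, met, tuple(evidence) if met else tuple(evidence), ()
    )


def eval_rx_history(
    store: EventStore,
    patient_id: str,
    t_eval: datetime,
    config: TriggerConfig,
    index_rx_id: Optional[str] = None,
) -> TriggerDetail:
    """3+ (configurable) opioid/benzodiazepine prescriptions in the window.

    Every prescription of either class counts once, even when several were
    written in the same encounter; the index prescription is excluded.
    """
    t0 = _window_start(t_eval, config.rx_window_days)
    evidence = [
        {
            "rx_id": rx.rx_id,
            "drug_class": rx.drug_class.value,
            "written_at": rx.written_at.isoformat(),
        }
        for rx in store.query_window(patient_id, EventKind.PRESCRIPTION, t0, t_eval)
        if not (index_rx_id is not None and rx.rx_id == index_rx_id)
    ]
    met = len(evidence) >= config.min_prescriptions
    return TriggerDetail(Criterion.RX_HISTORY, met, tuple(evidence), ())


def eval_overdose_history(
    store: EventStore, patient_id: str, t_eval: datetime
) -> TriggerDetail:
    """Any previous overdose presentation on record (lifetime lookback)."""
    evidence = [
        {"encounter_id": enc.encounter_id, "start_at": enc.start_at.isoformat()}
        for enc in store.patient_events(patient_id, EventKind.ENCOUNTER)
        if enc.is_overdose_presentation and enc.start_at < t_eval
    ]
    return TriggerDetail(Criterion.OVERDOSE, bool(evidence), tuple(evidence), ())


def eval_tox_screen(store: EventStore, patient_id: str, t_eval: datetime) -> TriggerDetail:
    """Any positive blood-alcohol, cocaine, or marijuana screen (lifetime).

    Evidence lists every positive analyte, so one patient can contribute to
    several analyte tallies in the surveillance report.
    """
    evidence = [
        {"analyte": ts.analyte.value, "collected_at": ts.collected_at.isoformat()}
        for ts in store.patient_events(patient_id, EventKind.TOX_SCREEN)
        if ts.positive and ts.collected_at < t_eval
    ]
    return TriggerDetail(Criterion.TOX_SCREEN, bool(evidence), tuple(evidence), ())


def evaluate_triggers(
    store: EventStore, index_rx: Prescription, config: TriggerConfig
) -> TriggerResult:
    """Run the full rule for one prescription initiation.

    Evaluates all five criteria at ``index_rx.written_at`` with the index
    prescription (and its encounter, for the onsite-treatment criterion)
    excluded where the definitions require.
    """
    if store.prescriptions.get(index_rx.rx_id) != index_rx:
        raise ValueError(f"index prescription {index_rx.rx_id!r} not in store")
    pid = index_rx.patient_id
    t_eval = index_rx.written_at
    details = (
        eval_early_refill(store, pid, t_eval, config, index_rx_id=index_rx.rx_id),
        eval_ed_uc_onsite(
            store, pid, t_eval, config, index_encounter_id=index_rx.encounter_id
        ),
        eval_rx_history(store, pid, t_eval, config, index_rx_id=index_rx.rx_id),
        eval_overdose_history(store, pid, t_eval),
        eval_tox_screen(store, pid, t_eval),
    )
    return TriggerResult(details=details, evaluated_at=t_eval)
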