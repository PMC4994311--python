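"""Threshold-tuning sweep: alert burden vs additional at-risk patients.

Replays silent surveillance under a grid of trigger configurations and
tabulates, per configuration, each criterion's encounter-level rate, the
overall >=1-criterion rate, and how many encounters/distinct patients would
be flagged. ``compare_configs`` reports the marginal effect of moving from
one configuration to another, including the count of patients captured by
the second configuration but missed by the first — the quantity that matters
when relaxing a threshold to find more at-risk patients, weighed against the
added alert burden. No alert-rate objective is optimized; the module reports
trade-offs and leaves the decision to the reviewing clinicians.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable

from .engine import AlertLog, Mode, run_surveillance
from .event_store import EventStore
from .report import build_report, collect_prescribing_encounters
from .triggers import CRITERIA_ORDER, Criterion, TriggerConfig

__all__ = ["TuningRow", "sweep", "compare_configs"]


@dataclass(frozen=True)
class TuningRow:
    """Surveillance outcomes under one trigger configuration."""

    config: TriggerConfig
    n_prescribing_encounters: int
    criterion_rate_pct: dict  # {criterion: float percent of prescribing encounters}
    rate_ge1_pct: float
    n_encounters_flagged: int
    n_distinct_patients_flagged: int


def _flagged_patients(log: AlertLog) -> set[str]:
    return {r.patient_id for r in log if r.fired}


def _criterion_patients(log: AlertLog, criterion: Criterion) -> set[str]:
    return {r.patient_id for r in log if r.trigger_result.detail(criterion).met}


def _row_for(store: EventStore, period, config: TriggerConfig) -> tuple[TuningRow, AlertLog]:
    log = run_surveillance(store, period, config, mode=Mode.SILENT)
    summaries = collect_prescribing_encounters(log, store)
    report = build_report(summaries)
    n = report.n_prescribing_encounters
    rates = {
        c.value: (100.0 * report.criterion_counts[c.value] / n if n else 0.0)
        for c in CRITERIA_ORDER
    }
    row = TuningRow(
        config=config,
        n_prescribing_encounters=n,
        criterion_rate_pct=rates,
        rate_ge1_pct=(100.0 * report.n_alert_encounters / n if n else 0.0),
        n_encounters_flagged=report.n_alert_encounters,
        n_distinct_patients_flagged=len(_flagged_patients(log)),
    )
    return row, log


def sweep(
    store: EventStore,
    period: tuple[datetime, datetime],
    config_grid: Iterable[TriggerConfig],
) -> list[TuningRow]:
    """One surveillance run per configuration in the grid.

    Each row is exactly what an independent run_surveillance + build_report
    under that configuration yields; rows follow grid order.
    """
    grid = list(config_grid)
    if not grid:
        raise ValueError("config_grid must be non-empty")
    return [_row_for(store, period, cfg)[0] for cfg in grid]


def compare_configs(
    store: EventStore,
    period: tuple[datetime, datetime],
    config_a: TriggerConfig,
    config_b: TriggerConfig,
) -> dict:
    """Marginal effect of moving from config_a to config_b.

    Reports per-criterion rate deltas (b minus a, percentage points), the
    change in flagged encounters, and the distinct patients flagged under b
    but not under a (and vice versa).
    """
    row_a, log_a = _row_for(store, period, config_a)
    row_b, log_b = _row_for(store, period, config_b)
    pat_a, pat_b = _flagged_patients(log_a), _flagged_patients(log_b)
    return {
        "criterion_rate_delta_pct": {
            c.value: row_b.criterion_rate_pct[c.value] - row_a.criterion_rate_pct[c.value]
            for c in CRITERIA_ORDER
        },
        "rate_ge1_delta_pct": row_b.rate_ge1_pct - row_a.rate_ge1_pct,
        "n_encounters_flagged_a": row_a.n_encounters_flagged,
        "n_encounters_flagged_b": row_b.n_encounters_flagged,
        "n_encounters_flagged_delta": row_b.n_encounters_flagged - row_a.n_encounters_flagged,
        "n_patients_flagged_a": len(pat_a),
        "n_patients_flagged_b": len(pat_b),
        "additional_patients_b_not_a": len(pat_b - pat_a),
        "patients_lost_a_not_b": len(pat_a - pat_b),
        "additional_patient_ids_b_not_a": sorted(pat_b - pat_a),
    }
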