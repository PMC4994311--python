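"""Seeded synthetic EMR cohort generator.

Emulates a mixed-risk population so the rule engine, reporter and tuning
sweep are exercisable without real patient data. Four patient archetypes:

* BASELINE — occasional care users with sporadic prescriptions.
* FREQUENT_UTILIZER — heavy ED/urgent-care users with elevated encounter and
  prescription rates (drives the early-refill, onsite-treatment and
  prescription-history triggers).
* SUBSTANCE_USE — carries positive toxicology screens in the record.
* OVERDOSE_HISTORY — at least one overdose presentation predating the
  surveillance period.

Encounters arrive as a homogeneous Poisson process per patient over the
surveillance period plus a pre-period (default 90 days) so 30-day lookbacks
have history. Prescriptions are written at the encounter instant. One
RNG stream per patient, spawned from the master seed in a fixed order
(demographics and archetypes first, then per-patient event streams), so
identical configs produce byte-identical event logs.

The default configuration is calibrated so the five criterion prevalences
land at the same order of magnitude as a real mixed acute/ambulatory health
system (early refill the most common trigger, overdose history the rarest);
matching any particular system's rates exactly is not a contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .event_store import (
    Analyte,
    Disposition,
    DrugClass,
    Encounter,
    EventStore,
    FacilityType,
    MedicationAdministration,
    Patient,
    Prescription,
    ToxScreen,
    format_timestamp,
    parse_timestamp,
)

__all__ = [
    "Archetype",
    "CohortConfig",
    "ConfigError",
    "assign_archetypes",
    "generate_cohort",
    "summarize_cohort",
    "DEFAULT_PERIOD_START",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


class Archetype(str, Enum):
    BASELINE = "BASELINE"
    FREQUENT_UTILIZER = "FREQUENT_UTILIZER"
    SUBSTANCE_USE = "SUBSTANCE_USE"
    OVERDOSE_HISTORY = "OVERDOSE_HISTORY"


DEFAULT_PERIOD_START = datetime(2015, 4, 1, tzinfo=timezone.utc)

_DEFAULT_MIXTURE = {
    Archetype.BASELINE: 0.82,
    Archetype.FREQUENT_UTILIZER: 0.09,
    Archetype.SUBSTANCE_USE: 0.07,
    Archetype.OVERDOSE_HISTORY: 0.02,
}

_DEFAULT_RATES = {
    Archetype.BASELINE: 0.6,
    Archetype.FREQUENT_UTILIZER: 3.5,
    Archetype.SUBSTANCE_USE: 1.2,
    Archetype.OVERDOSE_HISTORY: 1.2,
}

_DEFAULT_FACILITY_MIX = {
    FacilityType.ED: 0.12,
    FacilityType.URGENT_CARE: 0.08,
    FacilityType.INPATIENT: 0.05,
    FacilityType.OUTPATIENT: 0.58,
    FacilityType.PHONE: 0.14,
    FacilityType.OTHER: 0.03,
}

# frequent utilizers seek acute care disproportionately
_DEFAULT_FACILITY_OVERRIDES = {
    Archetype.FREQUENT_UTILIZER: {
        FacilityType.ED: 0.45,
        FacilityType.URGENT_CARE: 0.25,
        FacilityType.INPATIENT: 0.05,
        FacilityType.OUTPATIENT: 0.20,
        FacilityType.PHONE: 0.04,
        FacilityType.OTHER: 0.01,
    }
}

_DEFAULT_P_PRESCRIBE = {
    FacilityType.ED: 0.40,
    FacilityType.URGENT_CARE: 0.35,
    FacilityType.INPATIENT: 0.50,
    FacilityType.OUTPATIENT: 0.25,
    FacilityType.PHONE: 0.15,
    FacilityType.OTHER: 0.10,
}

_DEFAULT_DRUG_CLASS_MIX = {"OPIOID_ONLY": 0.73, "BENZO_ONLY": 0.23, "BOTH": 0.04}

_DEFAULT_TOX_RATES = {
    Analyte.BLOOD_ALCOHOL: 0.35,
    Analyte.COCAINE: 0.30,
    Analyte.MARIJUANA: 0.60,
}


def _as_enum_map(d: dict, enum_cls, name: str) -> dict:
    out = {}
    for k, v in d.items():
        try:
            out[enum_cls(k)] = float(v)
        except ValueError:
            raise ConfigError(f"{name}: unknown key {k!r}") from None
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Probabilities are per the unit stated in each field name; encounter rates
    are expected encounters per 30 days per patient of that archetype.
    """

    n_patients: int = 2000
    period_days: int = 30
    pre_period_days: int = 90
    period_start: datetime = DEFAULT_PERIOD_START
    archetype_mixture: dict = field(default_factory=lambda: dict(_DEFAULT_MIXTURE))
    encounter_rate_per_30d: dict = field(default_factory=lambda: dict(_DEFAULT_RATES))
    facility_mix: dict = field(default_factory=lambda: dict(_DEFAULT_FACILITY_MIX))
    facility_mix_overrides: dict = field(
        default_factory=lambda: {a: dict(m) for a, m in _DEFAULT_FACILITY_OVERRIDES.items()}
    )
    p_prescribe_given_encounter: dict = field(
        default_factory=lambda: dict(_DEFAULT_P_PRESCRIBE)
    )
    drug_class_mix: dict = field(default_factory=lambda: dict(_DEFAULT_DRUG_CLASS_MIX))
    duration_days_distribution: tuple = ("uniform", 5.0, 30.0)  # or ("fixed", x)
    p_onsite_opioid_admin_ED_UC: float = 0.30
    p_admitted_given_ED: float = 0.15
    tox_positive_rates: dict = field(default_factory=lambda: dict(_DEFAULT_TOX_RATES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if self.period_days <= 0 or self.pre_period_days < 0:
            raise ConfigError("period_days must be positive, pre_period_days non-negative")
        mix = _as_enum_map(self.archetype_mixture, Archetype, "archetype_mixture")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError("archetype_mixture must sum to 1")
        fac = _as_enum_map(self.facility_mix, FacilityType, "facility_mix")
        if abs(sum(fac.values()) - 1.0) > 1e-9:
            raise ConfigError("facility_mix must sum to 1")
        for a, m in self.facility_mix_overrides.items():
            m = _as_enum_map(m, FacilityType, f"facility_mix_overrides[{a}]")
            if abs(sum(m.values()) - 1.0) > 1e-9:
                raise ConfigError(f"facility_mix_overrides[{a}] must sum to 1")
        dmix = {str(k): float(v) for k, v in self.drug_class_mix.items()}
        if set(dmix) != {"OPIOID_ONLY", "BENZO_ONLY", "BOTH"}:
            raise ConfigError("drug_class_mix needs keys OPIOID_ONLY, BENZO_ONLY, BOTH")
        if abs(sum(dmix.values()) - 1.0) > 1e-9:
            raise ConfigError("drug_class_mix must sum to 1")
        probs = (
            [self.p_onsite_opioid_admin_ED_UC, self.p_admitted_given_ED]
            + list(self.p_prescribe_given_encounter.values())
            + list(self.tox_positive_rates.values())
            + list(mix.values())
            + list(fac.values())
        )
        if any(not (0.0 <= float(p) <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if any(float(r) < 0 for r in self.encounter_rate_per_30d.values()):
            raise ConfigError("encounter rates must be non-negative")
        kind = self.duration_days_distribution[0]
        if kind == "fixed":
            if float(self.duration_days_distribution[1]) <= 0:
                raise ConfigError("fixed duration must be positive")
        elif kind == "uniform":
            lo, hi = map(float, self.duration_days_distribution[1:3])
            if not (0 < lo <= hi):
                raise ConfigError("uniform duration bounds must satisfy 0 < lo <= hi")
        else:
            raise ConfigError("duration_days_distribution must be fixed or uniform")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "period_start" in d and isinstance(d["period_start"], str):
            d["period_start"] = parse_timestamp(d["period_start"])
        if "duration_days_distribution" in d:
            d["duration_days_distribution"] = tuple(d["duration_days_distribution"])
        known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown cohort config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def assign_archetypes(n: int, mixture: dict, seed: int) -> list[Archetype]:
    """Draw ``n`` archetype labels i.i.d. from ``mixture`` (deterministic in seed)."""
    mix = _as_enum_map(mixture, Archetype, "archetype_mixture")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigError("archetype_mixture must sum to 1")
    if n < 0:
        raise ConfigError("n must be non-negative")
    labels = sorted(mix, key=lambda a: a.value)
    probs = np.array([mix[a] for a in labels], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(labels), size=n, p=probs)
    return [labels[i] for i in idx]


def _draw_facility(rng: np.random.Generator, mix: dict) -> FacilityType:
    keys = sorted(mix, key=lambda f: f.value)
    probs = np.array([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _draw_duration(rng: np.random.Generator, dist: tuple) -> float:
    if dist[0] == "fixed":
        return float(dist[1])
    lo, hi = float(dist[1]), float(dist[2])
    return float(rng.uniform(lo, hi))


def generate_cohort(config: CohortConfig) -> EventStore:
    """Generate a validated synthetic cohort event store.

    Deterministic: identical configs (including seed) yield identical stores
    and byte-identical serialized logs.
    """
    config.validate()
    n = config.n_patients
    mixture = _as_enum_map(config.archetype_mixture, Archetype, "archetype_mixture")
    rates = _as_enum_map(config.encounter_rate_per_30d, Archetype, "encounter_rate_per_30d")
    base_mix = _as_enum_map(config.facility_mix, FacilityType, "facility_mix")
    overrides = {
        Archetype(a): _as_enum_map(m, FacilityType, "facility_mix_overrides")
        for a, m in config.facility_mix_overrides.items()
    }
    p_rx = _as_enum_map(config.p_prescribe_given_encounter, FacilityType, "p_prescribe")
    tox_rates = _as_enum_map(config.tox_positive_rates, Analyte, "tox_positive_rates")
    class_mix = {str(k): float(v) for k, v in config.drug_class_mix.items()}

    master = np.random.SeedSequence(config.seed)
    demo_seed, *patient_seeds = master.spawn(n + 1)
    demo_rng = np.random.default_rng(demo_seed)

    archetypes = assign_archetypes(n, mixture, seed=config.seed)
    # ages 5-90 years at period start; dob precedes every generated event
    ages = demo_rng.uniform(5.0, 90.0, size=n)

    start = config.period_start
    span_start = start - timedelta(days=config.pre_period_days)
    span_days = config.pre_period_days + config.period_days

    patients: list[Patient] = []
    encounters: list[Encounter] = []
    prescriptions: list[Prescription] = []
    med_admins: list[MedicationAdministration] = []
    tox_screens: list[ToxScreen] = []

    for i in range(n):
        pid = f"P{i:06d}"
        arche = archetypes[i]
        dob = (start - timedelta(days=float(ages[i]) * 365.25)).date()
        patients.append(Patient(patient_id=pid, date_of_birth=dob))
        rng = np.random.default_rng(patient_seeds[i])

        # pre-period history specific to the archetype
        if arche is Archetype.OVERDOSE_HISTORY:
            t_od = span_start + timedelta(
                days=float(rng.uniform(0, max(config.pre_period_days, 1)))
            )
            t_od = min(t_od, start - timedelta(seconds=1))
            encounters.append(
                Encounter(
                    encounter_id=f"E{pid}OD",
                    patient_id=pid,
                    start_at=t_od,
                    facility_type=FacilityType.ED,
                    disposition=Disposition.DISCHARGED,
                    is_overdose_presentation=True,
                )
            )
        if arche is Archetype.SUBSTANCE_USE:
            for analyte in sorted(tox_rates, key=lambda a: a.value):
                if rng.uniform() < tox_rates[analyte]:
                    t_ts = span_start + timedelta(
                        days=float(rng.uniform(0, span_days))
                    )
                    tox_screens.append(
                        ToxScreen(
                            patient_id=pid,
                            collected_at=t_ts,
                            analyte=analyte,
                            positive=True,
                        )
                    )

        # encounter stream: homogeneous Poisson process over the full span
        rate = rates.get(arche, 0.0)
        n_enc = rng.poisson(rate * span_days / 30.0)
        times = np.sort(rng.uniform(0.0, span_days, size=n_enc))
        fac_mix = overrides.get(arche, base_mix)
        for j, offset in enumerate(times):
            eid = f"E{pid}N{j:03d}"
            t_enc = span_start + timedelta(days=float(offset))
            facility = _draw_facility(rng, fac_mix)
            is_ed_uc = facility in (FacilityType.ED, FacilityType.URGENT_CARE)
            if is_ed_uc:
                admitted = rng.uniform() < config.p_admitted_given_ED
                disposition = Disposition.ADMITTED if admitted else Disposition.DISCHARGED
            else:
                disposition = Disposition.NOT_APPLICABLE
            encounters.append(
                Encounter(
                    encounter_id=eid,
                    patient_id=pid,
                    start_at=t_enc,
                    facility_type=facility,
                    disposition=disposition,
                    is_overdose_presentation=False,
                )
            )
            if is_ed_uc and rng.uniform() < config.p_onsite_opioid_admin_ED_UC:
                med_admins.append(
                    MedicationAdministration(
                        patient_id=pid,
                        encounter_id=eid,
                        administered_at=t_enc + timedelta(minutes=30),
                        drug_class=DrugClass.OPIOID,
                    )
                )
            if rng.uniform() < p_rx.get(facility, 0.0):
                u = rng.uniform()
                if u < class_mix["OPIOID_ONLY"]:
                    classes = [DrugClass.OPIOID]
                elif u < class_mix["OPIOID_ONLY"] + class_mix["BENZO_ONLY"]:
                    classes = [DrugClass.BENZODIAZEPINE]
                else:
                    classes = [DrugClass.OPIOID, DrugClass.BENZODIAZEPINE]
                prescriber = f"DR{int(rng.integers(0, 40)):02d}"
                for k, drug_class in enumerate(classes):
                    prescriptions.append(
                        Prescription(
                            rx_id=f"R{eid[1:]}X{k}",
                            patient_id=pid,
                            encounter_id=eid,
                            written_at=t_enc,
                            drug_class=drug_class,
                            duration_days=round(
                                _draw_duration(rng, config.duration_days_distribution), 2
                            ),
                            prescriber_id=prescriber,
                        )
                    )

    return EventStore.build(
        patients=patients,
        encounters=encounters,
        prescriptions=prescriptions,
        med_admins=med_admins,
        tox_screens=tox_screens,
    )


def summarize_cohort(store: EventStore) -> dict:
    """Marginal summary: facility mix, drug-class mix, history prevalences."""
    n_enc = len(store.encounters)
    by_fac: dict[str, int] = {f.value: 0 for f in FacilityType}
    for enc in store.encounters.values():
        by_fac[enc.facility_type.value] += 1
    by_class: dict[str, int] = {
        DrugClass.OPIOID.value: 0,
        DrugClass.BENZODIAZEPINE.value: 0,
    }
    for rx in store.prescriptions.values():
        by_class[rx.drug_class.value] += 1
    pos_tox_patients = {ts.patient_id for ts in store.tox_screens if ts.positive}
    od_patients = {
        e.patient_id for e in store.encounters.values() if e.is_overdose_presentation
    }
    n_pat = len(store.patients)
    return {
        "n_patients": n_pat,
        "n_encounters": n_enc,
        "n_prescriptions": len(store.prescriptions),
        "encounters_by_facility": by_fac,
        "facility_fractions": {
            f: (c / n_enc if n_enc else 0.0) for f, c in by_fac.items()
        },
        "prescriptions_by_class": by_class,
        "frac_patients_any_positive_tox": (len(pos_tox_patients) / n_pat) if n_pat else 0.0,
        "frac_patients_any_overdose": (len(od_patients) / n_pat) if n_pat else 0.0,
    }
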