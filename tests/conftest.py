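from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pytest

from rxalert import (
    Analyte,
    CohortConfig,
    Disposition,
    DrugClass,
    Encounter,
    EventStore,
    FacilityType,
    MedicationAdministration,
    Patient,
    Prescription,
    ToxScreen,
    generate_cohort,
)

#: Reference evaluation instant used by hand-built fixtures.
T0 = datetime(2015, 4, 15, 12, 0, tzinfo=timezone.utc)


def days(x: float) -> timedelta:
    return timedelta(days=x)


class StoreBuilder:
    """Compact builder for hand-crafted event stores in tests.

    Times are given as day offsets relative to ``t0`` (so -30 means thirty
    days before the reference instant).
    """

    def __init__(self, t0: datetime = T0):
        self.t0 = t0
        self.patients: list[Patient] = []
        self.encounters: list[Encounter] = []
        self.prescriptions: list[Prescription] = []
        self.med_admins: list[MedicationAdministration] = []
        self.tox_screens: list[ToxScreen] = []
        self._enc_by_id: dict[str, Encounter] = {}

    def at(self, offset_days: float) -> datetime:
        return self.t0 + days(offset_days)

    def patient(self, pid: str = "P1", dob: date = date(1980, 1, 1)) -> "StoreBuilder":
        self.patients.append(Patient(patient_id=pid, date_of_birth=dob))
        return self

    def encounter(
        self,
        eid: str,
        pid: str = "P1",
        at: float = 0.0,
        facility: FacilityType = FacilityType.OUTPATIENT,
        disposition: Disposition | None = None,
        overdose: bool = False,
    ) -> "StoreBuilder":
        facility = FacilityType(facility)
        if disposition is None:
            disposition = (
                Disposition.DISCHARGED
                if facility in (FacilityType.ED, FacilityType.URGENT_CARE)
                else Disposition.NOT_APPLICABLE
            )
        disposition = Disposition(disposition)
        enc = Encounter(
            encounter_id=eid,
            patient_id=pid,
            start_at=self.at(at),
            facility_type=facility,
            disposition=disposition,
            is_overdose_presentation=overdose,
        )
        self.encounters.append(enc)
        self._enc_by_id[eid] = enc
        return self

    def rx(
        self,
        rid: str,
        eid: str,
        at: float | None = None,
        drug: DrugClass = DrugClass.OPIOID,
        duration: float | None = 10.0,
        prescriber: str = "DR1",
    ) -> "StoreBuilder":
        enc = self._enc_by_id[eid]
        self.prescriptions.append(
            Prescription(
                rx_id=rid,
                patient_id=enc.patient_id,
                encounter_id=eid,
                written_at=enc.start_at if at is None else self.at(at),
                drug_class=DrugClass(drug),
                duration_days=duration,
                prescriber_id=prescriber,
            )
        )
        return self

    def admin(
        self, eid: str, at: float | None = None, drug: DrugClass = DrugClass.OPIOID
    ) -> "StoreBuilder":
        enc = self._enc_by_id[eid]
        self.med_admins.append(
            MedicationAdministration(
                patient_id=enc.patient_id,
                encounter_id=eid,
                administered_at=enc.start_at if at is None else self.at(at),
                drug_class=DrugClass(drug),
            )
        )
        return self

    def tox(
        self,
        pid: str = "P1",
        at: float = -10.0,
        analyte: Analyte = Analyte.MARIJUANA,
        positive: bool = True,
    ) -> "StoreBuilder":
        self.tox_screens.append(
            ToxScreen(
                patient_id=pid,
                collected_at=self.at(at),
                analyte=Analyte(analyte),
                positive=positive,
            )
        )
        return self

    def build(self) -> EventStore:
        return EventStore.build(
            patients=self.patients,
            encounters=self.encounters,
            prescriptions=self.prescriptions,
            med_admins=self.med_admins,
            tox_screens=self.tox_screens,
        )


@pytest.fixture
def builder() -> StoreBuilder:
    return StoreBuilder().patient("P1")


@pytest.fixture(scope="session")
def small_cohort() -> EventStore:
    """Seeded 400-patient cohort shared by fast structural tests."""
    return generate_cohort(CohortConfig(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def medium_cohort() -> EventStore:
    """Seeded 2,000-patient cohort for oracle and conservation checks."""
    return generate_cohort(CohortConfig(n_patients=2000, seed=7))


@pytest.fixture(scope="session")
def default_period() -> tuple[datetime, datetime]:
    cfg = CohortConfig()
    return (cfg.period_start, cfg.period_start + days(cfg.period_days))
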