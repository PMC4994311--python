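"""Trigger evaluators: worked examples, boundaries, and brute-force oracles."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxalert import (
    CRITERIA_ORDER,
    CohortConfig,
    Criterion,
    DrugClass,
    Disposition,
    FacilityType,
    INITIAL_TRIGGER_CONFIG,
    TriggerConfig,
    evaluate_triggers,
    generate_cohort,
)
from rxalert.triggers import (
    eval_early_refill,
    eval_ed_uc_onsite,
    eval_overdose_history,
    eval_rx_history,
    eval_tox_screen,
)
from rxalert.event_store import days_between

from conftest import T0, StoreBuilder, days


# ---------------------------------------------------------------------------
# independent brute-force oracles: plain linear scans over the raw entity
# lists, sharing no code with the evaluators under test


def oracle_early_refill(store, patient_id, t_eval, config, index_rx_id=None) -> bool:
    for rx in store.prescriptions.values():
        if rx.patient_id != patient_id or rx.rx_id == index_rx_id:
            continue
        if rx.duration_days is None or rx.duration_days <= 0:
            continue
        elapsed = (t_eval - rx.written_at).total_seconds() / 86400.0
        if 0 <= elapsed < rx.duration_days:
            # same documented semantics: strictly above threshold, beyond
            # float representation noise
            if 1.0 - elapsed / rx.duration_days > config.remaining_fraction_threshold + 1e-12:
                return True
    return False


def oracle_ed_uc_onsite(store, patient_id, t_eval, config, index_encounter_id=None) -> bool:
    lo = t_eval - days(config.ed_uc_window_days)
    count = 0
    for enc in store.encounters.values():
        if enc.patient_id != patient_id or enc.encounter_id == index_encounter_id:
            continue
        if enc.facility_type not in (FacilityType.ED, FacilityType.URGENT_CARE):
            continue
        if enc.disposition == Disposition.ADMITTED:
            continue
        if not (lo <= enc.start_at < t_eval):
            continue
        if any(
            ma.encounter_id == enc.encounter_id and ma.drug_class == DrugClass.OPIOID
            for ma in store.med_admins
        ):
            count += 1
    return count >= config.min_ed_uc_visits


def oracle_rx_history(store, patient_id, t_eval, config, index_rx_id=None) -> bool:
    lo = t_eval - days(config.rx_window_days)
    n = sum(
        1
        for rx in store.prescriptions.values()
        if rx.patient_id == patient_id
        and rx.rx_id != index_rx_id
        and lo <= rx.written_at < t_eval
    )
    return n >= config.min_prescriptions


def oracle_overdose(store, patient_id, t_eval) -> bool:
    return any(
        e.patient_id == patient_id and e.is_overdose_presentation and e.start_at < t_eval
        for e in store.encounters.values()
    )


def oracle_tox(store, patient_id, t_eval) -> bool:
    return any(
        t.patient_id == patient_id and t.positive and t.collected_at < t_eval
        for t in store.tox_screens
    )


# ---------------------------------------------------------------------------
# early refill


class TestEarlyRefill:
    def test_worked_example_10_day_supply_3_days_elapsed(self, builder):
        """10-day supply written 3 days ago: 70% remains, so both the initial
        (>30%) and final (>50%) thresholds fire."""
        builder.encounter("E0", at=-3.0).rx("R0", "E0", duration=10.0)
        builder.encounter("E1", at=0.0).rx("R1", "E1")
        store = builder.build()
        for threshold in (0.30, 0.50):
            cfg = TriggerConfig(remaining_fraction_threshold=threshold)
            d = eval_early_refill(store, "P1", T0, cfg, index_rx_id="R1")
            assert d.met
            assert d.evidence[0]["rx_id"] == "R0"
            assert d.evidence[0]["remaining_fraction"] == pytest.approx(0.7)

    def test_no_prior_prescriptions(self, builder):
        store = builder.encounter("E1").rx("R1", "E1").build()
        d = eval_early_refill(store, "P1", T0, TriggerConfig(), index_rx_id="R1")
        assert not d.met and d.evidence == ()

    @pytest.mark.parametrize(
        "elapsed, threshold, expect",
        [
            (6.0, 0.50, False),  # 0.4 remaining, not > 0.5
            (4.0, 0.50, True),   # 0.6 remaining
            (5.0, 0.50, False),  # exactly 0.5: strict inequality
            (7.0, 0.30, False),  # exactly 0.3: strict inequality
            (10.0, 0.30, False), # supply exhausted, elapsed == duration
            (-1.0, 0.30, False), # future prescription never counts
        ],
    )
    def test_threshold_arithmetic(self, builder, elapsed, threshold, expect):
        builder.encounter("E0", at=-elapsed).rx("R0", "E0", duration=10.0)
        store = builder.build()
        cfg = TriggerConfig(remaining_fraction_threshold=threshold)
        assert eval_early_refill(store, "P1", T0, cfg).met is expect

    def test_missing_duration_skipped_with_warning(self, builder):
        builder.encounter("E0", at=-2.0).rx("R0", "E0", duration=None)
        store = builder.build()
        d = eval_early_refill(store, "P1", T0, TriggerConfig())
        assert not d.met
        assert any("R0" in w for w in d.warnings)

    def test_cross_class_prior_counts(self, builder):
        builder.encounter("E0", at=-2.0).rx("R0", "E0", drug="BENZODIAZEPINE", duration=10.0)
        store = builder.build()
        assert eval_early_refill(store, "P1", T0, TriggerConfig()).met

    def test_index_prescription_never_self_triggers(self, builder):
        store = builder.encounter("E1").rx("R1", "E1", duration=10.0).build()
        assert not eval_early_refill(store, "P1", T0, TriggerConfig(), index_rx_id="R1").met


# ---------------------------------------------------------------------------
# ED / urgent care onsite treatment


class TestEdUcOnsite:
    def test_no_prior_visits(self, builder):
        store = builder.build()
        assert not eval_ed_uc_onsite(store, "P1", T0, TriggerConfig()).met

    def test_two_qualifying_visits_meet_final_threshold(self, builder):
        builder.encounter("E1", at=-5.0, facility="ED").admin("E1")
        builder.encounter("E2", at=-20.0, facility="URGENT_CARE").admin("E2")
        store = builder.build()
        d = eval_ed_uc_onsite(store, "P1", T0, TriggerConfig(min_ed_uc_visits=2))
        assert d.met and len(d.evidence) == 2

    def test_admitted_visit_excluded(self, builder):
        builder.encounter("E1", at=-5.0, facility="ED").admin("E1")
        builder.encounter("E2", at=-20.0, facility="ED", disposition="ADMITTED").admin("E2")
        store = builder.build()
        assert not eval_ed_uc_onsite(store, "P1", T0, TriggerConfig(min_ed_uc_visits=2)).met

    def test_visit_without_opioid_admin_does_not_count(self, builder):
        builder.encounter("E1", at=-5.0, facility="ED").admin("E1", drug="OTHER")
        builder.encounter("E2", at=-20.0, facility="ED").admin("E2")
        store = builder.build()
        assert not eval_ed_uc_onsite(store, "P1", T0, TriggerConfig(min_ed_uc_visits=2)).met

    def test_window_boundaries(self, builder):
        # exactly 30 days back is inside [t-30d, t); the evaluation instant is not
        builder.encounter("E1", at=-30.0, facility="ED").admin("E1")
        builder.encounter("E2", at=0.0, facility="ED").admin("E2")
        store = builder.build()
        d = eval_ed_uc_onsite(store, "P1", T0, TriggerConfig(min_ed_uc_visits=1))
        assert d.met
        assert [e["encounter_id"] for e in d.evidence] == ["E1"]

    def test_index_encounter_excluded(self, builder):
        builder.encounter("E1", at=-5.0, facility="ED").admin("E1")
        store = builder.build()
        d = eval_ed_uc_onsite(
            store, "P1", T0, TriggerConfig(min_ed_uc_visits=1), index_encounter_id="E1"
        )
        assert not d.met


# ---------------------------------------------------------------------------
# 30-day prescription history


class TestRxHistory:
    def test_no_prior_prescriptions(self, builder):
        store = builder.build()
        assert not eval_rx_history(store, "P1", T0, TriggerConfig()).met

    def test_three_in_window_meets(self, builder):
        for i, off in enumerate((-1.0, -10.0, -29.0)):
            builder.encounter(f"E{i}", at=off).rx(f"R{i}", f"E{i}")
        store = builder.build()
        d = eval_rx_history(store, "P1", T0, TriggerConfig())
        assert d.met and len(d.evidence) == 3

    def test_boundary_rx_at_minus_31_days_not_counted(self, builder):
        for i, off in enumerate((-1.0, -10.0, -31.0)):
            builder.encounter(f"E{i}", at=off).rx(f"R{i}", f"E{i}")
        store = builder.build()
        d = eval_rx_history(store, "P1", T0, TriggerConfig())
        assert not d.met and len(d.evidence) == 2

    def test_both_classes_count_and_index_excluded(self, builder):
        builder.encounter("E0", at=-5.0).rx("R0", "E0", drug="BENZODIAZEPINE")
        builder.encounter("E1", at=-6.0).rx("R1", "E1")
        builder.encounter("E2", at=-7.0).rx("R2", "E2")
        builder.encounter("E3", at=0.0).rx("R3", "E3")
        store = builder.build()
        d = eval_rx_history(store, "P1", T0, TriggerConfig(), index_rx_id="R3")
        assert d.met
        assert {e["rx_id"] for e in d.evidence} == {"R0", "R1", "R2"}


# ---------------------------------------------------------------------------
# lifetime lookbacks


class TestLifetimeLookbacks:
    def test_overdose_400_days_prior_counts(self, builder):
        builder.encounter("E1", at=-400.0, facility="ED", overdose=True)
        store = builder.build()
        assert eval_overdose_history(store, "P1", T0).met

    def test_overdose_only_after_eval_does_not_count(self, builder):
        builder.encounter("E1", at=5.0, facility="ED", overdose=True)
        store = builder.build()
        assert not eval_overdose_history(store, "P1", T0).met

    def test_no_overdose(self, builder):
        store = builder.encounter("E1", at=-5.0).build()
        assert not eval_overdose_history(store, "P1", T0).met

    def test_all_negative_screens(self, builder):
        builder.tox(at=-100.0, positive=False).tox(at=-50.0, analyte="COCAINE", positive=False)
        store = builder.build()
        assert not eval_tox_screen(store, "P1", T0).met

    def test_positive_screen_two_years_prior(self, builder):
        store = builder.tox(at=-730.0).build()
        assert eval_tox_screen(store, "P1", T0).met

    def test_multiple_positive_analytes_all_in_evidence(self, builder):
        builder.tox(at=-30.0, analyte="BLOOD_ALCOHOL").tox(at=-20.0, analyte="COCAINE")
        store = builder.build()
        d = eval_tox_screen(store, "P1", T0)
        assert d.met
        assert {e["analyte"] for e in d.evidence} == {"BLOOD_ALCOHOL", "COCAINE"}


# ---------------------------------------------------------------------------
# composition


class TestEvaluateTriggers:
    def test_empty_history_meets_nothing(self, builder):
        store = builder.encounter("E1").rx("R1", "E1").build()
        result = evaluate_triggers(store, store.prescriptions["R1"], TriggerConfig())
        assert result.n_criteria_met == 0
        assert result.evaluated_at == T0

    def test_composed_fixture_exactly_two_flags(self, builder):
        builder.encounter("E0", at=-3.0).rx("R0", "E0", duration=10.0)
        builder.tox(at=-200.0)
        builder.encounter("E1", at=0.0).rx("R1", "E1")
        store = builder.build()
        result = evaluate_triggers(store, store.prescriptions["R1"], TriggerConfig())
        assert result.n_criteria_met == 2
        assert result.met_criteria == (Criterion.EARLY_REFILL, Criterion.TOX_SCREEN)

    def test_matches_independent_single_criterion_evaluations(self, medium_cohort, default_period):
        start, end = default_period
        cfg = TriggerConfig()
        checked = 0
        for rx in medium_cohort.prescriptions.values():
            if not (start <= rx.written_at < end):
                continue
            result = evaluate_triggers(medium_cohort, rx, cfg)
            t = rx.written_at
            singles = (
                eval_early_refill(medium_cohort, rx.patient_id, t, cfg, index_rx_id=rx.rx_id),
                eval_ed_uc_onsite(
                    medium_cohort, rx.patient_id, t, cfg, index_encounter_id=rx.encounter_id
                ),
                eval_rx_history(medium_cohort, rx.patient_id, t, cfg, index_rx_id=rx.rx_id),
                eval_overdose_history(medium_cohort, rx.patient_id, t),
                eval_tox_screen(medium_cohort, rx.patient_id, t),
            )
            assert result.details == singles
            checked += 1
        assert checked > 100

    def test_unknown_index_prescription_rejected(self, builder):
        store = builder.encounter("E1").rx("R1", "E1").build()
        import dataclasses
        ghost = dataclasses.replace(store.prescriptions["R1"], rx_id="R999")
        with pytest.raises(ValueError, match="R999"):
            evaluate_triggers(store, ghost, TriggerConfig())


# ---------------------------------------------------------------------------
# oracle equivalence and monotonicity on random cohorts


@pytest.fixture(scope="module")
def oracle_cohorts():
    """Three seeded cohorts totalling >= 1,000 patients for oracle checks."""
    return [generate_cohort(CohortConfig(n_patients=400, seed=s)) for s in (101, 202, 303)]


def test_evaluators_match_brute_force_oracles(oracle_cohorts):
    """Every evaluator agrees with a plain full-history scan at every
    prescription initiation across >= 1,000 random synthetic patients."""
    for cfg in (TriggerConfig(), INITIAL_TRIGGER_CONFIG):
        for store in oracle_cohorts:
            for rx in store.prescriptions.values():
                result = evaluate_triggers(store, rx, cfg)
                pid, t = rx.patient_id, rx.written_at
                expected = (
                    oracle_early_refill(store, pid, t, cfg, rx.rx_id),
                    oracle_ed_uc_onsite(store, pid, t, cfg, rx.encounter_id),
                    oracle_rx_history(store, pid, t, cfg, rx.rx_id),
                    oracle_overdose(store, pid, t),
                    oracle_tox(store, pid, t),
                )
                got = tuple(d.met for d in result.details)
                assert got == expected, f"{rx.rx_id}: {got} != oracle {expected}"


def test_threshold_monotonicity_on_fixed_store(medium_cohort):
    """Relaxing any threshold never unmeets a met criterion."""
    tight = TriggerConfig(remaining_fraction_threshold=0.50, min_ed_uc_visits=3,
                          min_prescriptions=4)
    loose = TriggerConfig(remaining_fraction_threshold=0.30, min_ed_uc_visits=2,
                          min_prescriptions=3)
    for rx in list(medium_cohort.prescriptions.values())[:800]:
        r_tight = evaluate_triggers(medium_cohort, rx, tight)
        r_loose = evaluate_triggers(medium_cohort, rx, loose)
        for d_tight, d_loose in zip(r_tight.details, r_loose.details):
            if d_tight.met:
                assert d_loose.met, f"{rx.rx_id} {d_tight.criterion} lost on relaxing"
        assert r_loose.n_criteria_met >= r_tight.n_criteria_met


@settings(max_examples=150, deadline=None)
@given(
    rx_offsets=st.lists(
        st.tuples(st.floats(-45, 0, allow_nan=False), st.floats(1, 30, allow_nan=False)),
        max_size=8,
    ),
    threshold=st.floats(0.05, 0.95, allow_nan=False),
)
def test_early_refill_property_random_histories(rx_offsets, threshold):
    """Early-refill decision equals the direct arithmetic on every history."""
    b = StoreBuilder().patient("P1")
    for i, (off, dur) in enumerate(rx_offsets):
        b.encounter(f"E{i}", at=off).rx(f"R{i}", f"E{i}", duration=dur)
    store = b.build()
    cfg = TriggerConfig(remaining_fraction_threshold=threshold)
    got = eval_early_refill(store, "P1", T0, cfg)
    assert got.met == oracle_early_refill(store, "P1", T0, cfg)
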