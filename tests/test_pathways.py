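"""Stock-and-flow engine: builders, integration, gate, resource accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stepcare.params import ConfigError
from stepcare.pathways import (
    TERMINAL,
    PathwayConfig,
    PathwayModel,
    StageSpec,
    build_mild_pathway,
    build_moderate_pathway,
    build_pathways,
    build_severe_pathway,
    coverage_gate,
    enumerate_paths,
    expected_resources_per_entrant,
)

SPECIALIST_STAGES = {"inpatient", "cmht_intake", "cmht_followup", "crhtt"}


def drain(model: PathwayModel, weeks: int = 4000, dt: float = 1.0) -> None:
    for _ in range(int(weeks / dt)):
        model.integrate_step(entry_inflow=0.0, dt=dt)


class TestBuilders:
    def test_mild_is_outpatient_only(self):
        model = build_mild_pathway()
        assert set(model.stages) == {"gp_assessment", "medication", "therapy", "gp_followup"}
        assert not (set(model.stages) & SPECIALIST_STAGES)

    def test_moderate_adds_psychiatrist_but_no_inpatient(self):
        model = build_moderate_pathway()
        assert "psychiatrist_med" in model.stages
        assert not (set(model.stages) & SPECIALIST_STAGES)

    def test_severe_contains_inpatient_cmht_crhtt(self):
        model = build_severe_pathway()
        assert SPECIALIST_STAGES <= set(model.stages)
        assert model.crisis_entry_stage == "crhtt"

    def test_full_remission_leaves_downstream_empty(self):
        model = build_mild_pathway(PathwayConfig(remit_fraction=1.0))
        for _ in range(300):
            model.integrate_step(entry_inflow=1.0)
        for stage in ("medication", "therapy", "gp_followup"):
            assert model.levels[stage] == pytest.approx(0.0, abs=1e-12)
        # everyone ends up awaiting discharge (minus what is still assessed)
        assert model.levels[TERMINAL] > 0

    def test_zero_escalation_reduces_moderate_to_mild_plus_final_visit(self):
        cfg = PathwayConfig(remit_fraction=0.6, escalate_fraction=0.0)
        model = build_moderate_pathway(cfg)
        per_entrant = expected_resources_per_entrant(model)
        mild = expected_resources_per_entrant(build_mild_pathway(PathwayConfig(remit_fraction=0.6)))
        # same route plus exactly one extra GP visit for the final evaluation
        persist = 1 - 0.6
        assert per_entrant["gp"] == pytest.approx(mild["gp"] + persist * 1.0)
        assert per_entrant["psychiatrist"] == 0.0

    def test_medication_path_gp_visits_sum(self):
        """A full medication-path traversal accrues 4 + 6 + 1 GP visits."""
        cfg = PathwayConfig(remit_fraction=0.0, medication_fraction=1.0)
        model = build_mild_pathway(cfg)
        per_entrant = expected_resources_per_entrant(model)
        assert per_entrant["gp"] == pytest.approx(11.0)
        assert per_entrant["medication"] == pytest.approx(1.0)

    def test_psychiatrist_branch_accrues_psychiatrist_visits(self):
        cfg = PathwayConfig(remit_fraction=0.0, escalate_fraction=1.0, psychiatrist_fraction=1.0)
        per_entrant = expected_resources_per_entrant(build_moderate_pathway(cfg))
        assert per_entrant["psychiatrist"] >= 1.0

    def test_bad_branch_fractions_fail_fast(self):
        with pytest.raises(ConfigError):
            StageSpec("s", 4.0, {"a": 0.5, "b": 0.4})
        with pytest.raises(ConfigError):
            PathwayConfig(remit_fraction=1.3)

    def test_disconnected_graph_rejected(self):
        with pytest.raises(ConfigError):
            PathwayModel(
                "mild",
                {"loop": StageSpec("loop", 4.0, {"loop2": 1.0}),
                 "loop2": StageSpec("loop2", 4.0, {"loop": 1.0})},
                {"loop": 1.0},
            )


class TestIntegrateStep:
    def test_printed_difference_equation(self):
        """d(Stock)/dt = inflow - outflow: 10 + (5 - 2) * 1 = 13."""
        model = PathwayModel(
            "mild", {"s": StageSpec("s", 5.0, {TERMINAL: 1.0})}, {"s": 1.0}
        )
        model.levels["s"] = 10.0
        model.integrate_step(entry_inflow=5.0, dt=1.0)
        assert model.levels["s"] == pytest.approx(10.0 + 5.0 - 10.0 / 5.0)

    def test_first_order_outflow_rate(self):
        """A stock of 46 with mean stage duration 46 weeks drains 1 person/week."""
        model = PathwayModel(
            "mild", {"s": StageSpec("s", 46.0, {TERMINAL: 1.0})}, {"s": 1.0}
        )
        model.levels["s"] = 46.0
        model.integrate_step(entry_inflow=0.0, dt=1.0)
        assert model.levels["s"] == pytest.approx(45.0)
        assert model.levels[TERMINAL] == pytest.approx(1.0)

    @pytest.mark.parametrize("dt", [1.0, 0.5, 0.1, 0.01])
    def test_decay_matches_closed_form(self, dt):
        """Zero-inflow decay follows L0 (1 - dt/D)^(t/dt), -> L0 e^(-t/D) as dt -> 0."""
        D, L0, t = 12.0, 100.0, 24.0
        model = PathwayModel(
            "mild", {"s": StageSpec("s", D, {TERMINAL: 1.0})}, {"s": 1.0}
        )
        model.levels["s"] = L0
        for _ in range(int(round(t / dt))):
            model.integrate_step(entry_inflow=0.0, dt=dt)
        assert model.levels["s"] == pytest.approx(L0 * (1 - dt / D) ** (t / dt), rel=1e-9)
        if dt <= 0.01:
            assert model.levels["s"] == pytest.approx(L0 * math.exp(-t / D), rel=2e-3)

    def test_outflow_clamped_at_stock(self):
        model = PathwayModel(
            "mild", {"s": StageSpec("s", 0.5, {TERMINAL: 1.0})}, {"s": 1.0}
        )
        model.levels["s"] = 3.0
        model.integrate_step(entry_inflow=0.0, dt=1.0)  # rate L/0.5 would overdrain
        assert model.levels["s"] == pytest.approx(0.0)
        assert model.levels[TERMINAL] == pytest.approx(3.0)

    def test_negative_inflow_fails_fast(self):
        model = build_mild_pathway()
        with pytest.raises(ConfigError):
            model.integrate_step(entry_inflow=-1.0)
        with pytest.raises(ConfigError):
            model.integrate_step(entry_inflow=0.0, dt=0.0)

    def test_inpatient_occupancy_accrues_level_times_dt(self):
        model = build_severe_pathway()
        model.levels["inpatient"] = 10.0
        before = model.ledger["inpatient_weeks"]
        model.integrate_step(entry_inflow=0.0, dt=1.0)
        # one week at (almost) level 10: the Euler update drains 10/8 first
        expected_level = 10.0 - 10.0 / 8.0
        assert model.ledger["inpatient_weeks"] - before == pytest.approx(expected_level)

    def test_euler_refinement_stable_under_dt_halving(self):
        """Halving dt changes the 104-week trajectories by well under 2%."""
        masses = {}
        gp = {}
        for dt in (1.0, 0.5):
            model = build_moderate_pathway()
            traj = []
            for _ in range(int(104 / dt)):
                model.integrate_step(entry_inflow=2.0, dt=dt)
                traj.append(model.total_mass)
            masses[dt] = np.array(traj[:: int(1 / dt)] if dt < 1 else traj)
            gp[dt] = model.ledger["gp"]
        rel = np.abs(masses[1.0] - masses[0.5]) / masses[0.5].max()
        assert rel.max() < 0.02
        assert gp[1.0] == pytest.approx(gp[0.5], rel=0.02)


class TestMassBalanceAndLedger:
    @pytest.mark.parametrize("builder", [build_mild_pathway, build_moderate_pathway, build_severe_pathway])
    def test_mass_balance_exact_under_random_driving(self, builder, rng):
        model = builder()
        for week in range(200):
            inflow = float(rng.integers(0, 5))
            crisis = float(rng.integers(0, 2)) if model.crisis_entry_stage else 0.0
            model.integrate_step(entry_inflow=inflow, crisis_inflow=crisis)
            if week % 3 == 0 and model.total_mass > 1:
                model.remove_discharges(1.0)
            assert model.mass_balance_error() < 1e-6
            assert all(l >= 0 for l in model.levels.values())

    def test_ledger_nonnegative_and_nondecreasing(self, rng):
        model = build_severe_pathway()
        last = dict(model.ledger)
        for _ in range(100):
            model.integrate_step(entry_inflow=float(rng.random() * 3), crisis_inflow=0.5)
            for svc, units in model.ledger.items():
                assert units >= last[svc] >= 0
            last = dict(model.ledger)

    @pytest.mark.parametrize("builder", [build_mild_pathway, build_moderate_pathway, build_severe_pathway])
    def test_unit_cohort_ledger_matches_path_enumeration(self, builder):
        """Integrated resource use equals the branch-weighted path sums."""
        model = builder()
        model.integrate_step(entry_inflow=1.0, dt=1.0)
        drain(model, weeks=6000)
        assert model.levels[TERMINAL] == pytest.approx(1.0, abs=1e-6)
        expected = expected_resources_per_entrant(model)
        for svc, units in expected.items():
            if svc == "inpatient_weeks":
                continue
            assert model.ledger[svc] == pytest.approx(units, abs=1e-6), svc

    def test_unit_cohort_inpatient_weeks_equals_prob_times_stay(self):
        model = build_severe_pathway()
        paths = enumerate_paths(model)
        p_inpatient = sum(prob for trail, prob in paths if "inpatient" in trail)
        model.integrate_step(entry_inflow=1.0, dt=1.0)
        drain(model, weeks=6000)
        assert model.ledger["inpatient_weeks"] == pytest.approx(
            p_inpatient * model.stages["inpatient"].mean_duration_weeks, rel=1e-4
        )

    def test_no_initial_or_emergency_admissions_means_no_inpatient(self):
        cfg = PathwayConfig(remit_fraction=0.2, initial_inpatient_fraction=0.0, crisis_fraction=0.0)
        model = build_severe_pathway(cfg)
        for _ in range(300):
            model.integrate_step(entry_inflow=2.0)
        assert model.ledger["inpatient_weeks"] == pytest.approx(0.0, abs=1e-12)
        assert model.levels["inpatient"] == pytest.approx(0.0, abs=1e-12)

    def test_path_probabilities_sum_to_one(self):
        for builder in (build_mild_pathway, build_moderate_pathway, build_severe_pathway):
            total = sum(p for _, p in enumerate_paths(builder()))
            assert total == pytest.approx(1.0, abs=1e-12)


class TestCoverageGate:
    @pytest.mark.parametrize(
        "demand, coverage, expected",
        [(100.0, 0.47, (47.0, 53.0)), (385.0, 0.80, (308.0, 77.0)), (7.0, 0.0, (0.0, 7.0)), (12.0, 1.0, (12.0, 0.0))],
    )
    def test_known_splits(self, demand, coverage, expected):
        entering, not_entering = coverage_gate(demand, coverage)
        assert entering == pytest.approx(expected[0], abs=1e-9)
        assert not_entering == pytest.approx(expected[1], abs=1e-9)

    @given(
        demand=st.floats(min_value=0, max_value=1e6),
        coverage=st.floats(min_value=0, max_value=1),
    )
    @settings(deadline=None, derandomize=True)
    def test_split_partitions_demand(self, demand, coverage):
        entering, not_entering = coverage_gate(demand, coverage)
        assert entering >= 0 and not_entering >= 0
        assert entering + not_entering == pytest.approx(demand, rel=1e-12, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            coverage_gate(-1.0, 0.5)
        with pytest.raises(ConfigError):
            coverage_gate(1.0, 1.5)


def test_default_pathway_set_respects_stepped_care_structure():
    models = build_pathways()
    assert set(models) == {"mild", "moderate", "severe"}
    assert not (set(models["mild"].stages) & SPECIALIST_STAGES)
    assert not (set(models["moderate"].stages) & SPECIALIST_STAGES)
    assert SPECIALIST_STAGES <= set(models["severe"].stages)
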