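"""Unit and property tests for the agent-level weekly transitions."""

import numpy as np
import pytest
from scipy import stats

from stepcare import abm
from stepcare.abm import Agent, snapshot_counts
from stepcare.params import (
    Care,
    ContractError,
    ConfigError,
    DiseaseParams,
    Health,
    WeeklyHazards,
)


@pytest.fixture()
def params():
    return DiseaseParams(n0=100)


@pytest.fixture()
def hz(params):
    return WeeklyHazards.from_params(params)


def make_agent(health=Health.MILD, care=Care.UNTREATED, **kw) -> Agent:
    return Agent(id=0, health=health, care=care, **kw)


class TestInitPopulation:
    def test_all_healthy_and_sized(self):
        params = DiseaseParams(n0=5000)
        agents, _ = abm.init_population(params, seed=1)
        assert len(agents) == 5000
        assert all(a.alive and a.health is Health.NONE for a in agents)

    def test_minimal_population(self):
        agents, _ = abm.init_population(DiseaseParams(n0=1), seed=99)
        assert len(agents) == 1

    def test_seeded_determinism(self):
        p = DiseaseParams(n0=10)
        a1, r1 = abm.init_population(p, seed=7)
        a2, r2 = abm.init_population(p, seed=7)
        assert [a.id for a in a1] == [a.id for a in a2]
        assert r1.random() == r2.random()

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ConfigError):
            DiseaseParams(n0=0)


class TestWeeklyOnset:
    def test_severity_split_matches_proportions(self, rng):
        """Incident severities follow the supplied multinomial split."""
        agents = [Agent(id=i) for i in range(30000)]
        cases = abm.weekly_onset(agents, 0.5, (0.294, 0.388, 0.318), rng)
        counts = np.array(
            [sum(1 for _, s in cases if s == h) for h in (Health.MILD, Health.MODERATE, Health.SEVERE)]
        )
        assert counts.sum() == len(cases) >= 10000
        expected = np.array([0.294, 0.388, 0.318]) * counts.sum()
        _, pval = stats.chisquare(counts, expected)
        assert pval > 0.01

    def test_zero_hazard_no_cases(self, rng):
        agents = [Agent(id=i) for i in range(100)]
        assert abm.weekly_onset(agents, 0.0, (0.294, 0.388, 0.318), rng) == []

    def test_degenerate_split_all_mild(self, rng):
        agents = [Agent(id=i) for i in range(500)]
        cases = abm.weekly_onset(agents, 1.0, (1.0, 0.0, 0.0), rng)
        assert len(cases) == 500
        assert all(s is Health.MILD for _, s in cases)


class TestStepUntreated:
    def test_severe_cannot_deteriorate(self, params, rng):
        hz = WeeklyHazards(
            death=0.0, remission=(0, 0, 0), deterioration=(1.0, 1.0, 0.0),
            relapse_treated=0, relapse_untreated=0,
            relapse_delay_weeks=26, relapse_window_weeks=52, emergency=0,
        )
        agent = make_agent(Health.SEVERE)
        events = abm.step_untreated(agent, hz, rng)
        assert events == [] and agent.health is Health.SEVERE

    def test_zero_hazards_only_clock_advances(self, params, rng):
        agent = make_agent(Health.MILD)
        events = abm.step_untreated(agent, WeeklyHazards.zeroed(params), rng)
        assert events == []
        assert agent.weeks_in_state == 1 and agent.care is Care.UNTREATED

    def test_deterioration_opens_fresh_offer(self, params, rng):
        hz = WeeklyHazards(
            death=0.0, remission=(0, 0, 0), deterioration=(1.0, 1.0, 0.0),
            relapse_treated=0, relapse_untreated=0,
            relapse_delay_weeks=26, relapse_window_weeks=52, emergency=0,
        )
        agent = make_agent(Health.MILD, offered=True)
        (event,) = abm.step_untreated(agent, hz, rng)
        assert event.kind == abm.DETERIORATION
        assert (event.severity, event.to_severity) == (0, 1)
        assert agent.health is Health.MODERATE and not agent.offered

    def test_remission_starts_recurrence_clock(self, params, rng):
        hz = WeeklyHazards(
            death=0.0, remission=(1.0, 1.0, 1.0), deterioration=(0, 0, 0),
            relapse_treated=0, relapse_untreated=0,
            relapse_delay_weeks=26, relapse_window_weeks=52, emergency=0,
        )
        agent = make_agent(Health.MODERATE)
        (event,) = abm.step_untreated(agent, hz, rng)
        assert event.kind == abm.REMISSION
        assert agent.health is Health.NONE
        assert agent.last_episode_treated is False
        assert agent.weeks_since_episode == 0
        assert agent.prior_severity is Health.MODERATE

    def test_contract_violations(self, hz, rng):
        with pytest.raises(ContractError):
            abm.step_untreated(make_agent(Health.NONE, Care.NOT_APPLICABLE), hz, rng)
        with pytest.raises(ContractError):
            abm.step_untreated(make_agent(Health.MILD, Care.IN_TREATMENT), hz, rng)


class TestAdmissionAndTreatment:
    def test_duration_draws_within_triangular_support(self, params, rng):
        for sev, (lo, hi) in enumerate([(4, 52), (4, 56), (26, 76)]):
            draws = [abm.draw_treatment_weeks(params, sev, rng) for _ in range(2000)]
            assert min(draws) >= lo and max(draws) <= hi

    def test_mean_duration_close_to_analytic_triangular_mean(self, params, rng):
        # ceiling to whole weeks adds ~0.5 on top of (4+26+52)/3
        draws = [abm.draw_treatment_weeks(params, 0, rng) for _ in range(20000)]
        assert np.mean(draws) == pytest.approx(27.33 + 0.5, abs=0.3)

    def test_degenerate_triangular_exact(self, rng):
        p = DiseaseParams(treatment_duration=[(26, 26, 26), (4, 26, 56), (26, 52, 76)])
        assert abm.draw_treatment_weeks(p, 0, rng) == 26

    def test_admit_schedules_discharge(self, params, rng):
        agent = make_agent(Health.SEVERE)
        weeks = abm.admit_to_treatment(agent, params, current_week=10, rng=rng)
        assert agent.care is Care.IN_TREATMENT
        assert agent.treatment_end_week == 10 + weeks
        assert 26 <= weeks <= 76

    def test_admitting_healthy_agent_fails(self, params, rng):
        with pytest.raises(ContractError):
            abm.admit_to_treatment(make_agent(Health.NONE, Care.NOT_APPLICABLE), params, 0, rng)

    def test_mid_treatment_week_is_inert(self, params, rng):
        hz = WeeklyHazards.zeroed(params)
        agent = make_agent(Health.MILD, Care.IN_TREATMENT, treatment_end_week=9)
        assert abm.step_in_treatment(agent, params, hz, current_week=5, rng=rng) == []
        assert agent.care is Care.IN_TREATMENT

    def test_certain_recovery_at_discharge(self, rng):
        p = DiseaseParams(recovery_treated=(1.0, 1.0, 1.0))
        hz = WeeklyHazards.zeroed(p)
        agent = make_agent(Health.MILD, Care.IN_TREATMENT, treatment_end_week=5)
        events = abm.step_in_treatment(agent, p, hz, current_week=5, rng=rng)
        assert [e.kind for e in events] == [abm.DISCHARGE, abm.RECOVERY]
        assert agent.health is Health.NONE and agent.care is Care.DISCHARGED
        assert agent.last_episode_treated is True

    def test_recovered_fraction_matches_probability(self, params, rng):
        """Across many discharges the recovered share tracks the mild recovery probability."""
        hz = WeeklyHazards.zeroed(params)
        recovered = 0
        n = 10000
        for _ in range(n):
            agent = make_agent(Health.MILD, Care.IN_TREATMENT, treatment_end_week=0)
            events = abm.step_in_treatment(agent, params, hz, current_week=0, rng=rng)
            recovered += events[-1].kind == abm.RECOVERY
        assert recovered / n == pytest.approx(0.793, abs=0.01)

    def test_failed_discharge_returns_to_untreated(self, rng):
        p = DiseaseParams(recovery_treated=(0.0, 0.0, 0.0))
        hz = WeeklyHazards.zeroed(p)
        agent = make_agent(Health.MODERATE, Care.IN_TREATMENT, treatment_end_week=3, offered=True)
        events = abm.step_in_treatment(agent, p, hz, current_week=3, rng=rng)
        assert [e.kind for e in events] == [abm.DISCHARGE, abm.TREATMENT_FAILURE]
        assert agent.care is Care.UNTREATED and agent.health is Health.MODERATE
        assert not agent.offered  # a continuing episode gets a fresh offer

    def test_missing_schedule_is_contract_violation(self, params, hz, rng):
        agent = make_agent(Health.MILD, Care.IN_TREATMENT, treatment_end_week=None)
        with pytest.raises(ContractError):
            abm.step_in_treatment(agent, params, hz, 0, rng)


class TestStepRecovered:
    def recovered_agent(self, treated: bool, weeks: int) -> Agent:
        return Agent(
            id=0, health=Health.NONE,
            care=Care.DISCHARGED if treated else Care.NOT_APPLICABLE,
            last_episode_treated=treated, weeks_since_episode=weeks,
            prior_severity=Health.MODERATE,
        )

    def test_no_relapse_during_delay(self, rng):
        p = DiseaseParams(recurrence_untreated=0.999999, relapse_treated=0.999999)
        hz = WeeklyHazards.from_params(p)
        agent = self.recovered_agent(treated=False, weeks=0)
        for _ in range(int(p.relapse_delay_weeks)):
            assert abm.step_recovered(agent, hz, rng) == []
        assert agent.health is Health.NONE

    def test_zero_hazard_never_relapses_and_window_expires(self, params, rng):
        hz = WeeklyHazards.zeroed(params)
        agent = self.recovered_agent(treated=True, weeks=0)
        for _ in range(60):
            assert abm.step_recovered(agent, hz, rng) == [] or agent.weeks_since_episode is None
            if agent.weeks_since_episode is None:
                break
        assert agent.weeks_since_episode is None  # rejoined susceptible pool
        assert agent.care is Care.NOT_APPLICABLE

    def test_relapse_reenters_at_prior_severity(self, rng):
        p = DiseaseParams(recurrence_untreated=0.999999)
        hz = WeeklyHazards.from_params(p)
        agent = self.recovered_agent(treated=False, weeks=int(p.relapse_delay_weeks))
        (event,) = abm.step_recovered(agent, hz, rng)
        assert event.kind == abm.RELAPSE
        assert event.prior_treated is False and event.severity == 1
        assert agent.health is Health.MODERATE and agent.care is Care.UNTREATED

    def test_treated_vs_untreated_hazard_ratio(self, hz):
        """Relapse hazards reflect the printed 14% vs 33% per-episode risks."""
        active = 52 - 26
        expected_ratio = (1 - (1 - 0.14) ** (1 / active)) / (1 - (1 - 0.33) ** (1 / active))
        assert hz.relapse_treated / hz.relapse_untreated == pytest.approx(expected_ratio, rel=1e-9)

    def test_missing_history_is_contract_violation(self, hz, rng):
        with pytest.raises(ContractError):
            abm.step_recovered(Agent(id=0), hz, rng)


class TestSnapshotCounts:
    def test_fresh_population_all_healthy(self):
        agents, _ = abm.init_population(DiseaseParams(n0=42), seed=0)
        sc = snapshot_counts(agents)
        assert sc.healthy == 42 and sc.counts.sum() == 0 and sc.deaths == 0
        assert sc.total == 42

    def test_forced_states_are_tallied(self):
        agents, _ = abm.init_population(DiseaseParams(n0=10), seed=0)
        for a in agents[:3]:
            a.health, a.care = Health.MILD, Care.UNTREATED
        agents[3].alive = False
        sc = snapshot_counts(agents)
        assert sc.counts[0, 0] == 3
        assert sc.deaths == 1
        assert sc.healthy == 6
        assert sc.total == 10

    def test_discharged_window_counted_by_prior_severity(self):
        agents, _ = abm.init_population(DiseaseParams(n0=5), seed=0)
        a = agents[0]
        a.care = Care.DISCHARGED
        a.weeks_since_episode = 3
        a.prior_severity = Health.SEVERE
        a.last_episode_treated = True
        sc = snapshot_counts(agents)
        assert sc.counts[2, 2] == 1 and sc.prevalent(2) == 0
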