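"""Discrete-time (weekly) agent-based model of depression progression.

Each agent is an adult who can be disease-free or have mild, moderate, or
severe depression, and — while ill — be untreated or in treatment. Weekly
transitions cover onset, deterioration (mild->moderate->severe, untreated
only), remission without treatment, scheduled discharge with probabilistic
recovery, recurrence/relapse after an episode, and all-cause death. There is
no direct agent–agent interaction; agents interact only through the shared
care system (the coupling layer decides who enters treatment).

Within a week, competing risks are resolved in a fixed order — death, then
remission/discharge, then deterioration/relapse — each applied to the
survivors of the previous draw. Weekly hazards are far below one, so the
ordering bias is negligible, and the fixed order makes runs exactly
reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .params import (
    Care,
    ConfigError,
    ContractError,
    DiseaseParams,
    Health,
    SEVERITIES,
    WeeklyHazards,
)

__all__ = [
    "Agent",
    "Event",
    "StateCounts",
    "init_population",
    "weekly_onset",
    "step_untreated",
    "admit_to_treatment",
    "step_in_treatment",
    "step_recovered",
    "step_healthy",
    "snapshot_counts",
    "draw_treatment_weeks",
]

# event kinds emitted by the step operations
ONSET = "onset"
DEATH = "death"
REMISSION = "remission"
DETERIORATION = "deterioration"
ADMISSION = "admission"
EMERGENCY_ADMISSION = "emergency_admission"
DISCHARGE = "discharge"
RECOVERY = "recovery"
TREATMENT_FAILURE = "treatment_failure"
RELAPSE = "relapse"


@dataclass(frozen=True)
class Event:
    """One typed event from the weekly update, for the outcome counters.

    ``severity`` is the severity index (0 mild, 1 moderate, 2 severe) the
    event refers to; for deterioration it is the *origin* state and
    ``to_severity`` the destination. ``prior_treated`` tags relapse events
    with whether the preceding episode was treated.
    """

    kind: str
    severity: int
    to_severity: Optional[int] = None
    prior_treated: Optional[bool] = None


@dataclass
class Agent:
    """One individual's health state, care state, timers and episode memory."""

    id: int
    health: Health = Health.NONE
    care: Care = Care.NOT_APPLICABLE
    weeks_in_state: int = 0
    treatment_end_week: Optional[int] = None
    last_episode_treated: Optional[bool] = None
    weeks_since_episode: Optional[int] = None
    prior_severity: Optional[Health] = None
    offered: bool = False
    alive: bool = True

    @property
    def symptomatic(self) -> bool:
        return self.alive and self.health is not Health.NONE

    @property
    def in_relapse_window(self) -> bool:
        return self.alive and self.health is Health.NONE and self.weeks_since_episode is not None


def init_population(params: DiseaseParams, seed: int) -> tuple[list[Agent], np.random.Generator]:
    """Create the initial disease-free population and its RNG stream.

    Returns ``n0`` alive, healthy agents plus a PCG64 generator seeded from
    ``seed`` (the single source of randomness for a replication).
    """
    n0 = int(params.n0)
    if n0 < 1:
        raise ConfigError(f"population size must be positive, got {params.n0}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    return [Agent(id=i) for i in range(n0)], rng


def weekly_onset(
    healthy_agents: Iterable[Agent],
    onset_hazard: float,
    severity_props: tuple[float, float, float],
    rng: np.random.Generator,
) -> list[tuple[Agent, Health]]:
    """Draw this week's incident cases among disease-free agents.

    Each agent independently develops depression with probability
    ``onset_hazard``; severity is drawn from ``severity_props``. New cases
    become untreated and await the coupling decision (``offered`` is False).
    """
    if not 0.0 <= onset_hazard <= 1.0:
        raise ConfigError(f"onset hazard must be in [0, 1], got {onset_hazard}")
    total = float(sum(severity_props))
    if total <= 0 and onset_hazard > 0:
        raise ConfigError("severity proportions must have positive mass")
    cum = np.cumsum(severity_props) / total if onset_hazard > 0 else None
    new_cases: list[tuple[Agent, Health]] = []
    for agent in healthy_agents:
        if onset_hazard == 0.0:
            break
        if rng.random() < onset_hazard:
            sev = Health(int(np.searchsorted(cum, rng.random(), side="right")) + 1)
            agent.health = sev
            agent.care = Care.UNTREATED
            agent.weeks_in_state = 0
            agent.offered = False
            agent.weeks_since_episode = None
            new_cases.append((agent, sev))
    return new_cases


def step_healthy(agent: Agent, hz: WeeklyHazards, rng: np.random.Generator) -> list[Event]:
    """Death draw for a disease-free agent with no recent episode."""
    if not agent.alive or agent.health is not Health.NONE:
        raise ContractError("step_healthy requires an alive, disease-free agent")
    if hz.death > 0 and rng.random() < hz.death:
        agent.alive = False
        return [Event(DEATH, -1)]
    return []


def step_untreated(agent: Agent, hz: WeeklyHazards, rng: np.random.Generator) -> list[Event]:
    """One week for an untreated symptomatic agent.

    Applies, in order, the weekly hazards of death, remission (episode ends
    untreated, recurrence clock starts) and deterioration (one severity step
    up; severe cannot deteriorate). Deterioration is treated as the start of
    a new, more severe episode, so the agent becomes eligible for a fresh
    service offer.
    """
    if not agent.alive or agent.health is Health.NONE or agent.care is not Care.UNTREATED:
        raise ContractError("step_untreated requires an alive, untreated, symptomatic agent")
    sev = agent.health.severity_index
    if hz.death > 0 and rng.random() < hz.death:
        agent.alive = False
        return [Event(DEATH, sev)]
    if hz.remission[sev] > 0 and rng.random() < hz.remission[sev]:
        _end_episode(agent, treated=False)
        return [Event(REMISSION, sev)]
    det = hz.deterioration[sev]
    if det > 0 and rng.random() < det:
        agent.health = Health(int(agent.health) + 1)
        agent.weeks_in_state = 0
        agent.offered = False  # a new, more severe episode: fresh offer
        return [Event(DETERIORATION, sev, to_severity=sev + 1)]
    agent.weeks_in_state += 1
    return []


def draw_treatment_weeks(params: DiseaseParams, severity: int, rng: np.random.Generator) -> int:
    """Whole-week treatment duration: ceiling of a severity-specific triangular draw."""
    tri = params.treatment_duration[severity]
    if tri.minimum == tri.maximum:
        return max(1, math.ceil(tri.minimum))
    return max(1, math.ceil(rng.triangular(tri.minimum, tri.mode, tri.maximum)))


def admit_to_treatment(
    agent: Agent,
    params: DiseaseParams,
    current_week: int,
    rng: np.random.Generator,
) -> int:
    """Move an untreated agent into treatment; returns the drawn duration in weeks.

    The discharge week is ``current_week + ceil(Triangular(min, mode, max))``
    with severity-specific parameters.
    """
    if not agent.alive or agent.health is Health.NONE:
        raise ContractError("cannot admit a disease-free agent to treatment")
    if agent.care is not Care.UNTREATED:
        raise ContractError("only untreated agents can be admitted")
    weeks = draw_treatment_weeks(params, agent.health.severity_index, rng)
    agent.care = Care.IN_TREATMENT
    agent.treatment_end_week = current_week + weeks
    agent.weeks_in_state = 0
    agent.offered = True
    return weeks


def step_in_treatment(
    agent: Agent,
    params: DiseaseParams,
    hz: WeeklyHazards,
    current_week: int,
    rng: np.random.Generator,
) -> list[Event]:
    """One week for an agent in treatment.

    The death hazard applies throughout. At the scheduled discharge week the
    agent leaves treatment: with the severity-specific recovery probability
    the episode ends (disease-free, relapse clock starts); otherwise
    treatment was unsuccessful and the agent returns to the untreated pool at
    unchanged severity, eligible for a fresh offer through the coverage gate.
    """
    if agent.care is not Care.IN_TREATMENT:
        raise ContractError("step_in_treatment requires an agent in treatment")
    if agent.treatment_end_week is None:
        raise ContractError("agent in treatment has no scheduled discharge week")
    sev = agent.health.severity_index
    if hz.death > 0 and rng.random() < hz.death:
        agent.alive = False
        return [Event(DEATH, sev)]
    if current_week < agent.treatment_end_week:
        agent.weeks_in_state += 1
        return []
    events = [Event(DISCHARGE, sev)]
    agent.treatment_end_week = None
    if rng.random() < params.recovery_treated[sev]:
        _end_episode(agent, treated=True)
        events.append(Event(RECOVERY, sev))
    else:
        agent.care = Care.UNTREATED
        agent.weeks_in_state = 0
        agent.offered = False
        events.append(Event(TREATMENT_FAILURE, sev))
    return events


def step_recovered(agent: Agent, hz: WeeklyHazards, rng: np.random.Generator) -> list[Event]:
    """One week for a disease-free agent within the recurrence window.

    No risk for the first ``relapse_delay_weeks`` after the episode ends;
    then a weekly hazard (relapse if the episode was treated, recurrence if
    not) until the window closes, after which the agent rejoins the fully
    susceptible pool. On relapse the agent re-enters the untreated pool at
    its prior severity.
    """
    if not agent.in_relapse_window:
        raise ContractError("step_recovered requires a recent resolved episode")
    if agent.prior_severity is None or agent.last_episode_treated is None:
        raise ContractError("agent has no recorded prior episode")
    sev = agent.prior_severity.severity_index
    if hz.death > 0 and rng.random() < hz.death:
        agent.alive = False
        return [Event(DEATH, -1)]
    agent.weeks_since_episode += 1
    if agent.weeks_since_episode > hz.relapse_window_weeks:
        # recurrence risk has resolved; back to the susceptible pool
        agent.care = Care.NOT_APPLICABLE
        agent.weeks_since_episode = None
        agent.prior_severity = None
        agent.last_episode_treated = None
        return []
    if agent.weeks_since_episode <= hz.relapse_delay_weeks:
        return []
    hazard = hz.relapse_treated if agent.last_episode_treated else hz.relapse_untreated
    if hazard > 0 and rng.random() < hazard:
        prior_treated = agent.last_episode_treated
        agent.health = agent.prior_severity
        agent.care = Care.UNTREATED
        agent.weeks_in_state = 0
        agent.offered = False
        agent.weeks_since_episode = None
        agent.prior_severity = None
        agent.last_episode_treated = None
        return [Event(RELAPSE, sev, prior_treated=prior_treated)]
    return []


def _end_episode(agent: Agent, treated: bool) -> None:
    agent.prior_severity = agent.health
    agent.health = Health.NONE
    agent.care = Care.DISCHARGED if treated else Care.NOT_APPLICABLE
    agent.last_episode_treated = treated
    agent.weeks_since_episode = 0
    agent.weeks_in_state = 0
    agent.treatment_end_week = None


@dataclass
class StateCounts:
    """Exact tally of the population by (severity, care) at one week.

    ``counts[i, j]`` holds severity ``i`` (mild, moderate, severe) in care
    state ``j`` (untreated, in treatment, discharged-recovered); the
    discharged column counts disease-free agents still inside the relapse
    window after a *treated* episode, tagged by their prior severity.
    ``healthy`` is everyone else alive and disease-free. The closed
    population satisfies ``healthy + counts.sum() + deaths == n0``.
    """

    healthy: int
    counts: np.ndarray  # shape (3 severities, 3 care states), ints
    deaths: int

    CARE_COLUMNS = ("untreated", "in_treatment", "discharged")

    @property
    def total(self) -> int:
        return int(self.healthy + self.counts.sum() + self.deaths)

    def prevalent(self, severity: int) -> int:
        """Actively symptomatic count for one severity (untreated + in treatment)."""
        return int(self.counts[severity, 0] + self.counts[severity, 1])

    @property
    def prevalent_total(self) -> int:
        return int(self.counts[:, :2].sum())


def snapshot_counts(population: Iterable[Agent]) -> StateCounts:
    """Tally a population into :class:`StateCounts` (closure holds exactly)."""
    counts = np.zeros((3, 3), dtype=np.int64)
    healthy = 0
    deaths = 0
    for agent in population:
        if not agent.alive:
            deaths += 1
        elif agent.health is not Health.NONE:
            j = 0 if agent.care is Care.UNTREATED else 1
            counts[agent.health.severity_index, j] += 1
        elif agent.care is Care.DISCHARGED and agent.weeks_since_episode is not None:
            counts[agent.prior_severity.severity_index, 2] += 1
        else:
            healthy += 1
    return StateCounts(healthy=healthy, counts=counts, deaths=deaths)
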