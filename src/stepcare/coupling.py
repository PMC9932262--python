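"""Synchronous weekly coupling of the agent model and the pathway stocks.

Both engines share a weekly clock. Each week the agent model reports its
newly symptomatic, untreated individuals per severity (the demand), the
coverage gate splits the demand into entering / not entering, the entering
share is integerised by stochastic rounding, and exactly that many agents —
drawn uniformly from the week's demand — are admitted to treatment and
injected into the matching pathway as entry inflow. Untreated severe agents
additionally reach the pathway through the emergency channel (crisis
admission via the CRHTT). In the opposite direction, every discharge or
in-treatment death reported by the agent model withdraws one unit of mass
from the pathway, so admissions and pathway inflow agree exactly — the
hybrid consistency check the framework is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import abm
from .abm import Agent, Event, StateCounts
from .params import (
    Care,
    ConfigError,
    DiseaseParams,
    Health,
    SEVERITIES,
    WeeklyHazards,
)
from .pathways import PathwayConfig, PathwayModel, build_pathways, coverage_gate

__all__ = [
    "CouplingSignal",
    "stochastic_round",
    "weekly_exchange",
    "HybridModel",
    "RunResult",
    "run_replication",
]


@dataclass
class CouplingSignal:
    """Per-week message bundle exchanged between the two engines.

    All entries are integer persons, indexed (mild, moderate, severe).
    ``entering + not_entering == demand`` holds exactly per severity;
    ``emergencies`` counts crisis admissions of untreated severe agents
    (zero for mild/moderate); ``discharges`` counts agents leaving
    treatment this week (including in-treatment deaths), i.e. the mass the
    pathway model must release.
    """

    week: int
    demand: np.ndarray
    entering: np.ndarray
    not_entering: np.ndarray
    discharges: np.ndarray
    emergencies: np.ndarray

    def validate(self) -> None:
        if not np.array_equal(self.entering + self.not_entering, self.demand):
            raise ConfigError("entering + not_entering must equal demand exactly")


def stochastic_round(value: float, rng: np.random.Generator) -> int:
    """Round to an integer, up with probability equal to the fractional part.

    Unbiased: the expectation equals ``value``, which preserves the coverage
    fraction at small weekly counts.
    """
    if value < 0:
        raise ConfigError("cannot round a negative count")
    base = math.floor(value)
    frac = value - base
    if frac > 0 and rng.random() < frac:
        base += 1
    return int(base)


def weekly_exchange(
    agents: Sequence[Agent],
    coverage: float,
    week: int,
    rng: np.random.Generator,
    params: DiseaseParams,
    hz: WeeklyHazards,
    discharges: np.ndarray,
    events: Optional[list] = None,
) -> CouplingSignal:
    """Run one week's AB -> gate -> AB exchange; returns the signal bundle.

    Demand is the set of untreated agents not yet offered service for the
    current episode (with ``reoffer_weekly`` every untreated agent is
    re-offered). The gate's continuous entering share is integerised by
    stochastic rounding, the entrants are sampled uniformly, admitted and
    their treatment durations drawn. Afterwards the severe emergency channel
    applies: each untreated severe agent reaches crisis care with the weekly
    emergency hazard (disabled at coverage zero, which models a complete
    service shutdown).
    """
    demand_pools: list[list[Agent]] = [[], [], []]
    for agent in agents:
        if agent.alive and agent.health is not Health.NONE and agent.care is Care.UNTREATED:
            if params.reoffer_weekly or not agent.offered:
                demand_pools[agent.health.severity_index].append(agent)

    demand = np.array([len(pool) for pool in demand_pools], dtype=np.int64)
    entering = np.zeros(3, dtype=np.int64)
    for i, pool in enumerate(demand_pools):
        cont_in, _ = coverage_gate(float(demand[i]), coverage)
        k = min(stochastic_round(cont_in, rng), demand[i])
        entering[i] = k
        if k:
            chosen = rng.choice(len(pool), size=k, replace=False)
            chosen_set = set(int(c) for c in chosen)
        else:
            chosen_set = set()
        for idx, agent in enumerate(pool):
            if idx in chosen_set:
                abm.admit_to_treatment(agent, params, week, rng)
                if events is not None:
                    events.append((week, Event(abm.ADMISSION, i)))
            else:
                agent.offered = True  # one offer per episode (unless re-offering)

    emergencies = np.zeros(3, dtype=np.int64)
    if coverage > 0 and hz.emergency > 0:
        sev_idx = Health.SEVERE.severity_index
        for agent in agents:
            if (
                agent.alive
                and agent.health is Health.SEVERE
                and agent.care is Care.UNTREATED
                and rng.random() < hz.emergency
            ):
                abm.admit_to_treatment(agent, params, week, rng)
                emergencies[sev_idx] += 1
                if events is not None:
                    events.append((week, Event(abm.EMERGENCY_ADMISSION, sev_idx)))

    signal = CouplingSignal(
        week=week,
        demand=demand,
        entering=entering,
        not_entering=demand - entering,
        discharges=np.asarray(discharges, dtype=np.int64),
        emergencies=emergencies,
    )
    signal.validate()
    return signal


@dataclass
class RunResult:
    """Time series and counters from one hybrid replication."""

    seed: int
    coverage: float
    horizon_weeks: int
    counts: pd.DataFrame          # week x state-count columns
    events: pd.DataFrame          # week, kind, severity, to_severity, prior_treated
    signals: pd.DataFrame         # weekly coupling signal per severity
    ledger_weekly: pd.DataFrame   # cumulative service units by week
    sd_mass: pd.DataFrame         # per-severity stock mass / admissions / discharges by week
    ab_admissions: np.ndarray     # cumulative per severity (gate + emergency)
    sd_entry_inflow: np.ndarray   # cumulative per severity (gate + crisis inflow)

    def prevalent_counts(self) -> pd.DataFrame:
        """Weekly actively-symptomatic counts per severity (+ total)."""
        out = pd.DataFrame(
            {
                sev: self.counts[f"{sev}_untreated"] + self.counts[f"{sev}_in_treatment"]
                for sev in SEVERITIES
            },
            index=self.counts.index,
        )
        out["total"] = out.sum(axis=1)
        return out

    def counts_tidy(self) -> pd.DataFrame:
        """Counts in tidy form: week, severity, care_state, count."""
        rows = []
        for sev in SEVERITIES:
            for care in ("untreated", "in_treatment", "discharged"):
                col = f"{sev}_{care}"
                rows.append(
                    pd.DataFrame(
                        {
                            "week": self.counts.index,
                            "severity": sev,
                            "care_state": care,
                            "count": self.counts[col].to_numpy(),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def service_use(self, warm_up_weeks: int, annualise: bool = True) -> dict[str, float]:
        """Service units accrued after warm-up, rescaled to a 52-week year."""
        if warm_up_weeks >= self.horizon_weeks:
            raise ConfigError("warm-up must be shorter than the horizon")
        end = self.ledger_weekly.iloc[-1]
        start = self.ledger_weekly.loc[warm_up_weeks]
        window = self.horizon_weeks - warm_up_weeks
        scale = 52.0 / window if annualise else 1.0
        return {svc: float((end[svc] - start[svc]) * scale) for svc in self.ledger_weekly.columns}


class HybridModel:
    """One replication of the coupled agent-based / stock-and-flow model.

    Parameters
    ----------
    params:
        Disease-progression parameters.
    onset_hazards:
        Per-severity weekly onset hazards for disease-free agents (typically
        from :func:`stepcare.calibrate.calibrate_incidence`).
    coverage:
        Service coverage in [0, 1].
    seed:
        Seed for the replication's RNG stream.
    pathway_configs:
        Optional per-severity pathway configuration; defaults are used when
        omitted.
    integrate_sd:
        When False the stock-and-flow side is skipped entirely (the gate
        itself does not depend on stock levels, so agent dynamics are
        unchanged); used for cheap calibration pilots.
    """

    def __init__(
        self,
        params: DiseaseParams,
        onset_hazards: Sequence[float],
        coverage: float,
        seed: int,
        pathway_configs: Optional[dict[str, PathwayConfig]] = None,
        integrate_sd: bool = True,
    ) -> None:
        if not 0.0 <= coverage <= 1.0:
            raise ConfigError(f"coverage must be in [0, 1], got {coverage}")
        onset = np.asarray(onset_hazards, dtype=float)
        if onset.shape != (3,) or (onset < 0).any() or onset.sum() > 1:
            raise ConfigError("onset hazards must be three probabilities summing to <= 1")
        self.params = params
        self.onset_hazards = onset
        self.coverage = float(coverage)
        self.seed = int(seed)
        self.hz = WeeklyHazards.from_params(params)
        self.agents, self.rng = abm.init_population(params, seed)
        self.week = 0
        self.integrate_sd = integrate_sd
        self.pathways: dict[str, PathwayModel] = (
            build_pathways(pathway_configs) if integrate_sd else {}
        )
        self.ab_admissions = np.zeros(3, dtype=np.int64)
        self.sd_entry_inflow = np.zeros(3, dtype=float)
        self._events: list[tuple[int, Event]] = []
        self._signals: list[CouplingSignal] = []
        self._count_rows: list[dict] = []
        self._ledger_rows: list[dict] = []
        self._mass_rows: list[dict] = []
        self._record_state()  # week 0 snapshot

    # -- weekly machinery --------------------------------------------------

    def _step_agents(self) -> np.ndarray:
        """Advance every agent one week; returns per-severity discharge counts."""
        removals = np.zeros(3, dtype=np.int64)  # discharges + in-treatment deaths
        onset_total = float(self.onset_hazards.sum())
        props = self.onset_hazards / onset_total if onset_total > 0 else None
        rng = self.rng
        for agent in self.agents:
            if not agent.alive:
                continue
            if agent.health is Health.NONE:
                if agent.weeks_since_episode is not None:
                    for ev in abm.step_recovered(agent, self.hz, rng):
                        self._events.append((self.week, ev))
                else:
                    died = abm.step_healthy(agent, self.hz, rng)
                    if died:
                        self._events.append((self.week, died[0]))
                    elif onset_total > 0 and rng.random() < onset_total:
                        sev = Health(int(np.searchsorted(np.cumsum(props), rng.random(), side="right")) + 1)
                        agent.health = sev
                        agent.care = Care.UNTREATED
                        agent.weeks_in_state = 0
                        agent.offered = False
                        agent.weeks_since_episode = None
                        self._events.append((self.week, Event(abm.ONSET, sev.severity_index)))
            elif agent.care is Care.UNTREATED:
                for ev in abm.step_untreated(agent, self.hz, rng):
                    self._events.append((self.week, ev))
            elif agent.care is Care.IN_TREATMENT:
                sev = agent.health.severity_index
                evs = abm.step_in_treatment(agent, self.params, self.hz, self.week, rng)
                for ev in evs:
                    self._events.append((self.week, ev))
                    if ev.kind in (abm.DISCHARGE, abm.DEATH):
                        removals[sev] += 1
        return removals

    def step_week(self) -> CouplingSignal:
        """Run one synchronous week: AB dynamics, exchange, SD integration."""
        self.week += 1
        removals = self._step_agents()
        signal = weekly_exchange(
            self.agents,
            self.coverage,
            self.week,
            self.rng,
            self.params,
            self.hz,
            discharges=removals,
            events=self._events,
        )
        self._signals.append(signal)
        self.ab_admissions += signal.entering + signal.emergencies
        self.sd_entry_inflow += signal.entering + signal.emergencies
        if self.integrate_sd:
            for i, sev in enumerate(SEVERITIES):
                model = self.pathways[sev]
                model.integrate_step(
                    entry_inflow=float(signal.entering[i]),
                    crisis_inflow=float(signal.emergencies[i]),
                    dt=1.0,
                )
                if removals[i]:
                    model.remove_discharges(float(removals[i]))
        self._record_state()
        return signal

    def run(self, horizon_weeks: Optional[int] = None) -> RunResult:
        horizon = int(horizon_weeks or self.params.horizon_weeks)
        while self.week < horizon:
            self.step_week()
        return self._result(horizon)

    # -- bookkeeping -------------------------------------------------------

    def _record_state(self) -> None:
        sc = abm.snapshot_counts(self.agents)
        row = {"week": self.week, "healthy": sc.healthy, "deaths": sc.deaths}
        for i, sev in enumerate(SEVERITIES):
            row[f"{sev}_untreated"] = int(sc.counts[i, 0])
            row[f"{sev}_in_treatment"] = int(sc.counts[i, 1])
            row[f"{sev}_discharged"] = int(sc.counts[i, 2])
        self._count_rows.append(row)
        if self.integrate_sd:
            lrow = {"week": self.week}
            for svc in self.pathways["mild"].ledger:
                lrow[svc] = sum(p.ledger[svc] for p in self.pathways.values())
            self._ledger_rows.append(lrow)
            for sev in SEVERITIES:
                p = self.pathways[sev]
                self._mass_rows.append(
                    {
                        "week": self.week,
                        "severity": sev,
                        "total_mass": p.total_mass,
                        "cumulative_admissions": p.cumulative_admissions,
                        "cumulative_discharges": p.cumulative_discharges,
                        "in_treatment_agents": row[f"{sev}_in_treatment"],
                    }
                )

    def _result(self, horizon: int) -> RunResult:
        counts = pd.DataFrame(self._count_rows).set_index("week")
        events = pd.DataFrame(
            [
                {
                    "week": week,
                    "kind": ev.kind,
                    "severity": ev.severity,
                    "to_severity": ev.to_severity,
                    "prior_treated": ev.prior_treated,
                }
                for week, ev in self._events
            ],
            columns=["week", "kind", "severity", "to_severity", "prior_treated"],
        )
        signals = pd.DataFrame(
            [
                {
                    "week": s.week,
                    "severity": sev,
                    "demand": int(s.demand[i]),
                    "entering": int(s.entering[i]),
                    "not_entering": int(s.not_entering[i]),
                    "discharges": int(s.discharges[i]),
                    "emergencies": int(s.emergencies[i]),
                }
                for s in self._signals
                for i, sev in enumerate(SEVERITIES)
            ],
            columns=["week", "severity", "demand", "entering", "not_entering", "discharges", "emergencies"],
        )
        ledger = (
            pd.DataFrame(self._ledger_rows).set_index("week")
            if self._ledger_rows
            else pd.DataFrame()
        )
        sd_mass = pd.DataFrame(
            self._mass_rows,
            columns=[
                "week",
                "severity",
                "total_mass",
                "cumulative_admissions",
                "cumulative_discharges",
                "in_treatment_agents",
            ],
        )
        return RunResult(
            seed=self.seed,
            coverage=self.coverage,
            horizon_weeks=horizon,
            counts=counts,
            events=events,
            signals=signals,
            ledger_weekly=ledger,
            sd_mass=sd_mass,
            ab_admissions=self.ab_admissions.copy(),
            sd_entry_inflow=self.sd_entry_inflow.copy(),
        )


def run_replication(
    params: DiseaseParams,
    onset_hazards: Sequence[float],
    coverage: float,
    seed: int,
    pathway_configs: Optional[dict[str, PathwayConfig]] = None,
    horizon_weeks: Optional[int] = None,
    integrate_sd: bool = True,
) -> RunResult:
    """Convenience wrapper: build a :class:`HybridModel` and run it."""
    model = HybridModel(
        params,
        onset_hazards,
        coverage,
        seed,
        pathway_configs=pathway_configs,
        integrate_sd=integrate_sd,
    )
    return model.run(horizon_weeks)
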