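"""Stock-and-flow models of the stepped-care treatment pathways.

One continuous, Euler-integrated pathway per severity level. Stages are
first-order delays: a stage with level ``L`` and mean duration ``D`` drains
at ``L / D`` persons per week, and its outflow is split across downstream
stages by branch fractions. Each stage carries resource coefficients
(service units consumed per person entering the stage, e.g. four GP visits
during the assessment stage) accrued into a :class:`ServiceLedger`; a stage
may additionally meter an occupancy resource (level x dt, used for
inpatient bed-weeks).

Structure follows a stepped-care recommendation: mild and moderate
depression are managed entirely in outpatient settings (GP assessment,
then GP-supervised medication or psychologist-led therapy, with an
escalation step for moderate cases); the severe pathway adds community
mental health team (CMHT) contact, a crisis resolution home treatment team
(CRHTT) route, and inpatient care, including direct admission at the start
of treatment and emergency admission from the crisis channel.

Discharge authority rests with the agent-based model: every pathway exit
pools into a terminal ``awaiting_discharge`` stock with no autonomous
outflow, and each individual discharge reported by the agent model removes
one unit of mass (terminal stock first, then proportionally across the
remaining stocks). As a consequence the pathway's total mass equals the
agent model's in-treatment head count week by week, and the mass balance
``admissions == stocks + discharges`` is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .params import ConfigError, SEVERITIES

__all__ = [
    "SERVICE_TYPES",
    "StageSpec",
    "PathwayConfig",
    "PathwayModel",
    "ServiceLedger",
    "build_mild_pathway",
    "build_moderate_pathway",
    "build_severe_pathway",
    "build_pathways",
    "integrate_step",
    "coverage_gate",
    "enumerate_paths",
    "expected_resources_per_entrant",
]

#: Service types metered by the ledger, matching the service-use report
#: columns: GP (visits), psychological therapy (visits), medication
#: (people), psychiatrist (visits), CMHT (visits), CRHTT (people),
#: inpatient (weeks).
SERVICE_TYPES = (
    "gp",
    "psych_therapy",
    "medication",
    "psychiatrist",
    "cmht",
    "crhtt",
    "inpatient_weeks",
)

#: Name of the terminal holding stock present in every pathway.
TERMINAL = "awaiting_discharge"


@dataclass(frozen=True)
class StageSpec:
    """One care stage: a first-order delay with resource accounting.

    ``branch_fractions`` maps successor stage names (or the terminal
    ``awaiting_discharge`` stock) to the fraction of this stage's outflow
    routed there; fractions must sum to one. ``resource_coefficients`` are
    service units accrued per person *entering* the stage.
    ``occupancy_resource`` names a service accrued as level x dt each step.
    """

    name: str
    mean_duration_weeks: float
    branch_fractions: Mapping[str, float]
    resource_coefficients: Mapping[str, float] = field(default_factory=dict)
    occupancy_resource: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mean_duration_weeks <= 0:
            raise ConfigError(f"stage {self.name!r}: duration must be positive")
        total = sum(self.branch_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"stage {self.name!r}: branch fractions sum to {total!r}, expected 1"
            )
        for target, frac in self.branch_fractions.items():
            if frac < 0:
                raise ConfigError(f"stage {self.name!r}: negative fraction to {target!r}")
        for svc, coef in self.resource_coefficients.items():
            if coef < 0:
                raise ConfigError(f"stage {self.name!r}: negative coefficient for {svc!r}")


class ServiceLedger(dict):
    """Cumulative service units by type; entries are non-negative and non-decreasing."""

    def __init__(self) -> None:
        super().__init__({svc: 0.0 for svc in SERVICE_TYPES})

    def accrue(self, service: str, units: float) -> None:
        if units < 0:
            raise ConfigError(f"negative accrual for {service!r}")
        self[service] = self.get(service, 0.0) + units

    def copy(self) -> "ServiceLedger":
        new = ServiceLedger()
        new.update(self)
        return new


@dataclass
class PathwayConfig:
    """Branch fractions, stage durations and visit coefficients for one severity.

    All values are exposed because the published pathway narratives fix the
    structure but not every split; defaults are documented one-time choices
    (see the methods note).
    """

    # fraction remitting during the initial GP assessment ("majority remit
    # within 6 weeks" for mild; graded down with severity)
    remit_fraction: float = 0.6
    # medication vs psychologist-led therapy among persisting cases
    medication_fraction: float = 0.5
    # moderate/severe only: fraction escalating to intensive treatment after
    # the first-line block, and the psychiatrist share within that escalation
    escalate_fraction: float = 0.5
    psychiatrist_fraction: float = 0.5
    # severe only
    initial_inpatient_fraction: float = 0.1
    crisis_fraction: float = 0.1          # in-pathway crisis branch from active treatment
    crisis_admission_fraction: float = 0.5  # CRHTT -> inpatient share
    durations: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    coefficients: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()})

    def __post_init__(self) -> None:
        for name in (
            "remit_fraction",
            "medication_fraction",
            "escalate_fraction",
            "psychiatrist_fraction",
            "initial_inpatient_fraction",
            "crisis_fraction",
            "crisis_admission_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return {
            "remit_fraction": self.remit_fraction,
            "medication_fraction": self.medication_fraction,
            "escalate_fraction": self.escalate_fraction,
            "psychiatrist_fraction": self.psychiatrist_fraction,
            "initial_inpatient_fraction": self.initial_inpatient_fraction,
            "crisis_fraction": self.crisis_fraction,
            "crisis_admission_fraction": self.crisis_admission_fraction,
            "durations": dict(self.durations),
            "coefficients": {k: dict(v) for k, v in self.coefficients.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathwayConfig":
        return cls(**dict(d))


#: Stage durations in weeks. The 6-week assessment ("remit within 6 weeks")
#: and the 46-week medication course are from the pathway recommendation;
#: the rest are documented defaults.
DEFAULT_DURATIONS = {
    "gp_assessment": 6.0,
    "medication": 46.0,
    "therapy": 12.0,
    "gp_followup": 2.0,
    "intensive_therapy": 12.0,
    "psychiatrist_med": 12.0,
    "final_gp_eval": 2.0,
    "cmht_intake": 4.0,
    "crhtt": 4.0,
    "inpatient": 8.0,
    "cmht_followup": 4.0,
}

#: Service units per person entering each stage ("up to N visits" counted as
#: exactly N, upper-bound capacity accounting). Medication is counted once
#: per person entering a medication stage.
DEFAULT_COEFFICIENTS = {
    "gp_assessment": {"gp": 4.0},
    "medication": {"gp": 6.0, "medication": 1.0},
    "therapy": {"psych_therapy": 6.0},
    "gp_followup": {"gp": 1.0},
    "intensive_therapy": {"psych_therapy": 6.0},
    "psychiatrist_med": {"psychiatrist": 6.0, "medication": 1.0},
    "final_gp_eval": {"gp": 1.0},
    "cmht_intake": {"cmht": 4.0},
    "crhtt": {"crhtt": 1.0},
    "inpatient": {"cmht": 2.0},
    "cmht_followup": {"cmht": 4.0},
}

INPATIENT_STAGES = ("inpatient", "cmht_intake", "cmht_followup", "crhtt")


@dataclass
class PathwayModel:
    """A wired stock-and-flow graph for one severity level."""

    severity: str
    stages: dict  # name -> StageSpec
    entry_split: dict  # stage name -> fraction of gate entrants
    crisis_entry_stage: Optional[str] = None
    levels: dict = field(init=False)
    ledger: ServiceLedger = field(init=False)
    cumulative_admissions: float = field(init=False, default=0.0)
    cumulative_discharges: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        total = sum(self.entry_split.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"entry split sums to {total!r}, expected 1")
        for spec in self.stages.values():
            for target in spec.branch_fractions:
                if target != TERMINAL and target not in self.stages:
                    raise ConfigError(
                        f"stage {spec.name!r} routes to unknown stage {target!r}"
                    )
        for stage in self.entry_split:
            if stage not in self.stages:
                raise ConfigError(f"entry split routes to unknown stage {stage!r}")
        if not self._reaches_terminal():
            raise ConfigError("pathway graph does not connect entry to discharge")
        self.reset()

    def _reaches_terminal(self) -> bool:
        seen: set[str] = set()
        frontier = [s for s in self.entry_split]
        while frontier:
            name = frontier.pop()
            if name == TERMINAL:
                return True
            if name in seen:
                continue
            seen.add(name)
            frontier.extend(self.stages[name].branch_fractions)
        return False

    def reset(self) -> None:
        self.levels = {name: 0.0 for name in self.stages}
        self.levels[TERMINAL] = 0.0
        self.ledger = ServiceLedger()
        self.cumulative_admissions = 0.0
        self.cumulative_discharges = 0.0

    @property
    def total_mass(self) -> float:
        return sum(self.levels.values())

    def mass_balance_error(self) -> float:
        """|admissions - (stocks + discharges)|; exactly ~0 by construction."""
        return abs(self.cumulative_admissions - (self.total_mass + self.cumulative_discharges))

    # -- dynamics ---------------------------------------------------------

    def integrate_step(self, entry_inflow: float, crisis_inflow: float = 0.0, dt: float = 1.0) -> None:
        """Advance the stocks by ``dt`` weeks with explicit Euler.

        ``entry_inflow``/``crisis_inflow`` are persons per week entering via
        the coverage gate and (severe only) the emergency channel. Outflows
        are clamped so no stock goes negative, and resource coefficients are
        accrued on stage entry (inflow x dt).
        """
        if dt <= 0:
            raise ConfigError("dt must be positive")
        if entry_inflow < 0 or crisis_inflow < 0:
            raise ConfigError("inflows must be non-negative")
        if crisis_inflow > 0 and self.crisis_entry_stage is None:
            raise ConfigError(f"{self.severity} pathway has no crisis entry stage")

        inflows = {name: 0.0 for name in self.levels}
        for stage, frac in self.entry_split.items():
            inflows[stage] += entry_inflow * frac
        if crisis_inflow > 0:
            inflows[self.crisis_entry_stage] += crisis_inflow

        outflows: dict[str, float] = {}
        for name, spec in self.stages.items():
            rate = self.levels[name] / spec.mean_duration_weeks
            rate = min(rate, self.levels[name] / dt)  # never drain below zero
            outflows[name] = rate
            for target, frac in spec.branch_fractions.items():
                inflows[target] += rate * frac

        for name, spec in self.stages.items():
            entered = inflows[name] * dt
            if entered:
                for svc, coef in spec.resource_coefficients.items():
                    self.ledger.accrue(svc, coef * entered)
            self.levels[name] += (inflows[name] - outflows[name]) * dt
            if self.levels[name] < 0:  # float noise only
                self.levels[name] = 0.0
            if spec.occupancy_resource:
                self.ledger.accrue(spec.occupancy_resource, self.levels[name] * dt)
        self.levels[TERMINAL] += inflows[TERMINAL] * dt
        self.cumulative_admissions += (entry_inflow + crisis_inflow) * dt

    def remove_discharges(self, persons: float) -> float:
        """Withdraw discharged mass: terminal stock first, then pro rata.

        Called with the agent model's discharge (and in-treatment death)
        count for the week. Returns the mass actually removed, which equals
        ``persons`` whenever the hybrid engine drives both sides from the
        same admission events.
        """
        if persons < 0:
            raise ConfigError("discharge count must be non-negative")
        remaining = float(persons)
        take = min(self.levels[TERMINAL], remaining)
        self.levels[TERMINAL] -= take
        remaining -= take
        if remaining > 1e-12:
            other = {n: l for n, l in self.levels.items() if n != TERMINAL and l > 0}
            pool = sum(other.values())
            drawn = min(pool, remaining)
            if pool > 0:
                for name, level in other.items():
                    self.levels[name] -= drawn * level / pool
            remaining -= drawn
        removed = float(persons) - max(remaining, 0.0)
        self.cumulative_discharges += removed
        return removed


def integrate_step(model: PathwayModel, dt: float = 1.0, entry_inflow: float = 0.0, crisis_inflow: float = 0.0) -> None:
    """Functional wrapper around :meth:`PathwayModel.integrate_step`."""
    model.integrate_step(entry_inflow=entry_inflow, crisis_inflow=crisis_inflow, dt=dt)


def coverage_gate(demand: float, coverage: float) -> tuple[float, float]:
    """Split weekly demand into (entering, not entering) by service coverage.

    ``entering = coverage * demand``; both branches are returned to the
    coupling layer, which integerises them for the agent model.
    """
    if demand < 0:
        raise ConfigError(f"demand must be non-negative, got {demand}")
    if not 0.0 <= coverage <= 1.0:
        raise ConfigError(f"coverage must be in [0, 1], got {coverage}")
    entering = coverage * demand
    return entering, demand - entering


# -- builders --------------------------------------------------------------


def _first_line_stages(cfg: PathwayConfig, crisis: float = 0.0) -> dict:
    """Shared GP-led first-line block: assessment, medication, therapy.

    ``crisis`` diverts a fraction of the medication/therapy outflow to the
    CRHTT (severe only); the caller wires the follow-up stage.
    """
    d, c = cfg.durations, cfg.coefficients
    persist = 1.0 - cfg.remit_fraction
    active_exit = (
        {"crhtt": crisis, "gp_followup": 1.0 - crisis} if crisis else {"gp_followup": 1.0}
    )
    return {
        "gp_assessment": StageSpec(
            "gp_assessment",
            d["gp_assessment"],
            {
                TERMINAL: cfg.remit_fraction,
                "medication": persist * cfg.medication_fraction,
                "therapy": persist * (1.0 - cfg.medication_fraction),
            },
            c["gp_assessment"],
        ),
        "medication": StageSpec("medication", d["medication"], dict(active_exit), c["medication"]),
        "therapy": StageSpec("therapy", d["therapy"], dict(active_exit), c["therapy"]),
    }


def build_mild_pathway(config: PathwayConfig | None = None) -> PathwayModel:
    """Primary-care pathway for mild depression (no inpatient, CMHT or CRHTT).

    entry -> GP assessment (4 GP visits, 6 weeks) -> remit, or persist into
    GP-supervised medication (46 weeks, 6 GP visits, 1 medication person) or
    psychologist-led therapy (6 therapy visits) -> GP follow-up (1 visit) ->
    discharge.
    """
    cfg = config or PathwayConfig()
    d, c = cfg.durations, cfg.coefficients
    stages = _first_line_stages(cfg)
    stages["gp_followup"] = StageSpec("gp_followup", d["gp_followup"], {TERMINAL: 1.0}, c["gp_followup"])
    return PathwayModel("mild", stages, {"gp_assessment": 1.0})


def _escalation_wiring(cfg: PathwayConfig) -> Mapping[str, float]:
    esc = cfg.escalate_fraction
    return {
        "psychiatrist_med": esc * cfg.psychiatrist_fraction,
        "intensive_therapy": esc * (1.0 - cfg.psychiatrist_fraction),
        "final_gp_eval": 1.0 - esc,
    }


def build_moderate_pathway(config: PathwayConfig | None = None) -> PathwayModel:
    """Moderate pathway: the mild structure plus an escalation step.

    After the first-line block a configurable fraction escalates to more
    intensive psychologist-led therapy or psychiatrist-managed medication;
    everyone closes with a final GP evaluation. Still fully outpatient.
    """
    cfg = config or PathwayConfig(remit_fraction=0.4)
    d, c = cfg.durations, cfg.coefficients
    stages = _first_line_stages(cfg)
    stages["gp_followup"] = StageSpec("gp_followup", d["gp_followup"], _escalation_wiring(cfg), c["gp_followup"])
    stages["intensive_therapy"] = StageSpec(
        "intensive_therapy", d["intensive_therapy"], {"final_gp_eval": 1.0}, c["intensive_therapy"]
    )
    stages["psychiatrist_med"] = StageSpec(
        "psychiatrist_med", d["psychiatrist_med"], {"final_gp_eval": 1.0}, c["psychiatrist_med"]
    )
    stages["final_gp_eval"] = StageSpec("final_gp_eval", d["final_gp_eval"], {TERMINAL: 1.0}, c["final_gp_eval"])
    return PathwayModel("moderate", stages, {"gp_assessment": 1.0})


def build_severe_pathway(config: PathwayConfig | None = None) -> PathwayModel:
    """Severe pathway: moderate structure plus CMHT, CRHTT and inpatient care.

    A fraction of entrants is admitted directly to the inpatient facility;
    the rest start with CMHT contact before the GP-led block. A crisis
    branch from active treatment routes through the CRHTT, which either
    resolves the crisis at home or admits to inpatient care; inpatient
    discharge is followed up by the CMHT. The emergency coupling channel
    (untreated severe agents in crisis) enters at the CRHTT.
    """
    cfg = config or PathwayConfig(remit_fraction=0.2)
    d, c = cfg.durations, cfg.coefficients
    stages = _first_line_stages(cfg, crisis=cfg.crisis_fraction)
    stages["cmht_intake"] = StageSpec("cmht_intake", d["cmht_intake"], {"gp_assessment": 1.0}, c["cmht_intake"])
    stages["gp_followup"] = StageSpec("gp_followup", d["gp_followup"], _escalation_wiring(cfg), c["gp_followup"])
    stages["intensive_therapy"] = StageSpec(
        "intensive_therapy", d["intensive_therapy"], {"final_gp_eval": 1.0}, c["intensive_therapy"]
    )
    stages["psychiatrist_med"] = StageSpec(
        "psychiatrist_med", d["psychiatrist_med"], {"final_gp_eval": 1.0}, c["psychiatrist_med"]
    )
    stages["crhtt"] = StageSpec(
        "crhtt",
        d["crhtt"],
        {
            "inpatient": cfg.crisis_admission_fraction,
            "gp_followup": 1.0 - cfg.crisis_admission_fraction,
        },
        c["crhtt"],
    )
    stages["inpatient"] = StageSpec(
        "inpatient", d["inpatient"], {"cmht_followup": 1.0}, c["inpatient"], occupancy_resource="inpatient_weeks"
    )
    stages["cmht_followup"] = StageSpec(
        "cmht_followup", d["cmht_followup"], {"final_gp_eval": 1.0}, c["cmht_followup"]
    )
    stages["final_gp_eval"] = StageSpec("final_gp_eval", d["final_gp_eval"], {TERMINAL: 1.0}, c["final_gp_eval"])
    return PathwayModel(
        "severe",
        stages,
        {
            "inpatient": cfg.initial_inpatient_fraction,
            "cmht_intake": 1.0 - cfg.initial_inpatient_fraction,
        },
        crisis_entry_stage="crhtt",
    )


_BUILDERS = {
    "mild": build_mild_pathway,
    "moderate": build_moderate_pathway,
    "severe": build_severe_pathway,
}

DEFAULT_REMIT_FRACTIONS = {"mild": 0.6, "moderate": 0.4, "severe": 0.2}


def default_pathway_configs() -> dict[str, PathwayConfig]:
    """Documented default configuration per severity level."""
    return {
        sev: PathwayConfig(remit_fraction=DEFAULT_REMIT_FRACTIONS[sev])
        for sev in SEVERITIES
    }


def build_pathways(configs: Mapping[str, PathwayConfig] | None = None) -> dict[str, PathwayModel]:
    """Build the three pathway models (mild, moderate, severe)."""
    configs = dict(configs) if configs else default_pathway_configs()
    models = {}
    for sev in SEVERITIES:
        models[sev] = _BUILDERS[sev](configs.get(sev))
    # structural invariants of the stepped-care recommendation
    for sev, model in models.items():
        has_specialist = any(s in model.stages for s in INPATIENT_STAGES)
        if sev == "severe" and not has_specialist:
            raise ConfigError("severe pathway must include inpatient/CMHT/CRHTT stages")
        if sev != "severe" and has_specialist:
            raise ConfigError(f"{sev} pathway must be outpatient-only")
    return models


def pathway_configs_to_yaml(configs: Mapping[str, PathwayConfig], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({sev: cfg.to_dict() for sev, cfg in configs.items()}, sort_keys=False)
    )


def pathway_configs_from_yaml(path: str | Path) -> dict[str, PathwayConfig]:
    raw = yaml.safe_load(Path(path).read_text())
    return {sev: PathwayConfig.from_dict(d) for sev, d in raw.items()}


# -- analytic oracle helpers ----------------------------------------------


def enumerate_paths(model: PathwayModel) -> list[tuple[tuple[str, ...], float]]:
    """All entry-to-discharge routes with their probabilities (brute force).

    Walks the branch graph depth-first from each entry stage. The graph is
    acyclic by construction, so enumeration terminates; probabilities sum
    to one.
    """
    paths: list[tuple[tuple[str, ...], float]] = []

    def walk(stage: str, prob: float, trail: tuple[str, ...]) -> None:
        if stage == TERMINAL:
            paths.append((trail, prob))
            return
        if stage in trail:
            raise ConfigError(f"cycle through stage {stage!r}")
        for target, frac in model.stages[stage].branch_fractions.items():
            if frac > 0:
                walk(target, prob * frac, trail + (stage,))

    for stage, frac in model.entry_split.items():
        if frac > 0:
            walk(stage, frac, ())
    return paths


def expected_resources_per_entrant(model: PathwayModel) -> dict[str, float]:
    """Branch-weighted entry-coefficient totals per unit admitted cohort.

    Independent closed form for the ledger's per-entrant resource use
    (occupancy-metered resources such as inpatient weeks excluded).
    """
    totals = {svc: 0.0 for svc in SERVICE_TYPES}
    for trail, prob in enumerate_paths(model):
        for stage in trail:
            for svc, coef in model.stages[stage].resource_coefficients.items():
                totals[svc] += prob * coef
    return totals
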