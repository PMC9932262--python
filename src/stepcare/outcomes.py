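"""Derived outputs: prevalence summaries, counters, scaling, costs, DALYs.

Everything here operates on run logs (the :class:`~stepcare.coupling.RunResult`
bundles) and is deliberately free of simulation logic, so the same code
summarises any scenario. Yearly figures average the post-warm-up weeks and
rescale to a 52-week year.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abm import DETERIORATION, RELAPSE
from .params import ConfigError, SEVERITIES
from .pathways import SERVICE_TYPES

__all__ = [
    "PrevalenceSummary",
    "DalyParams",
    "summarize_prevalence",
    "count_transitions",
    "scale_to_population",
    "load_scaling_table",
    "cost_report",
    "placeholder_cost_table",
    "compute_dalys",
    "dalys_averted",
    "person_years",
]


@dataclass(frozen=True)
class DalyParams:
    """Disability weights per severity (mild, moderate, severe)."""

    weights: tuple[float, float, float] = (0.145, 0.396, 0.658)

    def __post_init__(self) -> None:
        for w in self.weights:
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"disability weights must be in [0, 1], got {w}")


@dataclass
class PrevalenceSummary:
    """Mean weekly symptomatic counts with 95% t-based CIs across replications."""

    table: pd.DataFrame  # index: mild/moderate/severe/total; columns: mean, ci_low, ci_high
    n_replications: int

    def mean(self, severity: str) -> float:
        return float(self.table.loc[severity, "mean"])


def _postwarmup_prevalence(run, warm_up_weeks: int) -> pd.Series:
    prev = run.prevalent_counts()
    if prev.index.max() <= warm_up_weeks:
        raise ConfigError("run does not extend beyond the warm-up period")
    return prev.loc[warm_up_weeks + 1 :].mean()


def summarize_prevalence(runs: Sequence, warm_up_weeks: int = 26) -> PrevalenceSummary:
    """Average weekly severity counts over the post-warm-up window.

    ``runs`` are replications of one scenario. The replication means are
    averaged and a 95% Student-t interval across replications attached;
    with a single replication the CI is reported as NaN.
    """
    if not runs:
        raise ConfigError("at least one replication is required")
    per_rep = pd.DataFrame([_postwarmup_prevalence(r, warm_up_weeks) for r in runs])
    rows = {}
    n = len(runs)
    for col in per_rep.columns:
        vals = per_rep[col].to_numpy(dtype=float)
        mean = vals.mean()
        if n >= 2 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        elif n >= 2:
            half = 0.0
        else:
            half = np.nan
        rows[col] = {"mean": mean, "ci_low": mean - half, "ci_high": mean + half}
    table = pd.DataFrame(rows).T.loc[list(SEVERITIES) + ["total"]]
    return PrevalenceSummary(table=table, n_replications=n)


def count_transitions(
    events: pd.DataFrame, warm_up_weeks: int = 0
) -> dict[str, int]:
    """Deterioration and relapse counters from a typed event log.

    Returns counts of mild->moderate and moderate->severe progressions plus
    relapse events stratified by severity x prior-treatment status
    (``relapse_<severity>_treated`` / ``..._untreated``); the strata
    partition the total with no double counting.
    """
    counters = {"deterioration_mild_to_moderate": 0, "deterioration_moderate_to_severe": 0}
    for sev in SEVERITIES:
        counters[f"relapse_{sev}_treated"] = 0
        counters[f"relapse_{sev}_untreated"] = 0
    if len(events) == 0:
        return counters
    window = events[events["week"] > warm_up_weeks]
    det = window[window["kind"] == DETERIORATION]
    counters["deterioration_mild_to_moderate"] = int((det["severity"] == 0).sum())
    counters["deterioration_moderate_to_severe"] = int((det["severity"] == 1).sum())
    rel = window[window["kind"] == RELAPSE]
    for i, sev in enumerate(SEVERITIES):
        sel = rel[rel["severity"] == i]
        counters[f"relapse_{sev}_treated"] = int((sel["prior_treated"] == True).sum())  # noqa: E712
        counters[f"relapse_{sev}_untreated"] = int((sel["prior_treated"] == False).sum())  # noqa: E712
    return counters


def scale_to_population(model_stat: float, model_n: int, region_pop: int) -> int:
    """Project a model count onto a real population, nearest-integer rounded."""
    if model_n <= 0:
        raise ConfigError(f"model population must be positive, got {model_n}")
    if region_pop < 0:
        raise ConfigError("region population must be non-negative")
    return int(round(model_stat * region_pop / model_n))


def load_scaling_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Region populations for projection; defaults to the bundled Welsh
    local-health-board table."""
    if path is None:
        ref = importlib.resources.files("stepcare").joinpath("data/welsh_lhb_populations.csv")
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    if not {"region", "population"} <= set(table.columns):
        raise ConfigError("scaling table needs 'region' and 'population' columns")
    if (table["population"] <= 0).any():
        raise ConfigError("region populations must be positive")
    return table


def project_prevalence(
    model_stats: Mapping[str, float], model_n: int, table: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Scale one or more model statistics to every region in the table."""
    table = load_scaling_table() if table is None else table
    out = table.copy()
    for name, value in model_stats.items():
        out[name] = [
            scale_to_population(value, model_n, int(p)) for p in table["population"]
        ]
    return out


class MissingCostError(ConfigError):
    """A ledger service has no unit cost."""


def placeholder_cost_table() -> dict[str, float]:
    """Synthetic unit costs (GBP) for demonstration only.

    These are NOT authoritative reference costs — supply your own table for
    real analyses; magnitudes are merely plausible so that cost *directions*
    across scenarios are meaningful.
    """
    return {
        "gp": 39.0,
        "psych_therapy": 55.0,
        "medication": 30.0,
        "psychiatrist": 120.0,
        "cmht": 40.0,
        "crhtt": 200.0,
        "inpatient_weeks": 2500.0,
    }


def cost_report(ledger: Mapping[str, float], costs: Mapping[str, float]) -> dict[str, float]:
    """Per-service and total cost for a service ledger.

    Raises :class:`MissingCostError` naming every service without a unit
    cost.
    """
    missing = [svc for svc in ledger if svc not in costs]
    if missing:
        raise MissingCostError(f"no unit cost for service(s): {sorted(missing)}")
    report = {svc: float(ledger[svc]) * float(costs[svc]) for svc in ledger}
    report["total"] = float(sum(report.values()))
    return report


def person_years(mean_weekly_counts: Mapping[str, float]) -> dict[str, float]:
    """Mean weekly symptomatic counts are person-years per calendar year."""
    return {sev: float(mean_weekly_counts[sev]) for sev in SEVERITIES}


def compute_dalys(person_years_by_severity: Mapping[str, float], params: DalyParams = DalyParams()) -> float:
    """Years lived with disability: sum of person-years x disability weight.

    The single all-cause death rate carries no excess-mortality signal, so
    no years-of-life-lost term is added.
    """
    total = 0.0
    for i, sev in enumerate(SEVERITIES):
        py = float(person_years_by_severity[sev])
        if py < 0:
            raise ConfigError(f"negative person-years for {sev}")
        total += py * params.weights[i]
    return total


def dalys_averted(dalys_a: float, dalys_b: float) -> float:
    """DALYs averted by moving from scenario ``a`` to scenario ``b``."""
    return float(dalys_a) - float(dalys_b)
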