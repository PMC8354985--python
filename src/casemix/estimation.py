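"""Parameter estimation from raw operational records.

Turns per-case phase records, monthly volume tables, surgeon rosters and
encounter-level financials into the parameters of a network instance:
which services and equipment to include, typical per-case resource usage
(median duration x mean quantity), capacities and their segmentation to
the studied scope, surgeon classes, and average per-case profitability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Profitability

__all__ = [
    "PhaseRecord",
    "SurgeonRoster",
    "SurgeonClass",
    "select_services",
    "select_type_a_resources",
    "typical_usage",
    "daily_capacity",
    "annualize",
    "segment_capacity",
    "surgeon_classes",
    "average_profitability",
]


@dataclass(frozen=True)
class PhaseRecord:
    """One (case, phase) observation: how long the phase took and how much
    of one resource it consumed."""

    case_id: str
    service: str
    activity: str
    duration_minutes: float
    resource: str
    quantity: float
    location: str

    def __post_init__(self):
        if self.duration_minutes < 0:
            raise ValueError("duration must be >= 0")
        if self.quantity < 0:
            raise ValueError("quantity must be >= 0")


@dataclass(frozen=True)
class SurgeonRoster:
    """surgeon id -> (specialty set, operating minutes per horizon)."""

    specialties: Mapping[str, frozenset[str]]
    capacity_minutes: Mapping[str, float]

    def __post_init__(self):
        for s, spec in self.specialties.items():
            if not spec:
                raise ValueError(f"surgeon {s!r} has an empty specialty set")


def select_services(volumes: pd.DataFrame, min_annual_volume: float,
                    require_monthly: bool = True) -> list[str]:
    """Retain services with annual volume >= threshold and (optionally) at
    least one case every month. ``volumes`` has columns service, month,
    count; missing months count as zero.
    """
    required = {"service", "month", "count"}
    if not required.issubset(volumes.columns):
        raise ValueError(f"volume table needs columns {sorted(required)}")
    kept = []
    for service, grp in volumes.groupby("service", sort=True):
        annual = grp["count"].sum()
        if annual < min_annual_volume:
            continue
        if require_monthly:
            months_with_cases = set(grp.loc[grp["count"] >= 1, "month"])
            if len(months_with_cases) < 12:
                continue
        kept.append(service)
    return kept


def select_type_a_resources(incidence: pd.DataFrame, min_usage_fraction: float = 0.05,
                            critical_set: Iterable[str] = ()) -> list[str]:
    """Equipment/supply screen: keep a resource iff it is critical or used
    in at least ``min_usage_fraction`` of the cases of some service.
    ``incidence`` has columns resource, service, fraction.
    """
    critical = set(critical_set)
    if ((incidence["fraction"] < 0) | (incidence["fraction"] > 1)).any():
        raise ValueError("usage fractions must lie in [0, 1]")
    kept = []
    for resource, grp in incidence.groupby("resource", sort=True):
        if resource in critical or grp["fraction"].max() >= min_usage_fraction:
            kept.append(resource)
    kept.extend(sorted(critical - set(incidence["resource"])))
    return sorted(set(kept))


def typical_usage(records: Sequence[PhaseRecord],
                  standard_turnover_minutes: float | None = None,
                  turnover_activity: str | None = None,
                  usage_quantile: float = 0.5) -> float:
    """Typical per-case consumption for one (service, activity, resource,
    location) cell: median duration x mean quantity, in unit-minutes.

    Phase V (turnover) uses the hospital's standard turnover duration
    instead of recorded durations; pass the activity id via
    ``turnover_activity``. ``usage_quantile`` generalizes the median for
    conservative planning (0.5 reproduces the default behavior).
    """
    if not records:
        raise ValueError("typical_usage requires at least one record")
    quantities = np.array([r.quantity for r in records], dtype=float)
    mean_q = float(quantities.mean())
    is_turnover = (turnover_activity is not None
                   and all(r.activity == turnover_activity for r in records))
    if is_turnover:
        if standard_turnover_minutes is None:
            raise ValueError("turnover phase requires standard_turnover_minutes")
        duration = float(standard_turnover_minutes)
    else:
        durations = np.array([r.duration_minutes for r in records], dtype=float)
        duration = float(np.quantile(durations, usage_quantile))
    return duration * mean_q


def daily_capacity(availability_hours_per_day: float, units: float) -> float:
    """Hours of resource time available per day: availability x quantity."""
    if availability_hours_per_day < 0 or units < 0:
        raise ValueError("inputs must be >= 0")
    return availability_hours_per_day * units


def annualize(daily: float, horizon_days: int) -> float:
    """Scale a daily capacity to the model horizon."""
    if daily < 0 or horizon_days < 0:
        raise ValueError("inputs must be >= 0")
    return daily * horizon_days


def segment_capacity(total_capacity: float, usage: pd.DataFrame,
                     strategy: Literal["proportional", "manual", "peak"] = "proportional",
                     manual_share: float | None = None) -> tuple[float, dict]:
    """Portion of a resource's capacity available to the studied services.

    Shared resources also serve out-of-scope work; the in-scope share is
    inferred from historical utilization. ``usage`` has columns time (any
    consistent unit) and in_scope (bool). Strategies:

    * ``proportional`` — share = in-scope time / total time;
    * ``manual`` — use ``manual_share`` directly;
    * ``peak`` — share = in-scope time / peak-period total, via an optional
      ``period`` column (falls back to proportional without one).

    Returns (capacity, log dict recording the rule and share applied).
    """
    if strategy == "manual":
        if manual_share is None or not 0 <= manual_share <= 1:
            raise ValueError("manual strategy requires manual_share in [0, 1]")
        share = manual_share
    else:
        total_time = float(usage["time"].sum())
        if total_time <= 0:
            raise ValueError("zero historical usage; supply a manual share instead")
        in_scope = float(usage.loc[usage["in_scope"], "time"].sum())
        if strategy == "peak" and "period" in usage.columns:
            by_period = usage.groupby("period")["time"].sum()
            peak = float(by_period.max())
            share = min(in_scope / peak, 1.0) if peak > 0 else 0.0
        else:
            share = in_scope / total_time
    log = {"strategy": strategy, "share": share, "total_capacity": total_capacity}
    if share == 0.0:
        log["warning"] = "no in-scope historical usage; segmented capacity is zero"
    return total_capacity * share, log


@dataclass(frozen=True)
class SurgeonClass:
    id: str
    specialties: frozenset[str]
    members: tuple[str, ...]
    capacity_minutes: float


def surgeon_classes(roster: SurgeonRoster) -> tuple[list[SurgeonClass], dict[str, list[str]]]:
    """Partition surgeons into classes by identical specialty sets.

    Two surgeons share a class iff they can perform exactly the same set
    of specialties; the class capacity pools its members'. Also returns
    the substitution sets S: specialty -> class ids able to serve it.
    """
    if not roster.specialties:
        raise ValueError("roster is empty")
    groups: dict[frozenset[str], list[str]] = {}
    for surgeon in sorted(roster.specialties):
        groups.setdefault(frozenset(roster.specialties[surgeon]), []).append(surgeon)
    classes = []
    for spec_set in sorted(groups, key=lambda s: tuple(sorted(s))):
        members = tuple(groups[spec_set])
        cap = sum(roster.capacity_minutes.get(s, 0.0) for s in members)
        cid = "class_" + "+".join(sorted(spec_set))
        classes.append(SurgeonClass(cid, spec_set, members, cap))
    subs: dict[str, list[str]] = {}
    for cls in classes:
        for q in sorted(cls.specialties):
            subs.setdefault(q, []).append(cls.id)
    return classes, subs


def average_profitability(revenue: pd.DataFrame, cost: pd.DataFrame,
                          default_cost_from: str | None = None) -> Profitability:
    """Average revenue minus average service cost per (service, location).

    ``revenue`` and ``cost`` have columns service, location, amount (one
    row per observation; averaging happens here). When a location has
    revenue but no cost records, ``default_cost_from`` names the location
    whose average cost stands in — the study convention of carrying the
    academic center's cost over to the community.
    """
    rev_mean = revenue.groupby(["service", "location"])["amount"].mean()
    cost_mean = cost.groupby(["service", "location"])["amount"].mean()
    pi: dict[tuple[str, str], float] = {}
    rev_d: dict[tuple[str, str], float] = {}
    cost_d: dict[tuple[str, str], float] = {}
    for (p, l), r in rev_mean.items():
        if (p, l) in cost_mean.index:
            c = float(cost_mean[(p, l)])
        elif default_cost_from is not None and (p, default_cost_from) in cost_mean.index:
            c = float(cost_mean[(p, default_cost_from)])
        else:
            raise ValueError(f"no cost recorded for ({p!r}, {l!r}) and no default location")
        rev_d[(p, l)] = float(r)
        cost_d[(p, l)] = c
        pi[(p, l)] = float(r) - c
    return Profitability(pi=pi, revenue=rev_d, service_cost=cost_d)
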