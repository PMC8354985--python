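"""Traditional cost-accounting valuation and the myopic priority allocation.

The comparator values each service by *net contribution* = revenue minus
allocated cost, where allocated cost adds a time-driven labor allocation
(labor rate x time on the allocation-basis resource) to the direct service
cost. A myopic manager then admits demand greedily in decreasing net
contribution order until a hard capacity binds. Contrasting this with the
RNVC-optimal LP solution exposes how allocated costs invert priorities:
a service can look cheaper per case yet crowd out more value because it
occupies scarce resources longer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model import Mobility, NetworkModel
from .lp import Solution, solve
from .units import to_minutes

__all__ = [
    "AllocationRule",
    "labor_rate_from_capacity",
    "allocated_cost",
    "net_contribution_ranking",
    "myopic_allocation",
    "MyopicAllocation",
    "comparison_report",
]


@dataclass(frozen=True)
class AllocationRule:
    """Single-basis time-driven allocation: labor dollars per unit of basis-resource time."""

    labor_rate: float
    basis_resource: str
    #: unit the rate is quoted in (e.g. "hour" for $/OR-hour)
    rate_time_unit: str = "hour"

    def __post_init__(self):
        if self.labor_rate < 0:
            raise ValueError("labor_rate must be >= 0")


def labor_rate_from_capacity(total_labor_cost: float, effective_capacity: float) -> float:
    """Labor cost per time unit implied by spreading a committed labor budget
    over the effective capacity it staffs (e.g. $300K over 1500 OR-hours -> $200/h)."""
    if effective_capacity <= 0:
        raise ValueError("effective_capacity must be > 0")
    if total_labor_cost < 0:
        raise ValueError("total_labor_cost must be >= 0")
    return total_labor_cost / effective_capacity


def _basis_usage_minutes(model: NetworkModel, service: str, rule: AllocationRule) -> float:
    total = 0.0
    found = False
    for (p, _a, r, _l), u in model.usage.items():
        if p == service and r == rule.basis_resource:
            total += u
            found = True
    if not found:
        raise ValueError(
            f"service {service!r} has no usage entry on basis resource {rule.basis_resource!r}"
        )
    return total


def _mean_over_locations(d: dict[tuple[str, str], float], service: str) -> float:
    vals = [v for (p, _l), v in d.items() if p == service]
    if not vals:
        raise ValueError(f"no financial figure recorded for service {service!r}")
    return sum(vals) / len(vals)


def allocated_cost(service: str, rule: AllocationRule, model: NetworkModel) -> float:
    """Direct service cost plus the time-driven labor allocation, per case."""
    direct = _mean_over_locations(model.profitability.service_cost, service)
    minutes = _basis_usage_minutes(model, service, rule)
    basis_time = minutes / to_minutes(1.0, rule.rate_time_unit)
    return direct + rule.labor_rate * basis_time


def net_contribution_ranking(model: NetworkModel, rule: AllocationRule) -> pd.DataFrame:
    """Services ordered by net contribution (revenue - allocated cost), descending.

    Ties break toward the lower direct service cost, then lexicographic id.
    """
    rows = []
    for svc in model.services:
        revenue = _mean_over_locations(model.profitability.revenue, svc.id)
        cost = _mean_over_locations(model.profitability.service_cost, svc.id)
        alloc = allocated_cost(svc.id, rule, model)
        rows.append({
            "service": svc.id,
            "revenue": revenue,
            "service_cost": cost,
            "allocated_cost": alloc,
            "net_contribution": revenue - alloc,
        })
    df = pd.DataFrame(rows).sort_values(
        by=["net_contribution", "service_cost", "service"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank_traditional"] = df.index + 1
    return df


@dataclass
class MyopicAllocation:
    volumes: dict[tuple[str, str], float]
    leaked: dict[str, float]

    def volume_of(self, service: str) -> float:
        return sum(v for (p, _l), v in self.volumes.items() if p == service)


def myopic_allocation(model: NetworkModel, ranking: pd.DataFrame) -> MyopicAllocation:
    """Greedy continuous admission in ranking order.

    Each service in turn takes the largest volume feasible under every
    remaining hard capacity (min over binding resources of remaining
    capacity / per-case usage) and its demand bounds, location by location
    (academic first). Unserved upper-bound demand is the leak.
    """
    order = list(ranking["service"])
    missing = set(model.service_ids()) - set(order)
    if missing:
        raise ValueError(f"ranking does not cover services {sorted(missing)}")

    remaining: dict[tuple[str, str | None], float] = {}
    for res in model.resources:
        if not res.hard_constraint:
            continue
        loc = res.location if res.mobility is Mobility.fixed else None
        remaining[(res.id, loc)] = res.capacity

    amc = model.academic_location().id
    loc_order = [amc] + sorted(l for l in model.location_ids() if l != amc)

    volumes: dict[tuple[str, str], float] = {}
    leaked: dict[str, float] = {}
    for p in order:
        demand_left = model.demand.net_up(p)
        served = 0.0
        for l in loc_order:
            if (p, l) not in model.profitability.pi:
                continue
            cap_left = min(model.demand.loc_up(p, l), demand_left - served)
            if cap_left <= 0:
                continue
            per_case: dict[tuple[str, str | None], float] = {}
            for (pp, _a, r, ll), u in model.usage.items():
                if pp != p or ll != l or u == 0.0:
                    continue
                res = model.resource(r)
                if not res.hard_constraint:
                    continue
                key = (r, res.location if res.mobility is Mobility.fixed else None)
                if key in remaining:
                    per_case[key] = per_case.get(key, 0.0) + u
            vol = cap_left
            for key, u in per_case.items():
                vol = min(vol, remaining[key] / u)
            if not math.isfinite(vol):
                # demand and every touched resource unbounded: nothing limits
                # admission; treat as serving no leak-relevant volume
                vol = 0.0
            vol = max(vol, 0.0)
            for key, u in per_case.items():
                remaining[key] -= vol * u
            volumes[(p, l)] = volumes.get((p, l), 0.0) + vol
            served += vol
        upper = model.demand.net_up(p)
        if not math.isfinite(upper):
            upper = sum(model.demand.loc_up(p, l) for l in loc_order
                        if (p, l) in model.profitability.pi)
        leaked[p] = max(upper - served, 0.0) if math.isfinite(upper) else 0.0
    return MyopicAllocation(volumes=volumes, leaked=leaked)


def comparison_report(model: NetworkModel, rule: AllocationRule,
                      optimal: Solution | None = None) -> pd.DataFrame:
    """Side-by-side of the traditional ranking and the LP's marginal preference.

    ``lp_marginal_signal`` is the sign of the optimal-minus-myopic volume
    change per service; a service is flagged as a disagreement when some
    service ranked below it carries a strictly higher signal (the
    traditional order inverts the LP's preference).
    """
    ranking = net_contribution_ranking(model, rule)
    myo = myopic_allocation(model, ranking)
    if optimal is None:
        optimal = solve(model)
    if optimal.status != "optimal":
        raise ValueError("comparison requires an optimal LP solution")

    signals = {}
    for p in model.service_ids():
        opt_vol = sum(v for (pp, _l), v in optimal.x.items() if pp == p)
        delta = opt_vol - myo.volume_of(p)
        tol = max(1e-6 * max(myo.volume_of(p), 1.0), 1e-9)
        signals[p] = 1 if delta > tol else (-1 if delta < -tol else 0)

    df = ranking.copy()
    df["lp_marginal_signal"] = df["service"].map(signals)
    sig = list(df["lp_marginal_signal"])
    disagree = []
    for i in range(len(sig)):
        worse_below = any(s > sig[i] for s in sig[i + 1:])
        better_above = any(s < sig[i] for s in sig[:i])
        disagree.append(worse_below or better_above)
    df["disagreement"] = disagree
    return df
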