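"""Domain types for a multi-site surgical care network.

The network offers a set of surgical *services* at one or more *locations*.
Each case of a service executes a sequence of *activities* (the phases of
the surgical path: pre-operative care, surgery, post-anesthesia care, ward
stay, and room turnover), and each activity consumes *resources* for some
time. Capacity and usage are both measured in time-equivalent units
(quantity x duration), stored internally in minutes.

Resources come in three mobility classes:

* **fixed** — tied to one location (operating rooms, ward beds, supplies);
* **flexible** — a single pooled capacity shared across the network;
* **substitutable** — members of a capability pool (surgeon classes) whose
  time must additionally be *deployed* to a specialty requirement, an
  activity and a location before cases can consume it.

Profitability of a service is revenue net of variable cost (RNVC):
average revenue minus average direct variable cost per case. Labor and
overhead are never allocated per case; they enter only as capacity or as
an inert network-building-cost scalar used for bottom-line reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "LocationKind",
    "ResourceCategory",
    "Mobility",
    "Location",
    "Service",
    "Activity",
    "Resource",
    "UsageMatrix",
    "Profitability",
    "DemandBounds",
    "NetworkModel",
    "Violation",
    "validate_model",
    "build_worked_example",
]


class LocationKind(str, Enum):
    academic = "academic"
    community = "community"


class ResourceCategory(str, Enum):
    #: equipment and supplies
    A = "A"
    #: physical infrastructure (operating rooms, bays, ward beds)
    B = "B"
    #: staff (surgeon classes)
    C = "C"


class Mobility(str, Enum):
    fixed = "fixed"
    flexible = "flexible"
    substitutable = "substitutable"


@dataclass(frozen=True)
class Location:
    id: str
    kind: LocationKind = LocationKind.academic
    #: default hours/day a resource at this location is available; a
    #: resource may override this through its own capacity figure
    daily_operating_hours: float | None = None


@dataclass(frozen=True)
class Service:
    id: str
    specialty: str
    department: str = ""
    #: typical inpatient length of stay, days per case
    length_of_stay_days: float = 0.0


@dataclass(frozen=True)
class Activity:
    id: str
    #: phase index along the surgical path (1..5)
    ordinal: int
    #: False for turnover: the room is busy but the patient is not present
    concurrent_with_patient: bool = True


@dataclass(frozen=True)
class Resource:
    id: str
    category: ResourceCategory
    mobility: Mobility
    #: capacity over the model horizon, minutes (time-equivalent units)
    capacity: float
    #: unit the capacity was declared in; used for reporting only
    capacity_unit: str = "min"
    #: required iff fixed
    location: str | None = None
    #: specialties this (substitutable) resource can serve; required iff substitutable
    capability_set: frozenset[str] = frozenset()
    #: False turns the resource into a reporting-only resource: its
    #: utilization is tracked but it never constrains the LP
    hard_constraint: bool = True


class UsageMatrix:
    """Sparse per-case resource consumption u[service, activity, resource, location].

    Entries are minutes of the resource consumed by one case of the service
    during the activity at the location; absent entries are zero.
    """

    def __init__(self, entries: Mapping[tuple[str, str, str, str], float] | None = None):
        self._u: dict[tuple[str, str, str, str], float] = dict(entries or {})

    def set(self, service: str, activity: str, resource: str, location: str, minutes: float) -> None:
        self._u[(service, activity, resource, location)] = float(minutes)

    def get(self, service: str, activity: str, resource: str, location: str) -> float:
        return self._u.get((service, activity, resource, location), 0.0)

    def items(self):
        return self._u.items()

    def __len__(self) -> int:
        return len(self._u)

    def __eq__(self, other) -> bool:
        return isinstance(other, UsageMatrix) and self._u == other._u

    def total_for_resource(self, resource: str, location: str | None = None) -> dict[tuple[str, str], float]:
        """Per-(service, location) minutes on *resource*, summed over activities."""
        out: dict[tuple[str, str], float] = {}
        for (p, a, r, l), v in self._u.items():
            if r != resource or (location is not None and l != location):
                continue
            out[(p, l)] = out.get((p, l), 0.0) + v
        return out


@dataclass
class Profitability:
    """Per-case RNVC margin pi[p, l] = average revenue - average service cost.

    Revenue and service cost are kept when known so the traditional
    comparator can re-derive allocated costs; ``pi`` is authoritative.
    """

    pi: dict[tuple[str, str], float] = field(default_factory=dict)
    revenue: dict[tuple[str, str], float] = field(default_factory=dict)
    service_cost: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_revenue_cost(
        cls,
        revenue: Mapping[tuple[str, str], float],
        service_cost: Mapping[tuple[str, str], float],
    ) -> "Profitability":
        pi = {k: revenue[k] - service_cost.get(k, 0.0) for k in revenue}
        return cls(pi=pi, revenue=dict(revenue), service_cost=dict(service_cost))


#: sentinel for an absent (infinite) upper bound
UNBOUNDED = math.inf


@dataclass
class DemandBounds:
    """Volume limits per horizon, at network and at location level."""

    network_lower: dict[str, float] = field(default_factory=dict)
    network_upper: dict[str, float] = field(default_factory=dict)
    location_lower: dict[tuple[str, str], float] = field(default_factory=dict)
    location_upper: dict[tuple[str, str], float] = field(default_factory=dict)

    def net_lo(self, p: str) -> float:
        return self.network_lower.get(p, 0.0)

    def net_up(self, p: str) -> float:
        return self.network_upper.get(p, UNBOUNDED)

    def loc_lo(self, p: str, l: str) -> float:
        return self.location_lower.get((p, l), 0.0)

    def loc_up(self, p: str, l: str) -> float:
        return self.location_upper.get((p, l), UNBOUNDED)


@dataclass
class NetworkModel:
    """A complete instance of the network allocation problem."""

    locations: list[Location]
    services: list[Service]
    activities: list[Activity]
    resources: list[Resource]
    usage: UsageMatrix
    profitability: Profitability
    demand: DemandBounds
    horizon_days: int = 365
    #: fixed/indirect cost of capacity (labor, overhead); reporting only,
    #: never allocated per case
    network_building_cost: float = 0.0

    # -- index helpers -------------------------------------------------
    def location_ids(self) -> list[str]:
        return [l.id for l in self.locations]

    def service_ids(self) -> list[str]:
        return [p.id for p in self.services]

    def service(self, pid: str) -> Service:
        return self._by_id(self.services, pid)

    def resource(self, rid: str) -> Resource:
        return self._by_id(self.resources, rid)

    def activity(self, aid: str) -> Activity:
        return self._by_id(self.activities, aid)

    def location(self, lid: str) -> Location:
        return self._by_id(self.locations, lid)

    @staticmethod
    def _by_id(seq, ident):
        for item in seq:
            if item.id == ident:
                return item
        raise KeyError(ident)

    def specialty_of(self, service_id: str) -> str:
        return self.service(service_id).specialty

    def resources_by_mobility(self, mobility: Mobility) -> list[Resource]:
        return [r for r in self.resources if r.mobility is mobility]

    def substitution_sets(self) -> dict[str, list[str]]:
        """S(q): substitutable resource ids able to serve specialty requirement q."""
        out: dict[str, list[str]] = {}
        for r in self.resources_by_mobility(Mobility.substitutable):
            for q in sorted(r.capability_set):
                out.setdefault(q, []).append(r.id)
        return out

    def academic_location(self) -> Location:
        for l in self.locations:
            if l.kind is LocationKind.academic:
                return l
        return self.locations[0]


@dataclass(frozen=True)
class Violation:
    record: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.record}: [{self.rule}] {self.message}"


def validate_model(model: NetworkModel) -> list[Violation]:
    """Check every type invariant and referential-integrity rule.

    Returns an empty list iff the instance is valid. Validation reports
    and never raises.
    """
    v: list[Violation] = []

    def dup_check(items: Iterable, kind: str):
        seen = set()
        for item in items:
            if item.id in seen:
                v.append(Violation(f"{kind}:{item.id}", "unique-id", f"duplicate {kind} id {item.id!r}"))
            seen.add(item.id)
        return seen

    loc_ids = dup_check(model.locations, "location")
    svc_ids = dup_check(model.services, "service")
    act_ids = dup_check(model.activities, "activity")
    res_ids = dup_check(model.resources, "resource")

    if not model.locations:
        v.append(Violation("model", "nonempty", "at least one location is required"))
    if not model.services:
        v.append(Violation("model", "nonempty", "at least one service is required"))

    for loc in model.locations:
        if loc.daily_operating_hours is not None and loc.daily_operating_hours <= 0:
            v.append(Violation(f"location:{loc.id}", "positive-hours",
                               f"daily_operating_hours must be > 0, got {loc.daily_operating_hours}"))

    for svc in model.services:
        if svc.length_of_stay_days < 0:
            v.append(Violation(f"service:{svc.id}", "nonneg-los",
                               f"length_of_stay_days must be >= 0, got {svc.length_of_stay_days}"))

    for res in model.resources:
        if res.capacity < 0:
            v.append(Violation(f"resource:{res.id}", "nonneg-capacity",
                               f"capacity must be >= 0, got {res.capacity}"))
        if res.mobility is Mobility.fixed:
            if res.location is None:
                v.append(Violation(f"resource:{res.id}", "fixed-needs-location",
                                   "fixed resource must name exactly one location"))
            elif res.location not in loc_ids:
                v.append(Violation(f"resource:{res.id}", "ref-location",
                                   f"location {res.location!r} is not declared"))
        else:
            if res.location is not None:
                v.append(Violation(f"resource:{res.id}", "mobile-no-location",
                                   f"{res.mobility.value} resource must not carry a location"))
        if res.mobility is Mobility.substitutable and not res.capability_set:
            v.append(Violation(f"resource:{res.id}", "substitutable-needs-capabilities",
                               "substitutable resource must declare a nonempty capability_set"))

    specialties = {s.specialty for s in model.services}
    for res in model.resources_by_mobility(Mobility.substitutable):
        unknown = set(res.capability_set) - specialties
        if unknown:
            v.append(Violation(f"resource:{res.id}", "ref-specialty",
                               f"capability specialties {sorted(unknown)} match no declared service specialty"))

    for (p, a, r, l), u in model.usage.items():
        key = f"usage:({p},{a},{r},{l})"
        if u < 0:
            v.append(Violation(key, "nonneg-usage", f"usage must be >= 0, got {u}"))
        if p not in svc_ids:
            v.append(Violation(key, "ref-service", f"service {p!r} is not declared"))
        if a not in act_ids:
            v.append(Violation(key, "ref-activity", f"activity {a!r} is not declared"))
        if r not in res_ids:
            v.append(Violation(key, "ref-resource", f"resource {r!r} is not declared"))
        if l not in loc_ids:
            v.append(Violation(key, "ref-location", f"location {l!r} is not declared"))

    for (p, l), val in model.profitability.pi.items():
        key = f"profitability:({p},{l})"
        if not math.isfinite(val):
            v.append(Violation(key, "finite-pi", f"pi must be finite, got {val}"))
        if p not in svc_ids:
            v.append(Violation(key, "ref-service", f"service {p!r} is not declared"))
        if l not in loc_ids:
            v.append(Violation(key, "ref-location", f"location {l!r} is not declared"))

    d = model.demand
    for p in svc_ids:
        lo, up = d.net_lo(p), d.net_up(p)
        if lo < 0 or lo > up:
            v.append(Violation(f"demand-network:{p}", "bound-order",
                               f"need 0 <= lower <= upper, got [{lo}, {up}]"))
        loc_up_sum = sum(d.loc_up(p, l) for l in loc_ids)
        if loc_up_sum < lo:
            v.append(Violation(f"demand-network:{p}", "infeasible-by-construction",
                               f"sum of location upper bounds {loc_up_sum} < network lower bound {lo}"))
    for (p, l) in set(d.location_lower) | set(d.location_upper):
        lo, up = d.loc_lo(p, l), d.loc_up(p, l)
        key = f"demand:({p},{l})"
        if lo < 0 or lo > up:
            v.append(Violation(key, "bound-order", f"need 0 <= lower <= upper, got [{lo}, {up}]"))
        if p not in svc_ids:
            v.append(Violation(key, "ref-service", f"service {p!r} is not declared"))
        if l not in loc_ids:
            v.append(Violation(key, "ref-location", f"location {l!r} is not declared"))

    for (p, l), up in d.location_upper.items():
        if up > 0 and math.isfinite(up) and (p, l) not in model.profitability.pi:
            v.append(Violation(f"profitability:({p},{l})", "pi-required",
                               "pi must be defined wherever the location demand upper bound is positive"))

    return v


def build_worked_example() -> NetworkModel:
    """The two-service, one-location teaching instance.

    One operating room adds 1500 operating hours over the year and a
    nursing team costing $300K (network building cost, never allocated per
    case). Floor beds provide 800 bed-days. Both services reimburse $1500
    per case; service I takes 120 OR-minutes and $100 of supplies, service
    II takes 60 OR-minutes and $200 of supplies; each occupies one bed-day.
    Demand tops out at 500 (I) and 400 (II) cases.
    """
    loc = Location("main", LocationKind.academic)
    services = [
        Service("I", specialty="general", department="surgery", length_of_stay_days=1.0),
        Service("II", specialty="general", department="surgery", length_of_stay_days=1.0),
    ]
    activities = [
        Activity("surgery", ordinal=2),
        Activity("ward_stay", ordinal=4),
    ]
    resources = [
        Resource("operating_room", ResourceCategory.B, Mobility.fixed,
                 capacity=1500 * 60.0, capacity_unit="hour", location="main"),
        Resource("floor_beds", ResourceCategory.B, Mobility.fixed,
                 capacity=800 * 1440.0, capacity_unit="day", location="main"),
    ]
    usage = UsageMatrix({
        ("I", "surgery", "operating_room", "main"): 120.0,
        ("II", "surgery", "operating_room", "main"): 60.0,
        ("I", "ward_stay", "floor_beds", "main"): 1440.0,
        ("II", "ward_stay", "floor_beds", "main"): 1440.0,
    })
    profitability = Profitability.from_revenue_cost(
        revenue={("I", "main"): 1500.0, ("II", "main"): 1500.0},
        service_cost={("I", "main"): 100.0, ("II", "main"): 200.0},
    )
    demand = DemandBounds(
        location_lower={("I", "main"): 0.0, ("II", "main"): 0.0},
        location_upper={("I", "main"): 500.0, ("II", "main"): 400.0},
    )
    return NetworkModel(
        locations=[loc],
        services=services,
        activities=activities,
        resources=resources,
        usage=usage,
        profitability=profitability,
        demand=demand,
        horizon_days=365,
        network_building_cost=300_000.0,
    )
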