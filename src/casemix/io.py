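"""Reading and writing instance directories and solution documents.

An instance directory holds UTF-8 CSV files with mandatory header rows:
``locations.csv``, ``services.csv``, ``activities.csv``, ``resources.csv``,
``usage.csv``, ``profitability.csv``, ``demand.csv``, ``demand_network.csv``
and a ``config.yaml`` with the horizon and the network building cost.
Infinite demand bounds are written as the explicit sentinel ``unbounded``
(never a large number). Writing a model and re-reading it round-trips to
an identical instance.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd
import yaml

from .lp import Solution, solution_to_json_dict
from .model import (Activity, DemandBounds, Location, LocationKind, Mobility,
                    NetworkModel, Profitability, Resource, ResourceCategory,
                    Service, UsageMatrix)
from .units import from_minutes, to_minutes

__all__ = ["write_model", "read_model", "write_solution", "write_run_manifest"]

UNBOUNDED_SENTINEL = "unbounded"


def _bound_str(v: float) -> str:
    return UNBOUNDED_SENTINEL if math.isinf(v) else repr(float(v))


def _bound_val(s) -> float:
    if isinstance(s, str) and s.strip().lower() == UNBOUNDED_SENTINEL:
        return math.inf
    return float(s)


def write_model(model: NetworkModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([
        {"id": l.id, "kind": l.kind.value,
         "daily_operating_hours": "" if l.daily_operating_hours is None else l.daily_operating_hours}
        for l in model.locations
    ]).to_csv(d / "locations.csv", index=False)

    pd.DataFrame([
        {"id": s.id, "specialty": s.specialty, "department": s.department,
         "length_of_stay_days": s.length_of_stay_days}
        for s in model.services
    ]).to_csv(d / "services.csv", index=False)

    pd.DataFrame([
        {"id": a.id, "ordinal": a.ordinal,
         "concurrent_with_patient": a.concurrent_with_patient}
        for a in model.activities
    ]).to_csv(d / "activities.csv", index=False)

    pd.DataFrame([
        {"id": r.id, "category": r.category.value, "mobility": r.mobility.value,
         "location": r.location or "",
         "capacity": from_minutes(r.capacity, r.capacity_unit),
         "capacity_unit": r.capacity_unit,
         "capability_set": ";".join(sorted(r.capability_set)),
         "hard_constraint": r.hard_constraint}
        for r in model.resources
    ]).to_csv(d / "resources.csv", index=False)

    pd.DataFrame([
        {"service": p, "activity": a, "resource": r, "location": l,
         "usage": u, "usage_unit": "min"}
        for (p, a, r, l), u in sorted(model.usage.items())
    ], columns=["service", "activity", "resource", "location", "usage",
                "usage_unit"]).to_csv(d / "usage.csv", index=False)

    prof = model.profitability
    pd.DataFrame([
        {"service": p, "location": l,
         "revenue": prof.revenue.get((p, l), ""),
         "service_cost": prof.service_cost.get((p, l), ""),
         "pi": prof.pi[(p, l)]}
        for (p, l) in sorted(prof.pi)
    ]).to_csv(d / "profitability.csv", index=False)

    dm = model.demand
    keys = sorted(set(dm.location_lower) | set(dm.location_upper))
    pd.DataFrame([
        {"service": p, "location": l, "lower": _bound_str(dm.loc_lo(p, l)),
         "upper": _bound_str(dm.loc_up(p, l))}
        for (p, l) in keys
    ], columns=["service", "location", "lower", "upper"]).to_csv(
        d / "demand.csv", index=False)
    net_keys = sorted(set(dm.network_lower) | set(dm.network_upper))
    pd.DataFrame([
        {"service": p, "lower": _bound_str(dm.net_lo(p)),
         "upper": _bound_str(dm.net_up(p))}
        for p in net_keys
    ], columns=["service", "lower", "upper"]).to_csv(
        d / "demand_network.csv", index=False)

    with open(d / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"horizon_days": model.horizon_days,
                        "network_building_cost": model.network_building_cost}, fh)


def read_model(directory) -> NetworkModel:
    d = Path(directory)

    def load(name, **kw):
        return pd.read_csv(d / name, dtype=str, keep_default_na=False, **kw)

    locations = []
    for _, row in load("locations.csv").iterrows():
        hours = row.get("daily_operating_hours", "")
        locations.append(Location(
            row["id"], LocationKind(row["kind"]),
            None if hours in ("", None) else float(hours)))

    services = [Service(r["id"], r["specialty"], r.get("department", ""),
                        float(r["length_of_stay_days"]))
                for _, r in load("services.csv").iterrows()]

    activities = [Activity(r["id"], int(r["ordinal"]),
                           str(r["concurrent_with_patient"]).lower() in ("true", "1"))
                  for _, r in load("activities.csv").iterrows()]

    resources = []
    for _, r in load("resources.csv").iterrows():
        cap_set = frozenset(c for c in r.get("capability_set", "").split(";") if c)
        resources.append(Resource(
            r["id"], ResourceCategory(r["category"]), Mobility(r["mobility"]),
            capacity=to_minutes(float(r["capacity"]), r["capacity_unit"]),
            capacity_unit=r["capacity_unit"],
            location=r["location"] or None,
            capability_set=cap_set,
            hard_constraint=str(r["hard_constraint"]).lower() in ("true", "1")))

    usage = UsageMatrix()
    for _, r in load("usage.csv").iterrows():
        usage.set(r["service"], r["activity"], r["resource"], r["location"],
                  to_minutes(float(r["usage"]), r["usage_unit"]))

    pi, rev, cost = {}, {}, {}
    for _, r in load("profitability.csv").iterrows():
        key = (r["service"], r["location"])
        pi[key] = float(r["pi"])
        if r.get("revenue", "") != "":
            rev[key] = float(r["revenue"])
        if r.get("service_cost", "") != "":
            cost[key] = float(r["service_cost"])
    profitability = Profitability(pi=pi, revenue=rev, service_cost=cost)

    loc_lo, loc_up = {}, {}
    for _, r in load("demand.csv").iterrows():
        key = (r["service"], r["location"])
        loc_lo[key] = _bound_val(r["lower"])
        loc_up[key] = _bound_val(r["upper"])
    net_lo, net_up = {}, {}
    for _, r in load("demand_network.csv").iterrows():
        net_lo[r["service"]] = _bound_val(r["lower"])
        net_up[r["service"]] = _bound_val(r["upper"])
    demand = DemandBounds(network_lower=net_lo, network_upper=net_up,
                          location_lower=loc_lo, location_upper=loc_up)

    with open(d / "config.yaml", "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}

    return NetworkModel(locations=locations, services=services, activities=activities,
                        resources=resources, usage=usage, profitability=profitability,
                        demand=demand, horizon_days=int(cfg.get("horizon_days", 365)),
                        network_building_cost=float(cfg.get("network_building_cost", 0.0)))


def write_solution(solution: Solution, model: NetworkModel, path) -> None:
    doc = solution_to_json_dict(solution, model)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_run_manifest(path, inputs: list, config: dict) -> None:
    """Machine-readable record of a run: input file hashes and the echoed
    configuration, enough to reproduce the outputs."""
    from importlib.metadata import version, PackageNotFoundError
    try:
        pkg_version = version("casemix")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    hashes = {}
    for f in inputs:
        f = Path(f)
        if f.is_file():
            hashes[str(f)] = hashlib.sha256(f.read_bytes()).hexdigest()
    doc = {"casemix_version": pkg_version, "inputs_sha256": hashes, "config": config}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
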