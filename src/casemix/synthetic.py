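"""Seeded generator of synthetic network instances and raw records.

Emulates the data a hospital network would extract for this kind of
study — a service catalog, multi-site resources with capacities, per-case
phase records, encounter-level financials coded in an external system,
and leakage claims — with the generating parameters retained as ground
truth so estimators can be validated end to end. The generator is a
model of the study's data structures, not of patient-level operations:
volumes are aggregate, arrivals are not simulated.

Distributional choices (documented defaults, all overridable):
log-normal phase durations around a known median, truncated-normal
quantities and payments around known means, categorical external-code
draws from known conditional code distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import SurgeonRoster, surgeon_classes
from .model import (Activity, DemandBounds, Location, LocationKind, Mobility,
                    NetworkModel, Profitability, Resource, ResourceCategory,
                    Service, UsageMatrix, validate_model)

__all__ = ["GroundTruth", "generate_instance", "generate_raw_records"]

_SPECIALTIES = ["general", "colorectal", "breast", "endocrine",
                "bariatric", "esophageal", "hpb"]

#: baseline utilization targets per bottleneck profile (AMC, hard resources)
_PROFILES = {
    "or_bound": {"operating_room": 0.85, "preop_bays": 0.60, "recovery_bays": 0.40,
                 "ward_beds": 0.70, "surgeons": 0.62, "supplies": 0.30},
    "bed_bound": {"operating_room": 0.70, "preop_bays": 0.55, "recovery_bays": 0.40,
                  "ward_beds": 0.95, "surgeons": 0.62, "supplies": 0.30},
}

TURNOVER_MINUTES = 30.0


@dataclass
class GroundTruth:
    """Generating parameters frozen alongside the instance."""

    duration_medians: dict[tuple[str, str], float] = field(default_factory=dict)
    quantity_means: dict[tuple[str, str, str], float] = field(default_factory=dict)
    typical_usage: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    #: true conditional weights, external code -> {service: w}
    drg_map: dict[str, dict[str, float]] = field(default_factory=dict)
    icd9_map: dict[str, dict[str, float]] = field(default_factory=dict)
    #: code emission distributions, service -> {code: prob}
    drg_emission: dict[str, dict[str, float]] = field(default_factory=dict)
    icd9_emission: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_volumes: dict[str, float] = field(default_factory=dict)
    unmet_demand: dict[str, float] = field(default_factory=dict)
    revenue: dict[tuple[str, str], float] = field(default_factory=dict)
    service_cost: dict[tuple[str, str], float] = field(default_factory=dict)
    turnover_minutes: float = TURNOVER_MINUTES


def _emission_and_map(services: list[str], volumes: Mapping[str, float],
                      prefix: str, rng: np.random.Generator,
                      overlap: float) -> tuple[dict, dict]:
    """Per-service code distributions and the implied true conditional map.

    Service i emits code {prefix}{i} with probability 1 - overlap and its
    neighbor's code with probability overlap, so adjacent services share
    codes (the many-to-many structure the mapping exists for). The true
    map w[d -> p] follows from the joint code/service frequencies at the
    baseline volumes.
    """
    n = len(services)
    emission: dict[str, dict[str, float]] = {}
    joint: dict[str, dict[str, float]] = {}
    for i, p in enumerate(services):
        own, neigh = f"{prefix}{i:03d}", f"{prefix}{(i + 1) % n:03d}"
        ov = float(rng.uniform(0.5, 1.0) * overlap)
        emission[p] = {own: 1.0 - ov, neigh: ov} if n > 1 else {own: 1.0}
        for code, prob in emission[p].items():
            joint.setdefault(code, {})[p] = joint.get(code, {}).get(p, 0.0) + prob * volumes[p]
    cmap = {}
    for code, by_service in joint.items():
        total = sum(by_service.values())
        cmap[code] = {p: v / total for p, v in sorted(by_service.items())}
    return emission, cmap


def generate_instance(seed: int, n_services: int = 12, n_locations: int = 3,
                      n_specialties: int = 4, n_surgeons: int = 8,
                      bottleneck_profile: str = "or_bound",
                      leak_fraction: float = 0.15,
                      community_eligible_fraction: float = 0.6,
                      code_overlap: float = 0.3,
                      harden_ward_beds: bool = False,
                      horizon_days: int = 365) -> tuple[NetworkModel, GroundTruth]:
    """Build a complete synthetic instance with known ground truth.

    One academic center plus ``n_locations - 1`` community hospitals;
    capacities are placed so the baseline volumes are feasible and the
    requested ``bottleneck_profile`` pins which resource runs hottest.
    Ward beds are reporting-only unless ``harden_ward_beds``.
    Deterministic for a fixed seed.
    """
    if n_services < 1 or n_locations < 1 or n_specialties < 1 or n_surgeons < 1:
        raise ValueError("counts must be >= 1")
    if not 0 <= leak_fraction <= 1:
        raise ValueError("leak_fraction must lie in [0, 1]")
    if bottleneck_profile not in _PROFILES:
        raise ValueError(f"unknown bottleneck_profile {bottleneck_profile!r}")
    targets = _PROFILES[bottleneck_profile]

    ss = np.random.SeedSequence(seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(["structure", "usage", "finance", "demand", "roster", "codes"],
                   ss.spawn(6))}

    amc = Location("AMC", LocationKind.academic, daily_operating_hours=10.0)
    community = [Location(f"COM{i}", LocationKind.community, daily_operating_hours=9.0)
                 for i in range(1, n_locations)]
    locations = [amc] + community

    specialties = _SPECIALTIES[:min(n_specialties, len(_SPECIALTIES))]
    rng = streams["structure"]
    services = [Service(f"S{i:02d}", specialty=specialties[i % len(specialties)],
                        department=specialties[i % len(specialties)],
                        length_of_stay_days=float(rng.integers(1, 5)))
                for i in range(n_services)]
    activities = [
        Activity("preop", 1),
        Activity("surgery", 2),
        Activity("recovery", 3),
        Activity("ward_stay", 4),
        Activity("turnover", 5, concurrent_with_patient=False),
    ]

    truth = GroundTruth()
    u_rng = streams["usage"]
    for svc in services:
        truth.duration_medians[(svc.id, "preop")] = float(u_rng.uniform(30, 90))
        truth.duration_medians[(svc.id, "surgery")] = float(u_rng.uniform(60, 240))
        truth.duration_medians[(svc.id, "recovery")] = float(u_rng.uniform(30, 120))
        truth.quantity_means[(svc.id, "surgery", "supplies")] = float(u_rng.uniform(1.0, 3.0))

    d_rng = streams["demand"]
    baseline = {svc.id: float(d_rng.integers(100, 500)) for svc in services}
    truth.baseline_volumes = dict(baseline)
    truth.unmet_demand = {p: leak_fraction * v for p, v in baseline.items()}

    eligible_specs = set(
        streams["structure"].choice(
            specialties,
            size=max(1, int(round(community_eligible_fraction * len(specialties)))),
            replace=False,
        ).tolist()
    )

    f_rng = streams["finance"]
    for svc in services:
        cost = float(f_rng.uniform(300, 3000))
        rev = cost + float(f_rng.uniform(800, 8000))
        truth.revenue[(svc.id, amc.id)] = rev
        truth.service_cost[(svc.id, amc.id)] = cost
        for loc in community:
            if svc.specialty in eligible_specs:
                # community reimbursement differs; cost carried over from the AMC
                truth.revenue[(svc.id, loc.id)] = rev * float(f_rng.uniform(0.85, 1.10))
                truth.service_cost[(svc.id, loc.id)] = cost

    roster = SurgeonRoster(
        specialties={f"dr{i:02d}": frozenset(
            streams["roster"].choice(specialties,
                                     size=int(streams["roster"].integers(1, min(3, len(specialties)) + 1)),
                                     replace=False).tolist())
            for i in range(n_surgeons)},
        capacity_minutes={f"dr{i:02d}": float(streams["roster"].uniform(40_000, 70_000))
                          for i in range(n_surgeons)},
    )
    classes, subs_sets = surgeon_classes(roster)
    covered = set().union(*(c.specialties for c in classes))
    uncovered = [q for q in specialties if q not in covered]
    if uncovered:
        # guarantee every specialty is operable: one generalist class
        from .estimation import SurgeonClass
        classes.append(SurgeonClass("class_" + "+".join(sorted(uncovered)),
                                    frozenset(uncovered), ("dr_generalist",), 0.0))

    usage = UsageMatrix()
    offered: dict[str, list[str]] = {}
    for svc in services:
        locs = [amc.id] + [l.id for l in community if svc.specialty in eligible_specs]
        offered[svc.id] = locs
        class_for_spec = subs_sets.get(svc.specialty,
                                       [c.id for c in classes if svc.specialty in c.specialties])
        for l in locs:
            pre = truth.duration_medians[(svc.id, "preop")]
            surg = truth.duration_medians[(svc.id, "surgery")]
            rec = truth.duration_medians[(svc.id, "recovery")]
            qty = truth.quantity_means[(svc.id, "surgery", "supplies")]
            usage.set(svc.id, "preop", f"preop_bays_{l}", l, pre)
            usage.set(svc.id, "surgery", f"operating_room_{l}", l, surg)
            usage.set(svc.id, "surgery", f"supplies_{l}", l, surg * qty)
            usage.set(svc.id, "surgery", class_for_spec[0], l, surg)
            usage.set(svc.id, "turnover", f"operating_room_{l}", l, TURNOVER_MINUTES)
            usage.set(svc.id, "recovery", f"recovery_bays_{l}", l, rec)
            usage.set(svc.id, "ward_stay", f"ward_beds_{l}", l,
                      svc.length_of_stay_days * 1440.0)
    for (p, a, r, l), v in usage.items():
        truth.typical_usage[(p, a, r, l)] = v

    # -- capacities: place AMC capacity so baseline hits the profile targets
    def amc_load(resource: str) -> float:
        return sum(u * baseline[p] for (p, _a, r, l), u in usage.items()
                   if r == resource and l == amc.id)

    resources: list[Resource] = []
    kinds = [("operating_room", ResourceCategory.B, "hour"),
             ("preop_bays", ResourceCategory.B, "hour"),
             ("recovery_bays", ResourceCategory.B, "hour"),
             ("ward_beds", ResourceCategory.B, "day"),
             ("supplies", ResourceCategory.A, "hour")]
    for loc in locations:
        is_amc = loc.id == amc.id
        for base_name, cat, unit in kinds:
            rid = f"{base_name}_{loc.id}"
            if is_amc:
                cap = amc_load(rid) / targets[base_name]
            else:
                cap = amc_load(f"{base_name}_{amc.id}") * 0.5
            hard = not (base_name == "ward_beds" and not harden_ward_beds)
            resources.append(Resource(rid, cat, Mobility.fixed, capacity=cap,
                                      capacity_unit=unit, location=loc.id,
                                      hard_constraint=hard))

    # surgeon classes: capacity sized off each class's share of baseline load
    spec_load = {q: sum(truth.duration_medians[(p, "surgery")] * baseline[p]
                        for p in baseline if next(s.specialty for s in services if s.id == p) == q)
                 for q in specialties}
    n_covering = {q: max(1, len(subs_sets.get(q, []))) for q in specialties}
    for cls in classes:
        share = sum(spec_load.get(q, 0.0) / n_covering.get(q, 1)
                    for q in sorted(cls.specialties))
        cap = share / targets["surgeons"] if share > 0 else 10_000.0
        resources.append(Resource(cls.id, ResourceCategory.C, Mobility.substitutable,
                                  capacity=cap, capacity_unit="hour",
                                  capability_set=frozenset(cls.specialties)))

    profitability = Profitability.from_revenue_cost(truth.revenue, truth.service_cost)
    loc_upper = {}
    net_upper = {}
    for svc in services:
        p = svc.id
        loc_upper[(p, amc.id)] = baseline[p] * 1.2
        for l in offered[p]:
            if l != amc.id:
                loc_upper[(p, l)] = baseline[p] * 0.6
        net_upper[p] = baseline[p] * 1.2 + truth.unmet_demand[p]
    demand = DemandBounds(network_upper=net_upper, location_upper=loc_upper)

    model = NetworkModel(locations=locations, services=services, activities=activities,
                         resources=resources, usage=usage, profitability=profitability,
                         demand=demand, horizon_days=horizon_days,
                         network_building_cost=float(f_rng.uniform(1e6, 5e6)))

    service_ids = [s.id for s in services]
    truth.drg_emission, truth.drg_map = _emission_and_map(
        service_ids, baseline, "D", streams["codes"], code_overlap)
    truth.icd9_emission, truth.icd9_map = _emission_and_map(
        service_ids, baseline, "IC", streams["codes"], code_overlap)

    problems = validate_model(model)
    if problems:  # pragma: no cover - generator contract
        raise AssertionError(f"generated instance failed validation: {problems[:3]}")
    return model, truth


def _draw_codes(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> list[str]:
    codes = sorted(dist)
    probs = np.array([dist[c] for c in codes])
    probs = probs / probs.sum()
    return [codes[i] for i in rng.choice(len(codes), size=n, p=probs)]


def generate_raw_records(model: NetworkModel, truth: GroundTruth,
                         n_cases_per_service: int = 50, seed: int = 0,
                         duration_sigma: float = 0.25,
                         quantity_sigma: float = 0.10,
                         payment_sigma: float = 0.10) -> dict[str, pd.DataFrame]:
    """Draw raw record files consistent with the ground truth.

    Returns frames: ``phase_records`` (per-case phase durations and
    quantities at the academic center), ``encounters`` (ICD-9-coded
    payments and costs), ``drg_records`` (labeled code/service pairs on
    existing demand, the input the claims map is fitted from), and
    ``leakage`` (leaked claim counts by code and nearest location).

    Durations are log-normal around the true median (``duration_sigma`` =
    0 reproduces the truth exactly); quantities and payments are normal
    around the true mean, truncated at zero.
    """
    ss = np.random.SeedSequence(seed)
    rngs = {name: np.random.default_rng(child) for name, child in
            zip(["phase", "encounter", "leak"], ss.spawn(3))}
    amc = model.academic_location().id

    phase_rows = []
    rng = rngs["phase"]
    for svc in model.services:
        p = svc.id
        for i in range(n_cases_per_service):
            cid = f"{p}-c{i:04d}"
            for act, res_base in (("preop", "preop_bays"), ("surgery", "operating_room"),
                                  ("recovery", "recovery_bays")):
                med = truth.duration_medians[(p, act)]
                dur = med * float(np.exp(duration_sigma * rng.standard_normal()))
                phase_rows.append((cid, p, act, dur, f"{res_base}_{amc}", 1.0, amc))
            qmean = truth.quantity_means[(p, "surgery", "supplies")]
            qty = max(0.0, qmean * (1.0 + quantity_sigma * float(rng.standard_normal())))
            surg_med = truth.duration_medians[(p, "surgery")]
            dur = surg_med * float(np.exp(duration_sigma * rng.standard_normal()))
            phase_rows.append((cid, p, "surgery", dur, f"supplies_{amc}", qty, amc))
            phase_rows.append((cid, p, "ward_stay", svc.length_of_stay_days * 1440.0,
                               f"ward_beds_{amc}", 1.0, amc))
            phase_rows.append((cid, p, "turnover", truth.turnover_minutes,
                               f"operating_room_{amc}", 1.0, amc))
    phase_records = pd.DataFrame(phase_rows, columns=[
        "case_id", "service", "activity", "duration_minutes", "resource",
        "quantity", "location"])

    enc_rows = []
    drg_rows = []
    rng = rngs["encounter"]
    # financial and claims records mirror existing demand, so their counts
    # scale with baseline volume (the fitted conditional frequencies then
    # converge to the volume-weighted ground-truth maps)
    mean_b = (sum(truth.baseline_volumes.values()) / len(truth.baseline_volumes)
              if truth.baseline_volumes else 1.0)
    for svc in model.services:
        p = svc.id
        n_p = max(1, int(round(n_cases_per_service
                               * truth.baseline_volumes.get(p, mean_b) / mean_b)))
        rev = truth.revenue[(p, amc)]
        cost = truth.service_cost[(p, amc)]
        icd_codes = _draw_codes(rng, truth.icd9_emission[p], n_p)
        drg_codes = _draw_codes(rng, truth.drg_emission[p], n_p)
        for i in range(n_p):
            pay = max(0.0, rev * (1.0 + payment_sigma * float(rng.standard_normal())))
            c = max(0.0, cost * (1.0 + payment_sigma * float(rng.standard_normal())))
            enc_rows.append((f"{p}-e{i:04d}", icd_codes[i], pay, c, amc, p))
            drg_rows.append((drg_codes[i], p))
    encounters = pd.DataFrame(enc_rows, columns=[
        "encounter_id", "codes", "payment", "cost", "location", "service_if_known"])
    drg_records = pd.DataFrame(drg_rows, columns=["external_code", "service"])

    leak_counts: dict[tuple[str, str], int] = {}
    rng = rngs["leak"]
    loc_ids = model.location_ids()
    for p, unmet in truth.unmet_demand.items():
        n = int(round(unmet))
        if n == 0:
            continue
        for code in _draw_codes(rng, truth.drg_emission[p], n):
            loc = loc_ids[int(rng.integers(0, len(loc_ids)))]
            leak_counts[(code, loc)] = leak_counts.get((code, loc), 0) + 1
    leakage = pd.DataFrame(
        [(c, l, n) for (c, l), n in sorted(leak_counts.items())],
        columns=["external_code", "location", "count"])

    return {"phase_records": phase_records, "encounters": encounters,
            "drg_records": drg_records, "leakage": leakage}
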