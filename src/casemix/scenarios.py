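"""Declarative scenario engine for the three study designs.

* **baseline** — pin demand to the current volumes at the academic center,
  solve, and report utilization and the ward-bed requirement;
* **casemix_perturbation** — let each service's volume move within +-x%
  of baseline while total volume stays within +-y%, with bottleneck
  resources capped at their baseline usage; report the RNVC gain and the
  direction (+1/-1/0) each service's volume moves;
* **reallocation_recovery** — allow shifting up to realloc% of each
  service's academic-center volume to the community and recovering up to
  w% of its leaked demand anywhere in the network, swept over a grid.

Scenario construction is pure: the same spec and model always produce the
same LP (see ``canonical_form``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .lp import (LinearProgram, Solution, build_lp, compute_utilization, rnvc, solve)
from .model import DemandBounds, LocationKind, NetworkModel

__all__ = [
    "ScenarioSpec",
    "DirectionalChangeReport",
    "BaselineResult",
    "PerturbationResult",
    "RecoveryResult",
    "required_beds",
    "run_baseline",
    "run_casemix_perturbation",
    "run_reallocation_recovery",
    "run_scenario",
    "canonical_form",
]


@dataclass
class ScenarioSpec:
    """Declarative perturbation of demand bounds and capacity caps."""

    kind: str  # baseline | casemix_perturbation | reallocation_recovery
    x_pct: float = 0.0
    y_pct: float = 0.0
    w_pct: float = 0.0
    realloc_pct: float = 0.0
    realloc_grid: list[float] = field(default_factory=list)
    w_grid: list[float] = field(default_factory=list)
    bottleneck_caps: list[str] = field(default_factory=list)
    tolerance: float | None = None
    #: reserved for stochastic extensions; unused
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("baseline", "casemix_perturbation", "reallocation_recovery"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        for name in ("x_pct", "y_pct", "w_pct", "realloc_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        for name in ("realloc_grid", "w_grid"):
            for v in getattr(self, name):
                if not 0 <= v <= 100:
                    raise ValueError(f"{name} entries must lie in [0, 100], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class DirectionalChangeReport:
    """Sign of the volume move per (service, location group).

    ``codes[(p, g)]`` is +1 when the volume rose by more than the
    tolerance, -1 when it fell by more, else 0; ``deltas`` holds the raw
    case differences. The default tolerance is max(1e-6 x baseline, 1e-9)
    per service so that solver noise never flips a sign.
    """

    codes: dict[tuple[str, str], int] = field(default_factory=dict)
    deltas: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"service": p, "group": g, "code": c, "delta": self.deltas[(p, g)]}
                for (p, g), c in sorted(self.codes.items())]
        return pd.DataFrame(rows, columns=["service", "group", "code", "delta"])


def _tolerance(baseline: float, override: float | None) -> float:
    if override is not None:
        return override
    return max(1e-6 * baseline, 1e-9)


def directional_report(model: NetworkModel,
                       baseline: Mapping[tuple[str, str], float],
                       new: Mapping[tuple[str, str], float],
                       tolerance: float | None = None) -> DirectionalChangeReport:
    amc = model.academic_location().id
    rep = DirectionalChangeReport()
    groups = {l.id: ("AMC" if l.id == amc else "COM") for l in model.locations}
    for p in model.service_ids():
        agg_base: dict[str, float] = {"AMC": 0.0, "COM": 0.0}
        agg_new: dict[str, float] = {"AMC": 0.0, "COM": 0.0}
        for l, g in groups.items():
            agg_base[g] += baseline.get((p, l), 0.0)
            agg_new[g] += new.get((p, l), 0.0)
        for g in ("AMC", "COM"):
            delta = agg_new[g] - agg_base[g]
            tau = _tolerance(agg_base[g], tolerance)
            rep.deltas[(p, g)] = delta
            rep.codes[(p, g)] = 1 if delta > tau else (-1 if delta < -tau else 0)
    return rep


def required_beds(volumes: Mapping[str, float] | Mapping[tuple[str, str], float],
                  length_of_stay_days: Mapping[str, float],
                  horizon_days: int) -> float:
    """Lower bound on ward beds: sum of volume x length-of-stay bed-days
    spread over the horizon."""
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    total = 0.0
    for key, vol in volumes.items():
        p = key[0] if isinstance(key, tuple) else key
        if vol < 0:
            raise ValueError(f"negative volume for {key!r}")
        total += vol * length_of_stay_days.get(p, 0.0)
    return total / horizon_days


def _normalize_baseline(model: NetworkModel,
                        baseline_volumes: Mapping) -> dict[tuple[str, str], float]:
    """Accept {service: cases} (implicitly at the academic center) or
    {(service, location): cases}."""
    amc = model.academic_location().id
    out: dict[tuple[str, str], float] = {}
    for key, v in baseline_volumes.items():
        if isinstance(key, tuple):
            out[key] = float(v)
        else:
            out[(key, amc)] = float(v)
    return out


def _baseline_usage(model: NetworkModel, volumes: Mapping[tuple[str, str], float],
                    resource_ids: Iterable[str]) -> dict[str, float]:
    """Minutes each listed resource consumes at the baseline volumes."""
    wanted = set(resource_ids)
    out = {r: 0.0 for r in wanted}
    for (p, _a, r, l), u in model.usage.items():
        if r in wanted:
            out[r] += u * volumes.get((p, l), 0.0)
    return out


@dataclass
class BaselineResult:
    solution: Solution
    utilization: pd.DataFrame | None
    required_beds: float
    rnvc: float


def _pin_demand(model: NetworkModel,
                volumes: Mapping[tuple[str, str], float]) -> NetworkModel:
    lower = {}
    upper = {}
    for p in model.service_ids():
        for l in model.location_ids():
            v = volumes.get((p, l), 0.0)
            lower[(p, l)] = v
            upper[(p, l)] = v
    demand = DemandBounds(location_lower=lower, location_upper=upper)
    return dataclasses.replace(model, demand=demand)


def run_baseline(model: NetworkModel, baseline_volumes: Mapping) -> BaselineResult:
    """Solve with demand pinned to the current volumes and report loads.

    When the pinned volumes violate a hard capacity the solution comes
    back infeasible with a diagnosis naming the violated families.
    """
    vols = _normalize_baseline(model, baseline_volumes)
    pinned = _pin_demand(model, vols)
    sol = solve(pinned, build_lp(pinned, skip_validation=True))
    los = {s.id: s.length_of_stay_days for s in model.services}
    beds = required_beds(vols, los, model.horizon_days)
    if sol.status != "optimal":
        return BaselineResult(sol, None, beds, math.nan)
    return BaselineResult(sol, compute_utilization(sol, model), beds, rnvc(sol, pinned))


@dataclass
class PerturbationResult:
    solution: Solution
    rnvc: float
    baseline_rnvc: float
    gain: float
    directional: DirectionalChangeReport


def run_casemix_perturbation(model: NetworkModel, baseline_volumes: Mapping,
                             x_pct: float, y_pct: float,
                             bottleneck_caps: Iterable[str] = (),
                             tolerance: float | None = None) -> PerturbationResult:
    """Marginal case-mix study around the baseline.

    Per-service volumes may move within +-x% of baseline, total volume
    within +-y% of the baseline total, and each capped resource's
    capacity is replaced by its baseline usage so the study never assumes
    capacity beyond what current operations already consume.
    """
    vols = _normalize_baseline(model, baseline_volumes)
    base_net = {p: sum(v for (pp, _l), v in vols.items() if pp == p)
                for p in model.service_ids()}
    lo_f, up_f = 1 - x_pct / 100.0, 1 + x_pct / 100.0
    lower = {(p, l): vols.get((p, l), 0.0) * lo_f
             for p in model.service_ids() for l in model.location_ids()}
    upper = {(p, l): vols.get((p, l), 0.0) * up_f
             for p in model.service_ids() for l in model.location_ids()}
    demand = DemandBounds(
        network_lower={p: b * lo_f for p, b in base_net.items()},
        network_upper={p: b * up_f for p, b in base_net.items()},
        location_lower=lower, location_upper=upper,
    )
    scen_model = dataclasses.replace(model, demand=demand)

    total = sum(vols.values())
    total_row = ("total_volume",
                 {("x", p, l): 1.0 for (p, l) in vols
                  if (p, l) in model.profitability.pi},
                 total * (1 - y_pct / 100.0), total * (1 + y_pct / 100.0))
    caps = _baseline_usage(model, vols, bottleneck_caps)
    lp = build_lp(scen_model, extra_rows=[total_row], capacity_overrides=caps,
                  skip_validation=True)
    sol = solve(scen_model, lp)
    base_rnvc = sum(model.profitability.pi.get(k, 0.0) * v for k, v in vols.items())
    if sol.status != "optimal":
        return PerturbationResult(sol, math.nan, base_rnvc, math.nan,
                                  DirectionalChangeReport())
    gain = (sol.objective_rnvc - base_rnvc) / base_rnvc if base_rnvc else math.nan
    rep = directional_report(model, vols, sol.x, tolerance)
    return PerturbationResult(sol, sol.objective_rnvc, base_rnvc, gain, rep)


@dataclass
class RecoveryResult:
    #: one row per grid point: realloc_pct, w_pct, rnvc, gain, required_beds_amc
    surface: pd.DataFrame
    #: volumes at each grid point
    volumes: dict[tuple[float, float], dict[tuple[str, str], float]]
    #: directional report at the most permissive grid point
    directional: DirectionalChangeReport
    #: surgeon-class deployment (minutes by specialty and location) at the
    #: most permissive grid point
    surgeon_time: pd.DataFrame
    baseline_rnvc: float


def _recovery_model(model: NetworkModel, vols: Mapping[tuple[str, str], float],
                    unmet_net: Mapping[str, float], realloc_pct: float,
                    w_pct: float) -> NetworkModel:
    amc = model.academic_location().id
    lower: dict[tuple[str, str], float] = {}
    upper: dict[tuple[str, str], float] = {}
    net_lower: dict[str, float] = {}
    net_upper: dict[str, float] = {}
    for p in model.service_ids():
        b = vols.get((p, amc), 0.0)
        recover = (w_pct / 100.0) * unmet_net.get(p, 0.0)
        shift = (realloc_pct / 100.0) * b
        net_lower[p] = b
        net_upper[p] = b + recover
        lower[(p, amc)] = b - shift
        upper[(p, amc)] = b + recover
        for l in model.location_ids():
            if l == amc:
                continue
            lower[(p, l)] = 0.0
            upper[(p, l)] = (shift + recover) if (p, l) in model.profitability.pi else 0.0
    demand = DemandBounds(network_lower=net_lower, network_upper=net_upper,
                          location_lower=lower, location_upper=upper)
    return dataclasses.replace(model, demand=demand)


def surgeon_time_table(solution: Solution, model: NetworkModel) -> pd.DataFrame:
    """Deployed substitutable (surgeon-class) minutes by specialty and location."""
    agg: dict[tuple[str, str], float] = {}
    for (s, q, _a, l), v in solution.y.items():
        agg[(q, l)] = agg.get((q, l), 0.0) + v
    rows = [{"specialty": q, "location": l, "minutes": v}
            for (q, l), v in sorted(agg.items())]
    return pd.DataFrame(rows, columns=["specialty", "location", "minutes"])


def run_reallocation_recovery(model: NetworkModel, baseline_volumes: Mapping,
                              unmet_demand: Mapping, realloc_grid: Sequence[float],
                              w_grid: Sequence[float],
                              bottleneck_caps: Iterable[str] = (),
                              tolerance: float | None = None) -> RecoveryResult:
    """Sweep reallocation and leaked-demand recovery over a grid.

    At each (realloc%, w%): the academic center may shed up to realloc%
    of each service's baseline volume to the community, the network may
    additionally serve up to w% of that service's unmet demand wherever
    the model finds it best, existing demand is never dropped, and the
    academic center's bottleneck resources stay capped at baseline usage.
    """
    vols = _normalize_baseline(model, baseline_volumes)
    amc = model.academic_location().id
    unmet_net: dict[str, float] = {}
    for key, v in unmet_demand.items():
        p = key[0] if isinstance(key, tuple) else key
        if v < 0:
            raise ValueError(f"negative unmet demand for {key!r}")
        unmet_net[p] = unmet_net.get(p, 0.0) + float(v)
    caps = _baseline_usage(model, vols, bottleneck_caps)
    base_rnvc = sum(model.profitability.pi.get(k, 0.0) * v for k, v in vols.items())
    los = {s.id: s.length_of_stay_days for s in model.services}

    rows = []
    volumes: dict[tuple[float, float], dict[tuple[str, str], float]] = {}
    last_sol: Solution | None = None
    for realloc in realloc_grid:
        for w in w_grid:
            scen = _recovery_model(model, vols, unmet_net, realloc, w)
            lp = build_lp(scen, capacity_overrides=caps, skip_validation=True)
            sol = solve(scen, lp)
            if sol.status != "optimal":
                rows.append({"realloc_pct": realloc, "w_pct": w, "rnvc": math.nan,
                             "gain": math.nan, "required_beds_amc": math.nan,
                             "status": sol.status})
                continue
            amc_vols = {p: sol.x.get((p, amc), 0.0) for p in model.service_ids()}
            beds = required_beds(amc_vols, los, model.horizon_days)
            rows.append({
                "realloc_pct": realloc, "w_pct": w, "rnvc": sol.objective_rnvc,
                "gain": (sol.objective_rnvc - base_rnvc) / base_rnvc if base_rnvc else math.nan,
                "required_beds_amc": beds, "status": "optimal",
            })
            volumes[(realloc, w)] = dict(sol.x)
            last_sol = sol
    surface = pd.DataFrame(rows, columns=["realloc_pct", "w_pct", "rnvc", "gain",
                                          "required_beds_amc", "status"])
    if last_sol is not None and last_sol.status == "optimal":
        rep = directional_report(model, vols, last_sol.x, tolerance)
        stime = surgeon_time_table(last_sol, model)
    else:
        rep = DirectionalChangeReport()
        stime = pd.DataFrame(columns=["specialty", "location", "minutes"])
    return RecoveryResult(surface=surface, volumes=volumes, directional=rep,
                          surgeon_time=stime, baseline_rnvc=base_rnvc)


def run_scenario(model: NetworkModel, spec: ScenarioSpec, baseline_volumes: Mapping,
                 unmet_demand: Mapping | None = None):
    """Dispatch a declarative ScenarioSpec to the matching study."""
    if spec.kind == "baseline":
        return run_baseline(model, baseline_volumes)
    if spec.kind == "casemix_perturbation":
        return run_casemix_perturbation(model, baseline_volumes, spec.x_pct, spec.y_pct,
                                        spec.bottleneck_caps, spec.tolerance)
    realloc_grid = spec.realloc_grid or [spec.realloc_pct]
    w_grid = spec.w_grid or [spec.w_pct]
    return run_reallocation_recovery(model, baseline_volumes, unmet_demand or {},
                                     realloc_grid, w_grid, spec.bottleneck_caps,
                                     spec.tolerance)


def canonical_form(lp: LinearProgram) -> str:
    """Deterministic digest of an LP: same scenario + model => same string."""
    parts = []
    for vid, coef in sorted(zip(lp.var_ids, lp.c)):
        parts.append(f"obj {vid} {coef:.12g}")
    for row in sorted(lp.rows, key=lambda r: r.id):
        terms = " ".join(f"{lp.var_ids[j]}:{row.coeffs[j] * row.sense:.12g}"
                         for j in sorted(row.coeffs))
        parts.append(f"row {row.id} {terms} <= {row.rhs * row.sense:.12g}")
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()
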