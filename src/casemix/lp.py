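"""Build and solve the network capacity-allocation linear program.

The decision variables are x[p, l], the number of cases of service p
performed at location l over the horizon, and y[s, q, a, l], the
time-equivalent units of substitutable resource s deployed to specialty
requirement q, activity a and location l. The objective maximizes revenue
net of variable cost, RNVC = sum_l sum_p pi_pl x_pl, subject to

* fixed-resource capacity per (resource, location);
* flexible-resource capacity pooled over the network;
* substitutable coverage per (specialty requirement, activity, location):
  cases may only consume substitutable time that has been deployed to
  their specialty, so no deployed unit can cover two requirements;
* total deployed time per substitutable resource bounded by its capacity;
* demand bounds per service at network and at location level.

All quantities are in canonical minutes; duals of capacity constraints are
therefore $ per minute unless rescaled to the resource's declared unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import Mobility, NetworkModel, validate_model
from .units import _MINUTES

__all__ = [
    "LinearProgram",
    "Solution",
    "build_lp",
    "solve",
    "rnvc",
    "bottom_line",
    "bottom_line_leverage",
    "compute_utilization",
    "utilization_by_service",
    "shadow_prices",
    "check_allocation_feasible",
    "solution_to_json_dict",
]

#: asserted primal feasibility slack, canonical units
FEAS_TOL = 1e-6


@dataclass(frozen=True)
class _Row:
    id: str
    family: str
    #: +1 for a "<=" constraint on the named bound, -1 for a ">=" lower bound
    sense: int
    coeffs: dict[int, float]
    rhs: float


@dataclass
class LinearProgram:
    """Named-constraint LP, maximize c @ v subject to rows (as <= after sign folding)."""

    var_keys: list[tuple]
    var_ids: list[str]
    c: np.ndarray
    rows: list[_Row]

    def n_vars(self) -> int:
        return len(self.var_keys)

    def to_dense(self) -> tuple[np.ndarray, np.ndarray]:
        """(A_ub, b_ub) with every row expressed as A v <= b."""
        A = np.zeros((len(self.rows), self.n_vars()))
        b = np.zeros(len(self.rows))
        for i, row in enumerate(self.rows):
            for j, coef in row.coeffs.items():
                A[i, j] = coef * row.sense
            b[i] = row.rhs * row.sense
        return A, b

    def row_ids(self) -> list[str]:
        return [r.id for r in self.rows]


@dataclass
class Solution:
    status: str
    objective_rnvc: float
    x: dict[tuple[str, str], float] = field(default_factory=dict)
    y: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    duals: dict[str, float] = field(default_factory=dict)
    #: conflicting constraint families when status == "infeasible"
    infeasibility_diagnosis: list[str] = field(default_factory=list)
    lp: LinearProgram | None = None


def _substitution_activities(model: NetworkModel) -> list[str]:
    subs_ids = {r.id for r in model.resources_by_mobility(Mobility.substitutable)}
    acts = {a for (_p, a, r, _l) in (k for k, _ in model.usage.items()) if r in subs_ids}
    order = {a.id: a.ordinal for a in model.activities}
    return sorted(acts, key=lambda a: (order.get(a, 0), a))


def build_lp(
    model: NetworkModel,
    *,
    extra_rows: Sequence[tuple[str, dict[tuple, float], float | None, float | None]] = (),
    capacity_overrides: Mapping[str, float] | None = None,
    skip_validation: bool = False,
) -> LinearProgram:
    """Assemble the LP for *model*.

    ``extra_rows`` are (name, {var_key: coef}, lower, upper) linear
    constraints in the x/y variable space (either bound may be None);
    scenarios use them for the total-volume band. ``capacity_overrides``
    replaces the right-hand side of a resource's capacity constraint (in
    canonical minutes) without touching the model — this is how bottleneck
    caps are imposed.

    Raises ``ValueError`` if the model fails validation.
    """
    if not skip_validation:
        problems = validate_model(model)
        if problems:
            raise ValueError(
                "model failed validation; first problems: "
                + "; ".join(str(p) for p in problems[:5])
            )
    overrides = dict(capacity_overrides or {})

    loc_ids = model.location_ids()
    d = model.demand

    # x variables: every (service, location) pair with a defined margin.
    x_keys = [("x", p, l) for p in model.service_ids() for l in loc_ids
              if (p, l) in model.profitability.pi]
    x_index = {k[1:]: i for i, k in enumerate(x_keys)}

    # y variables: deployment of substitutable resources.
    sub_acts = _substitution_activities(model)
    y_keys: list[tuple] = []
    for s in model.resources_by_mobility(Mobility.substitutable):
        for q in sorted(s.capability_set):
            for a in sub_acts:
                for l in loc_ids:
                    y_keys.append(("y", s.id, q, a, l))
    y_index = {k[1:]: len(x_keys) + i for i, k in enumerate(y_keys)}

    var_keys = x_keys + y_keys
    var_ids = [f"x[{p}@{l}]" for (_, p, l) in x_keys] + [
        f"y[{s}|{q}|{a}@{l}]" for (_, s, q, a, l) in y_keys
    ]
    c = np.zeros(len(var_keys))
    for (_, p, l) in x_keys:
        c[x_index[(p, l)]] = model.profitability.pi[(p, l)]

    rows: list[_Row] = []
    subs_ids = {r.id for r in model.resources_by_mobility(Mobility.substitutable)}

    # (i) fixed-resource capacity per (r, l); (ii) flexible per r
    for res in model.resources:
        if not res.hard_constraint or res.mobility is Mobility.substitutable:
            continue
        cap = overrides.get(res.id, res.capacity)
        coeffs: dict[int, float] = {}
        for (p, a, r, l), u in model.usage.items():
            if r != res.id or u == 0.0:
                continue
            if res.mobility is Mobility.fixed and l != res.location:
                continue
            j = x_index.get((p, l))
            if j is not None:
                coeffs[j] = coeffs.get(j, 0.0) + u
        if res.mobility is Mobility.fixed:
            rid = f"capacity[{res.id}@{res.location}]"
            family = "capacity_fixed"
        else:
            rid = f"capacity[{res.id}]"
            family = "capacity_flexible"
        rows.append(_Row(rid, family, +1, coeffs, cap))

    # (iii) substitutable coverage per (specialty requirement q, activity, location)
    subs_sets = model.substitution_sets()
    for q, classes in sorted(subs_sets.items()):
        for a in sub_acts:
            for l in loc_ids:
                coeffs = {}
                for (p, aa, r, ll), u in model.usage.items():
                    if aa != a or ll != l or r not in subs_ids or u == 0.0:
                        continue
                    if model.specialty_of(p) != q:
                        continue
                    j = x_index.get((p, l))
                    if j is not None:
                        coeffs[j] = coeffs.get(j, 0.0) + u
                if not coeffs:
                    continue
                for s in classes:
                    j = y_index.get((s, q, a, l))
                    if j is not None:
                        coeffs[j] = coeffs.get(j, 0.0) - 1.0
                rows.append(_Row(f"substitute_cover[{q}|{a}@{l}]", "subs_cover", +1, coeffs, 0.0))

    # (iv) total deployed time per substitutable resource
    for res in model.resources_by_mobility(Mobility.substitutable):
        if not res.hard_constraint:
            continue
        cap = overrides.get(res.id, res.capacity)
        coeffs = {j: 1.0 for (s, _q, _a, _l), j in y_index.items() if s == res.id}
        rows.append(_Row(f"substitute_capacity[{res.id}]", "subs_capacity", +1, coeffs, cap))

    # (v) network demand bounds
    for p in model.service_ids():
        coeffs = {j: 1.0 for (pp, _l), j in x_index.items() if pp == p}
        if not coeffs:
            continue
        up = d.net_up(p)
        if math.isfinite(up):
            rows.append(_Row(f"demand_network_upper[{p}]", "demand_network_upper", +1, dict(coeffs), up))
        lo = d.net_lo(p)
        if lo > 0:
            rows.append(_Row(f"demand_network_lower[{p}]", "demand_network_lower", -1, dict(coeffs), lo))

    # (vi) location demand bounds
    for (p, l), j in x_index.items():
        up = d.loc_up(p, l)
        if math.isfinite(up):
            rows.append(_Row(f"demand_upper[{p}@{l}]", "demand_loc_upper", +1, {j: 1.0}, up))
        lo = d.loc_lo(p, l)
        if lo > 0:
            rows.append(_Row(f"demand_lower[{p}@{l}]", "demand_loc_lower", -1, {j: 1.0}, lo))

    key_to_col = {k: i for i, k in enumerate(var_keys)}
    for (name, coeff_map, lower, upper) in extra_rows:
        coeffs = {key_to_col[k]: v for k, v in coeff_map.items()}
        if upper is not None and math.isfinite(upper):
            rows.append(_Row(f"{name}_upper", "extra", +1, dict(coeffs), upper))
        if lower is not None and lower > -math.inf:
            rows.append(_Row(f"{name}_lower", "extra", -1, dict(coeffs), lower))

    return LinearProgram(var_keys=var_keys, var_ids=var_ids, c=c, rows=rows)


def _diagnose_infeasibility(lp: LinearProgram) -> list[str]:
    """Name the conflicting constraint families.

    Each family in turn gets elastic slack; if relaxing that family alone
    restores feasibility, its rows that actually need slack are reported.
    Falls back to a fully elastic solve (slack weighted by constraint
    scale, so bed-minutes and cases are comparable) when no single family
    suffices.
    """
    A, b = lp.to_dense()
    m, n = A.shape
    if m == 0:
        return []
    scale = np.maximum(1.0, np.abs(b))

    def elastic(rows_idx: np.ndarray) -> tuple[bool, np.ndarray]:
        k = len(rows_idx)
        S = np.zeros((m, k))
        for col, i in enumerate(rows_idx):
            S[i, col] = -scale[i]
        res = linprog(np.concatenate([np.zeros(n), np.ones(k)]),
                      A_ub=np.hstack([A, S]), b_ub=b,
                      bounds=[(0, None)] * (n + k), method="highs")
        if not res.success:
            return False, np.zeros(k)
        return True, res.x[n:] * scale[rows_idx]

    families = list(dict.fromkeys(r.family for r in lp.rows))
    out: list[str] = []
    for fam in families:
        idx = np.array([i for i, r in enumerate(lp.rows) if r.family == fam])
        ok, slack = elastic(idx)
        if ok and slack.sum() > 1e-6:
            for i, s in zip(idx, slack):
                if s > 1e-6 * scale[i]:
                    out.append(f"{fam}: {lp.rows[i].id} short by {s:.6g}")
    if not out:
        ok, slack = elastic(np.arange(m))
        if not ok:
            return ["diagnosis unavailable (elastic relaxation did not solve)"]
        for i, s in enumerate(slack):
            if s > 1e-6 * scale[i]:
                out.append(f"{lp.rows[i].family}: {lp.rows[i].id} short by {s:.6g}")
    return out


def _tighten_deployment(lp: LinearProgram, v: np.ndarray) -> dict:
    """Minimal substitutable deployment covering the solved volumes.

    The main LP leaves y free above the coverage requirement, so an
    arbitrary optimal vertex may park unused capacity in y. With x fixed,
    first re-minimize total deployed time (deployment becomes exactly the
    time the case-mix consumes), then, holding that total, balance the
    load by minimizing the maximum class utilization so the per-class
    report is not an artifact of solver tie-breaking. Falls back to the
    solver's y if either subproblem fails.
    """
    y_cols = [j for j, k in enumerate(lp.var_keys) if k[0] == "y"]
    col_of = {j: i for i, j in enumerate(y_cols)}
    n_y = len(y_cols)
    A_rows, b_rows = [], []
    cap_rows: list[tuple[np.ndarray, float]] = []
    for row in lp.rows:
        if row.family not in ("subs_cover", "subs_capacity"):
            continue
        coeffs = np.zeros(n_y)
        rhs = row.rhs * row.sense
        for j, coef in row.coeffs.items():
            if j in col_of:
                coeffs[col_of[j]] = coef * row.sense
            else:
                rhs -= coef * row.sense * v[j]
        A_rows.append(coeffs)
        b_rows.append(rhs)
        if row.family == "subs_capacity":
            cap_rows.append((coeffs, rhs))
    fallback = {lp.var_keys[j][1:]: float(v[j]) for j in y_cols}
    res = linprog(np.ones(n_y), A_ub=np.array(A_rows), b_ub=np.array(b_rows),
                  bounds=[(0, None)] * n_y, method="highs")
    if not res.success:
        return fallback
    total = float(res.fun)
    # phase 2: among minimal-total deployments, minimize max class fraction
    A2 = [np.append(a, 0.0) for a in A_rows]
    b2 = list(b_rows)
    A2.append(np.append(np.ones(n_y), 0.0))
    b2.append(total + 1e-9 * max(1.0, total))
    for coeffs, cap in cap_rows:
        if cap > 0:
            A2.append(np.append(coeffs, -cap))
            b2.append(0.0)
    c2 = np.zeros(n_y + 1)
    c2[-1] = 1.0
    res2 = linprog(c2, A_ub=np.array(A2), b_ub=np.array(b2),
                   bounds=[(0, None)] * (n_y + 1), method="highs")
    source = res2.x[:n_y] if res2.success else res.x
    return {lp.var_keys[j][1:]: float(val) for j, val in zip(y_cols, source)}


def solve(model: NetworkModel, lp: LinearProgram | None = None) -> Solution:
    """Solve the instance with the HiGHS backend and extract primal and dual values.

    Duals are reported as the derivative of the optimal RNVC with respect
    to the named bound: nonnegative for capacities and upper demand bounds,
    nonpositive for lower demand bounds. Non-binding constraints carry a
    zero dual (complementary slackness).
    """
    if lp is None:
        lp = build_lp(model)
    A, b = lp.to_dense()
    n = lp.n_vars()
    res = linprog(-lp.c, A_ub=A if len(lp.rows) else None, b_ub=b if len(lp.rows) else None,
                  bounds=[(0, None)] * n, method="highs",
                  options={"primal_feasibility_tolerance": 1e-9,
                           "dual_feasibility_tolerance": 1e-9})
    if res.status == 2:
        return Solution(status="infeasible", objective_rnvc=math.nan,
                        infeasibility_diagnosis=_diagnose_infeasibility(lp), lp=lp)
    if res.status == 3:
        return Solution(status="unbounded", objective_rnvc=math.inf, lp=lp)
    if not res.success:  # pragma: no cover - solver failure path
        raise RuntimeError(f"LP solve failed: {res.message}")

    v = res.x
    if len(lp.rows):
        worst = float(np.max(A @ v - b, initial=0.0))
        if worst > FEAS_TOL * max(1.0, float(np.max(np.abs(b), initial=1.0))):
            raise RuntimeError(f"solver returned primally infeasible point (violation {worst:.3g})")

    x = {}
    y = {}
    for key, val in zip(lp.var_keys, v):
        if key[0] == "x":
            x[(key[1], key[2])] = float(val)
        else:
            y[(key[1], key[2], key[3], key[4])] = float(val)
    if y:
        y = _tighten_deployment(lp, v)

    duals: dict[str, float] = {}
    marg = res.ineqlin.marginals if len(lp.rows) else []
    for row, m_i in zip(lp.rows, marg):
        # marginals are for the minimization; flip to max sense, then orient
        # to the named bound (lower bounds were folded with sense -1).
        duals[row.id] = float(-m_i) * row.sense
    return Solution(status="optimal", objective_rnvc=float(-res.fun), x=x, y=y, duals=duals, lp=lp)


def rnvc(solution: Solution, model: NetworkModel) -> float:
    """Recompute the objective sum pi_pl x_pl from the primal volumes."""
    return sum(model.profitability.pi[k] * v for k, v in solution.x.items())


def bottom_line(solution: Solution, model: NetworkModel,
                network_building_cost: float | None = None) -> float:
    """Total profit = RNVC minus the (sunk) network building cost."""
    cost = model.network_building_cost if network_building_cost is None else network_building_cost
    return rnvc(solution, model) - cost


def bottom_line_leverage(margin: float = 0.04, fixed_cost_share: float = 0.60) -> float:
    """Percent bottom-line increase produced by a 1% RNVC increase.

    With revenue R, total cost C = (1 - margin) R, and a share
    ``fixed_cost_share`` of C being network building cost (overhead and
    labor), RNVC = R - variable cost = (1 - (1-margin)(1-fixed_cost_share)) R
    while the bottom line is margin * R. Because the building cost is
    unchanged by case-mix shifts, a 1% RNVC gain lifts the bottom line by
    RNVC / bottom-line percent.
    """
    if not 0 < margin < 1:
        raise ValueError("margin must be in (0, 1)")
    if not 0 <= fixed_cost_share < 1:
        raise ValueError("fixed_cost_share must be in [0, 1)")
    rnvc_share = 1.0 - (1.0 - margin) * (1.0 - fixed_cost_share)
    return rnvc_share / margin


def _used_minutes(model: NetworkModel, x: Mapping[tuple[str, str], float],
                  resource: str, location: str | None) -> float:
    total = 0.0
    for (p, a, r, l), u in model.usage.items():
        if r != resource:
            continue
        if location is not None and l != location:
            continue
        total += u * x.get((p, l), 0.0)
    return total


def compute_utilization(solution: Solution, model: NetworkModel) -> pd.DataFrame:
    """Per-resource load table.

    Columns: resource, location ("network" for pooled resources), used and
    capacity in the resource's declared unit, fraction (NaN when capacity
    is zero). Substitutable resources report deployed time from y against
    their pooled capacity. Reporting-only resources may exceed 1.
    """
    records = []
    for res in model.resources:
        unit_min = _MINUTES[res.capacity_unit.strip().lower()]
        if res.mobility is Mobility.substitutable:
            used = sum(v for (s, _q, _a, _l), v in solution.y.items() if s == res.id)
            loc = "network"
        elif res.mobility is Mobility.flexible:
            used = _used_minutes(model, solution.x, res.id, None)
            loc = "network"
        else:
            used = _used_minutes(model, solution.x, res.id, res.location)
            loc = res.location
        frac = used / res.capacity if res.capacity > 0 else math.nan
        records.append({
            "resource": res.id,
            "location": loc,
            "used": used / unit_min,
            "capacity": res.capacity / unit_min,
            "unit": res.capacity_unit,
            "fraction": frac,
            "hard_constraint": res.hard_constraint,
        })
    subs = model.resources_by_mobility(Mobility.substitutable)
    if subs:
        # overall pooled deployment: per-class splits are not unique under
        # alternative optima, the pooled fraction is
        used = sum(solution.y.values())
        cap = sum(r.capacity for r in subs)
        records.append({
            "resource": "substitutable_pool", "location": "network",
            "used": used / 60.0, "capacity": cap / 60.0, "unit": "hour",
            "fraction": used / cap if cap > 0 else math.nan,
            "hard_constraint": True,
        })
    return pd.DataFrame.from_records(records)


def utilization_by_service(solution: Solution, model: NetworkModel,
                           resource: str) -> dict[str, float]:
    """Fraction of *resource* capacity consumed by each service."""
    res = model.resource(resource)
    out: dict[str, float] = {}
    for (p, a, r, l), u in model.usage.items():
        if r != resource:
            continue
        if res.mobility is Mobility.fixed and l != res.location:
            continue
        out[p] = out.get(p, 0.0) + u * solution.x.get((p, l), 0.0)
    if res.capacity > 0:
        out = {p: v / res.capacity for p, v in out.items()}
    return out


def shadow_prices(solution: Solution, model: NetworkModel | None = None,
                  native_units: bool = False) -> dict[str, float]:
    """Dual values keyed by constraint id.

    Capacity duals are $ per canonical minute; with ``native_units`` and a
    model they are rescaled to $ per declared capacity unit (e.g. $ per
    bed-day), which is the scale at which marginal capacity investments
    are discussed. Demand-bound duals are $ per case either way.
    """
    if solution.status != "optimal":
        raise ValueError("shadow prices are defined only for an optimal solution")
    duals = dict(solution.duals)
    if native_units and model is not None:
        for res in model.resources:
            unit_min = _MINUTES[res.capacity_unit.strip().lower()]
            for rid in (f"capacity[{res.id}@{res.location}]", f"capacity[{res.id}]",
                        f"substitute_capacity[{res.id}]"):
                if rid in duals:
                    duals[rid] *= unit_min
    return duals


def check_allocation_feasible(model: NetworkModel, x: Mapping[tuple[str, str], float],
                              tol: float = FEAS_TOL) -> bool:
    """True iff volumes *x* admit a feasible substitutable deployment y.

    Fixes the case volumes and asks the solver for any feasible y; with no
    substitutable resources this reduces to checking the explicit rows.
    """
    lp = build_lp(model, skip_validation=True)
    A, b = lp.to_dense()
    n = lp.n_vars()
    bounds = []
    for key in lp.var_keys:
        if key[0] == "x":
            v = float(x.get((key[1], key[2]), 0.0))
            bounds.append((v, v))
        else:
            bounds.append((0, None))
    if len(lp.rows) == 0:
        return True
    res = linprog(np.zeros(n), A_ub=A, b_ub=b + tol * np.maximum(1.0, np.abs(b)),
                  bounds=bounds, method="highs")
    return bool(res.success)


def solution_to_json_dict(solution: Solution, model: NetworkModel) -> dict:
    """Stable, diff-friendly JSON form of a solution."""
    util = compute_utilization(solution, model) if solution.status == "optimal" else None
    doc = {
        "status": solution.status,
        "objective": None if math.isnan(solution.objective_rnvc) else solution.objective_rnvc,
        "x": [
            {"service": p, "location": l, "cases": v}
            for (p, l), v in sorted(solution.x.items())
        ],
        "y": [
            {"resource": s, "specialty": q, "activity": a, "location": l, "minutes": v}
            for (s, q, a, l), v in sorted(solution.y.items())
        ],
        "duals": [
            {"constraint": k, "value": v} for k, v in sorted(solution.duals.items())
        ],
        "utilization": [] if util is None else util.to_dict(orient="records"),
        "infeasibility_diagnosis": list(solution.infeasibility_diagnosis),
    }
    return doc
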