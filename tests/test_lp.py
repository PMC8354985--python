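import dataclasses
import math

import numpy as np
import pytest

from casemix.lp import (bottom_line, build_lp, compute_utilization, rnvc,
                        shadow_prices, solve, utilization_by_service)
from casemix.model import (Activity, DemandBounds, Location, Mobility,
                           NetworkModel, Profitability, Resource,
                           ResourceCategory, Service, UsageMatrix)

from oracles import random_small_model, vertex_enumeration_optimum


def test_worked_example_lp_structure(worked):
    lp = build_lp(worked)
    assert lp.n_vars() == 2
    families = [r.family for r in lp.rows]
    assert families.count("capacity_fixed") == 2
    assert families.count("demand_loc_upper") == 2
    assert families.count("subs_cover") == 0
    assert families.count("subs_capacity") == 0
    # every constraint carries a stable human-readable id
    assert "capacity[operating_room@main]" in lp.row_ids()
    assert "demand_upper[I@main]" in lp.row_ids()


def test_substitutable_deployment_variable_count():
    """One surgeon class covering two specialties at two locations deploys
    over 2 x |surgical activities| x 2 components."""
    locs = [Location("AMC"), Location("COM1")]
    services = [Service("P0", "breast"), Service("P1", "endocrine")]
    acts = [Activity("surgery", 2), Activity("recovery", 3)]
    cls = Resource("class_be", ResourceCategory.C, Mobility.substitutable,
                   capacity=10_000.0, capability_set=frozenset({"breast", "endocrine"}))
    usage = UsageMatrix()
    for p in ("P0", "P1"):
        for l in ("AMC", "COM1"):
            usage.set(p, "surgery", "class_be", l, 60.0)
    pi = {(p, l): 100.0 for p in ("P0", "P1") for l in ("AMC", "COM1")}
    demand = DemandBounds(location_upper={k: 10.0 for k in pi})
    m = NetworkModel(locations=locs, services=services, activities=acts,
                     resources=[cls], usage=usage,
                     profitability=Profitability(pi=pi), demand=demand)
    lp = build_lp(m)
    y_vars = [k for k in lp.var_keys if k[0] == "y"]
    # only "surgery" touches the class, so |A_surgical| = 1
    assert len(y_vars) == 2 * 1 * 2
    assert any(r.family == "subs_cover" for r in lp.rows)
    assert any(r.family == "subs_capacity" for r in lp.rows)
    sol = solve(m)
    assert sol.status == "optimal"
    # each deployed unit covers exactly one requirement: total y equals total load
    assert sum(sol.y.values()) == pytest.approx(
        sum(60.0 * v for v in sol.x.values()), abs=1e-6)


def test_worked_example_optimal_volumes(worked):
    sol = solve(worked)
    assert sol.status == "optimal"
    assert sol.x[("I", "main")] == pytest.approx(500.0, abs=1e-6)
    assert sol.x[("II", "main")] == pytest.approx(300.0, abs=1e-6)
    assert sol.objective_rnvc == pytest.approx(1_090_000.0, rel=1e-9)
    assert rnvc(sol, worked) == pytest.approx(sol.objective_rnvc, rel=1e-9)


def test_null_instance_solves_to_zero(worked):
    null = dataclasses.replace(worked)
    null.resources = [dataclasses.replace(r, capacity=0.0) for r in worked.resources]
    sol = solve(null)
    assert sol.status == "optimal"
    assert sol.objective_rnvc == pytest.approx(0.0, abs=1e-9)
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in sol.x.values())


def test_bottom_line_and_myopic_value(worked):
    sol = solve(worked)
    assert bottom_line(sol, worked) == pytest.approx(790_000.0, rel=1e-9)
    assert bottom_line(sol, worked, network_building_cost=0.0) == pytest.approx(
        rnvc(sol, worked), rel=1e-12)
    myopic = {("I", "main"): 400.0, ("II", "main"): 400.0}
    val = sum(worked.profitability.pi[k] * v for k, v in myopic.items())
    assert val == pytest.approx(1_080_000.0)
    assert val - worked.network_building_cost == pytest.approx(780_000.0)


def test_utilization_reports(worked):
    sol = solve(worked)
    util = compute_utilization(sol, worked).set_index("resource")
    assert util.loc["operating_room", "fraction"] == pytest.approx(1300 / 1500, rel=1e-9)
    assert util.loc["floor_beds", "fraction"] == pytest.approx(1.0, rel=1e-9)
    by_svc = utilization_by_service(sol, worked, "operating_room")
    # 1000 and 300 of the 1500 OR-hours
    assert by_svc["I"] * 1500 == pytest.approx(1000.0, abs=1e-6)
    assert by_svc["II"] * 1500 == pytest.approx(300.0, abs=1e-6)
    beds = utilization_by_service(sol, worked, "floor_beds")
    assert beds["I"] == pytest.approx(0.625, abs=1e-9)
    assert beds["II"] == pytest.approx(0.375, abs=1e-9)


def test_shadow_prices_match_resolve_differences(worked):
    sol = solve(worked)
    duals = shadow_prices(sol, worked, native_units=True)
    # OR has 200 h slack -> zero opportunity cost
    assert duals["capacity[operating_room@main]"] == pytest.approx(0.0, abs=1e-6)
    # frozen expectations from re-solving with capacity 801 bed-days / bound 501
    assert duals["capacity[floor_beds@main]"] == pytest.approx(1300.0, rel=1e-6)
    assert duals["demand_upper[I@main]"] == pytest.approx(100.0, rel=1e-6)

    plus_bed = dataclasses.replace(worked)
    plus_bed.resources = [worked.resources[0],
                          dataclasses.replace(worked.resources[1], capacity=801 * 1440.0)]
    assert solve(plus_bed).objective_rnvc - sol.objective_rnvc == pytest.approx(1300.0, rel=1e-9)

    plus_dem = dataclasses.replace(worked)
    plus_dem.demand = DemandBounds(
        location_lower=dict(worked.demand.location_lower),
        location_upper={("I", "main"): 501.0, ("II", "main"): 400.0})
    assert solve(plus_dem).objective_rnvc - sol.objective_rnvc == pytest.approx(100.0, rel=1e-9)


def test_infeasible_instance_names_conflicting_families(worked):
    bad = dataclasses.replace(worked)
    bad.demand = DemandBounds(
        network_lower={"I": 450.0},
        location_lower={("I", "main"): 450.0},
        location_upper={("I", "main"): 500.0, ("II", "main"): 400.0},
        network_upper={},
    )
    # 450 cases of I need 900 bed-days; shrink beds below that
    bad.resources = [worked.resources[0],
                     dataclasses.replace(worked.resources[1], capacity=400 * 1440.0)]
    sol = solve(bad)
    assert sol.status == "infeasible"
    assert any("floor_beds" in line for line in sol.infeasibility_diagnosis)


def test_unbounded_demand_with_positive_margin_is_unbounded(worked):
    free = dataclasses.replace(worked)
    free.demand = DemandBounds()  # no ceilings at all
    free.resources = [dataclasses.replace(r, hard_constraint=False)
                      for r in worked.resources]
    sol = solve(free)
    assert sol.status == "unbounded"


def test_solver_matches_vertex_enumeration_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(40):
        model = random_small_model(rng)
        lp = build_lp(model, skip_validation=True)
        sol = solve(model, lp)
        assert sol.status == "optimal"
        A, b = lp.to_dense()
        oracle = vertex_enumeration_optimum(lp.c, A, b)
        assert oracle is not None
        assert sol.objective_rnvc == pytest.approx(
            oracle, rel=1e-6, abs=1e-6)


def test_strong_duality_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(25):
        model = random_small_model(rng)
        lp = build_lp(model, skip_validation=True)
        sol = solve(model, lp)
        dual_value = sum(sol.duals[row.id] * row.rhs for row in lp.rows)
        assert dual_value == pytest.approx(sol.objective_rnvc, rel=1e-6, abs=1e-6)


def test_rnvc_monotone_in_capacity_and_demand(worked):
    base = solve(worked).objective_rnvc
    prev = None
    for scale in (0.5, 0.75, 1.0, 1.5, 2.0):
        m = dataclasses.replace(worked)
        m.resources = [worked.resources[0],
                       dataclasses.replace(worked.resources[1],
                                           capacity=800 * 1440.0 * scale)]
        val = solve(m).objective_rnvc
        if prev is not None:
            assert val >= prev - 1e-6
        prev = val
    # raising a lower bound can only hurt
    m = dataclasses.replace(worked)
    m.demand = DemandBounds(
        location_lower={("II", "main"): 400.0},
        location_upper=dict(worked.demand.location_upper))
    assert solve(m).objective_rnvc <= base + 1e-6


def test_rnvc_concave_in_bed_capacity(worked):
    vals = []
    for beds in np.linspace(200, 1200, 9):
        m = dataclasses.replace(worked)
        m.resources = [worked.resources[0],
                       dataclasses.replace(worked.resources[1], capacity=beds * 1440.0)]
        vals.append(solve(m).objective_rnvc)
    diffs = np.diff(vals)
    assert np.all(np.diff(diffs) <= 1e-6 * max(abs(v) for v in vals))
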