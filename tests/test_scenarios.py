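import dataclasses

import numpy as np
import pytest

from casemix.lp import build_lp, solve
from casemix.scenarios import (ScenarioSpec, canonical_form, directional_report,
                               required_beds, run_baseline,
                               run_casemix_perturbation,
                               run_reallocation_recovery, run_scenario)

BASELINE = {"I": 400.0, "II": 400.0}


def test_baseline_pins_volumes_and_reports_utilization(worked):
    res = run_baseline(worked, BASELINE)
    assert res.solution.status == "optimal"
    assert res.rnvc == pytest.approx(1_080_000.0, rel=1e-9)
    util = res.utilization.set_index("resource")
    assert util.loc["operating_room", "fraction"] == pytest.approx(0.80, abs=1e-9)
    assert util.loc["floor_beds", "fraction"] == pytest.approx(1.0, abs=1e-9)
    assert res.required_beds == pytest.approx(800 / 365, rel=1e-12)


def test_baseline_pinned_at_zero(worked):
    res = run_baseline(worked, {"I": 0.0, "II": 0.0})
    assert res.solution.status == "optimal"
    assert (res.utilization["fraction"].fillna(0.0) == 0.0).all()
    assert res.required_beds == 0.0


def test_infeasible_baseline_is_diagnosed(worked):
    res = run_baseline(worked, {"I": 600.0, "II": 400.0})  # 1000 bed-days > 800
    assert res.solution.status == "infeasible"
    assert any("floor_beds" in line for line in res.solution.infeasibility_diagnosis)


def test_baseline_utilization_matches_hand_arithmetic(synth_instance):
    model, truth = synth_instance
    res = run_baseline(model, truth.baseline_volumes)
    assert res.solution.status == "optimal"
    rid = "operating_room_AMC"
    expected = sum(u * truth.baseline_volumes[p]
                   for (p, _a, r, l), u in model.usage.items()
                   if r == rid and l == "AMC") / model.resource(rid).capacity
    util = res.utilization.set_index("resource")
    assert util.loc[rid, "fraction"] == pytest.approx(expected, rel=1e-9)


def test_required_beds_arithmetic():
    assert required_beds({"P": 365.0}, {"P": 1.0}, 365) == pytest.approx(1.0)
    assert required_beds({"P": 800.0}, {"P": 1.0}, 365) == pytest.approx(2.19178, rel=1e-4)
    assert required_beds({}, {}, 365) == 0.0
    with pytest.raises(ValueError):
        required_beds({"P": -1.0}, {"P": 1.0}, 365)


def test_zero_perturbation_reproduces_baseline(worked):
    res = run_casemix_perturbation(worked, BASELINE, x_pct=0, y_pct=0)
    assert res.solution.status == "optimal"
    assert res.gain == pytest.approx(0.0, abs=1e-9)
    assert all(c == 0 for c in res.directional.codes.values())


def test_perturbation_recovers_the_optimal_shift(worked):
    """+-25% around (400, 400) with the bed bottleneck capped reproduces the
    500/300 optimum and its 10K/1080K gain."""
    res = run_casemix_perturbation(worked, BASELINE, x_pct=25, y_pct=0,
                                   bottleneck_caps=["floor_beds"])
    assert res.solution.x[("I", "main")] == pytest.approx(500.0, abs=1e-6)
    assert res.solution.x[("II", "main")] == pytest.approx(300.0, abs=1e-6)
    assert res.gain == pytest.approx(10_000.0 / 1_080_000.0, rel=1e-9)
    codes = res.directional.codes
    assert codes[("I", "AMC")] == 1 and codes[("II", "AMC")] == -1


def test_bottleneck_cap_holds_resources_at_baseline_usage(worked):
    """Capping the OR too keeps its usage at the baseline 1200 h, which
    blocks the shift toward the OR-hungrier service."""
    res = run_casemix_perturbation(worked, BASELINE, x_pct=25, y_pct=0,
                                   bottleneck_caps=["floor_beds", "operating_room"])
    assert res.solution.status == "optimal"
    or_minutes = sum(u * res.solution.x.get((p, l), 0.0)
                     for (p, _a, r, l), u in worked.usage.items()
                     if r == "operating_room")
    assert or_minutes <= 72_000.0 + 1e-6
    assert res.gain == pytest.approx(0.0, abs=1e-9)


def test_perturbation_gain_monotone_in_x(worked):
    gains = [run_casemix_perturbation(worked, BASELINE, x, 0,
                                      bottleneck_caps=["floor_beds"]).gain
             for x in (0, 5, 10, 25, 50)]
    assert all(b >= a - 1e-9 for a, b in zip(gains, gains[1:]))


def test_recovery_at_zero_equals_baseline(synth_instance):
    model, truth = synth_instance
    res = run_reallocation_recovery(model, truth.baseline_volumes,
                                    truth.unmet_demand, [0.0], [0.0],
                                    bottleneck_caps=["operating_room_AMC"])
    row = res.surface.iloc[0]
    assert row["status"] == "optimal"
    assert row["rnvc"] == pytest.approx(res.baseline_rnvc, rel=1e-9)
    assert row["gain"] == pytest.approx(0.0, abs=1e-9)


def test_recovery_surface_monotone_and_concave(synth_instance):
    model, truth = synth_instance
    realloc_grid = [0.0, 25.0, 50.0, 75.0, 100.0]
    w_grid = [0.0, 50.0, 100.0]
    res = run_reallocation_recovery(model, truth.baseline_volumes,
                                    truth.unmet_demand, realloc_grid, w_grid,
                                    bottleneck_caps=["operating_room_AMC"])
    surf = res.surface.pivot(index="realloc_pct", columns="w_pct", values="rnvc")
    tol = 1e-7 * abs(res.baseline_rnvc)
    # non-decreasing along each axis (nested feasible regions)
    assert (surf.diff(axis=0).dropna() >= -tol).all().all()
    assert (surf.diff(axis=1).dropna(axis=1) >= -tol).all().all()
    # decreasing marginal returns along the reallocation axis
    for w in w_grid:
        diffs = np.diff(surf[w].to_numpy())
        assert np.all(np.diff(diffs) <= tol)


def test_recovery_reports_have_expected_shape(synth_instance):
    model, truth = synth_instance
    res = run_reallocation_recovery(model, truth.baseline_volumes,
                                    truth.unmet_demand, [0.0, 100.0], [100.0],
                                    bottleneck_caps=["operating_room_AMC"])
    assert set(res.surgeon_time.columns) == {"specialty", "location", "minutes"}
    assert (res.surgeon_time["minutes"] >= 0).all()
    frame = res.directional.to_frame()
    assert set(frame["code"]).issubset({-1, 0, 1})
    assert set(frame["group"]) == {"AMC", "COM"}
    # beds requirement at the AMC falls as volume moves out
    beds = res.surface.sort_values("realloc_pct")["required_beds_amc"].to_numpy()
    assert beds[-1] <= beds[0] + 1e-9


def test_directional_codes_ignore_sub_tolerance_noise(worked):
    base = {("I", "main"): 400.0, ("II", "main"): 400.0}
    noisy = {("I", "main"): 400.0 + 1e-7, ("II", "main"): 400.0 - 1e-7}
    rep = directional_report(worked, base, noisy)
    assert all(c == 0 for c in rep.codes.values())
    moved = {("I", "main"): 405.0, ("II", "main"): 395.0}
    rep2 = directional_report(worked, base, moved)
    assert rep2.codes[("I", "AMC")] == 1 and rep2.codes[("II", "AMC")] == -1


def test_scenario_lp_construction_is_pure(worked):
    lp1 = build_lp(worked)
    lp2 = build_lp(worked)
    assert canonical_form(lp1) == canonical_form(lp2)
    tweaked = dataclasses.replace(worked)
    tweaked.resources = [dataclasses.replace(worked.resources[0], capacity=1.0),
                         worked.resources[1]]
    assert canonical_form(build_lp(tweaked)) != canonical_form(lp1)


def test_scenario_spec_yaml_round_trip_and_dispatch(tmp_path, worked):
    spec = ScenarioSpec(kind="casemix_perturbation", x_pct=25.0, y_pct=0.0,
                        bottleneck_caps=["floor_beds"])
    path = tmp_path / "scenario.yaml"
    spec.to_yaml(path)
    again = ScenarioSpec.from_yaml(path)
    assert again == spec
    res = run_scenario(worked, again, BASELINE)
    assert res.solution.x[("I", "main")] == pytest.approx(500.0, abs=1e-6)
    with pytest.raises(ValueError):
        ScenarioSpec(kind="nope")
    with pytest.raises(ValueError):
        ScenarioSpec(kind="baseline", x_pct=120.0)


def test_solved_volumes_respect_printed_bound_formulas(synth_instance):
    """Re-check scenario bounds outside the solver."""
    model, truth = synth_instance
    amc = model.academic_location().id
    realloc, w = 50.0, 100.0
    res = run_reallocation_recovery(model, truth.baseline_volumes,
                                    truth.unmet_demand, [realloc], [w],
                                    bottleneck_caps=["operating_room_AMC"])
    x = res.volumes[(realloc, w)]
    for p in model.service_ids():
        b = truth.baseline_volumes[p]
        unmet = truth.unmet_demand[p]
        amc_vol = x.get((p, amc), 0.0)
        assert amc_vol >= b * (1 - realloc / 100) - 1e-6
        assert amc_vol <= b + unmet + 1e-6
        total = sum(v for (pp, _l), v in x.items() if pp == p)
        assert b - 1e-6 <= total <= b + (w / 100) * unmet + 1e-6
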