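import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casemix.estimation import (PhaseRecord, SurgeonRoster, annualize,
                                average_profitability, daily_capacity,
                                segment_capacity, select_services,
                                select_type_a_resources, surgeon_classes,
                                typical_usage)


def _volumes(counts_by_service):
    rows = []
    for svc, counts in counts_by_service.items():
        for month, c in enumerate(counts, start=1):
            rows.append({"service": svc, "month": month, "count": c})
    return pd.DataFrame(rows)


def test_select_services_applies_both_rules():
    vols = _volumes({
        "steady": [10] * 12,            # 120/yr, every month
        "bursty": [200] + [0] * 11,     # 200/yr, one month only
        "small": [5] * 12,              # 60/yr
    })
    assert select_services(vols, min_annual_volume=100) == ["steady"]
    assert select_services(vols, 100, require_monthly=False) == ["bursty", "steady"]
    assert select_services(vols, 0, require_monthly=False) == ["bursty", "small", "steady"]


def test_select_type_a_resources_threshold_and_critical_override():
    inc = pd.DataFrame([
        {"resource": "rare_kit", "service": "A", "fraction": 0.04},
        {"resource": "rare_kit", "service": "B", "fraction": 0.02},
        {"resource": "boundary", "service": "A", "fraction": 0.05},
        {"resource": "common", "service": "B", "fraction": 0.50},
    ])
    assert select_type_a_resources(inc) == ["boundary", "common"]
    assert select_type_a_resources(inc, critical_set={"rare_kit"}) == [
        "boundary", "common", "rare_kit"]


def _records(durations, quantities, activity="surgery"):
    return [PhaseRecord(f"c{i}", "P", activity, d, "res", q, "AMC")
            for i, (d, q) in enumerate(zip(durations, quantities))]


def test_typical_usage_median_times_mean():
    assert typical_usage(_records([30, 60, 90], [1, 1, 2])) == pytest.approx(80.0)
    assert typical_usage(_records([45, 45, 45], [1, 1, 1])) == pytest.approx(45.0)
    # even-length median uses the midpoint of the central pair
    assert typical_usage(_records([10, 20, 30, 40], [1, 1, 1, 1])) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        typical_usage([])


def test_turnover_phase_uses_standard_duration():
    recs = _records([75, 90, 120], [1, 1, 1], activity="turnover")
    assert typical_usage(recs, standard_turnover_minutes=30.0,
                         turnover_activity="turnover") == pytest.approx(30.0)
    with pytest.raises(ValueError):
        typical_usage(recs, turnover_activity="turnover")


def test_typical_usage_recovers_truth_on_noisy_records():
    """Median x mean estimator within 5% at n = 200 under log-normal noise."""
    rng = np.random.default_rng(42)
    for median, qmean in [(90.0, 1.5), (200.0, 1.0), (45.0, 2.5)]:
        durations = median * np.exp(0.25 * rng.standard_normal(200))
        quantities = np.maximum(0.0, qmean * (1 + 0.1 * rng.standard_normal(200)))
        est = typical_usage(_records(durations, quantities))
        assert est == pytest.approx(median * qmean, rel=0.05)


def test_capacity_arithmetic():
    assert daily_capacity(10.0, 3.0) == 30.0
    assert daily_capacity(24.0, 5.0) == 120.0   # ward beds run 24/7
    assert annualize(30.0, 365) == 10_950.0


def test_segment_capacity_proportional_and_bounds():
    usage = pd.DataFrame({"time": [40.0, 60.0], "in_scope": [True, False]})
    cap, log = segment_capacity(100.0, usage)
    assert cap == pytest.approx(40.0)
    assert log["share"] == pytest.approx(0.4)

    all_in = pd.DataFrame({"time": [70.0], "in_scope": [True]})
    assert segment_capacity(100.0, all_in)[0] == pytest.approx(100.0)

    none_in = pd.DataFrame({"time": [70.0], "in_scope": [False]})
    cap, log = segment_capacity(100.0, none_in)
    assert cap == 0.0
    assert "warning" in log

    with pytest.raises(ValueError):
        segment_capacity(100.0, pd.DataFrame({"time": [0.0], "in_scope": [True]}))
    cap, log = segment_capacity(80.0, usage, strategy="manual", manual_share=0.25)
    assert cap == pytest.approx(20.0)


@given(st.data())
@settings(max_examples=25, deadline=None)
def test_segment_capacity_stays_within_total(data):
    n = data.draw(st.integers(1, 6))
    times = data.draw(st.lists(st.floats(0.1, 1e4), min_size=n, max_size=n))
    flags = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    total = data.draw(st.floats(0.0, 1e6))
    usage = pd.DataFrame({"time": times, "in_scope": flags})
    cap, _ = segment_capacity(total, usage)
    assert -1e-9 <= cap <= total + 1e-9


def _roster(sets, caps=None):
    caps = caps or {s: 1000.0 for s in sets}
    return SurgeonRoster(specialties={k: frozenset(v) for k, v in sets.items()},
                         capacity_minutes=caps)


def test_surgeon_classes_partition_by_identical_sets():
    roster = _roster({"a": {"breast"}, "b": {"breast"},
                      "c": {"breast", "endocrine"}, "d": {"hpb"}})
    classes, subs = surgeon_classes(roster)
    sizes = sorted(len(c.members) for c in classes)
    assert sizes == [1, 1, 2]
    assert sum(c.capacity_minutes for c in classes) == pytest.approx(4000.0)
    assert set(subs["breast"]) == {"class_breast", "class_breast+endocrine"}
    assert subs["hpb"] == ["class_hpb"]


def test_surgeon_classes_degenerate_partitions():
    same, _ = surgeon_classes(_roster({"a": {"x"}, "b": {"x"}, "c": {"x"}}))
    assert len(same) == 1 and len(same[0].members) == 3
    distinct, _ = surgeon_classes(_roster({"a": {"x"}, "b": {"y"}, "c": {"z"}}))
    assert len(distinct) == 3


@given(st.permutations(["a", "b", "c", "d", "e"]))
@settings(max_examples=20, deadline=None)
def test_surgeon_classes_order_independent(order):
    base = {"a": {"x"}, "b": {"x", "y"}, "c": {"y"}, "d": {"x"}, "e": {"x", "y"}}
    caps = {k: float(i + 1) for i, k in enumerate(sorted(base))}
    shuffled = _roster({k: base[k] for k in order}, {k: caps[k] for k in order})
    reference = _roster(base, caps)
    c1, s1 = surgeon_classes(shuffled)
    c2, s2 = surgeon_classes(reference)
    assert c1 == c2 and s1 == s2
    assert sum(c.capacity_minutes for c in c1) == pytest.approx(sum(caps.values()))


def test_average_profitability_with_community_cost_default():
    revenue = pd.DataFrame([
        {"service": "P", "location": "AMC", "amount": 1500.0},
        {"service": "P", "location": "AMC", "amount": 1500.0},
        {"service": "P", "location": "COM", "amount": 1200.0},
    ])
    cost = pd.DataFrame([{"service": "P", "location": "AMC", "amount": 100.0}])
    prof = average_profitability(revenue, cost, default_cost_from="AMC")
    assert prof.pi[("P", "AMC")] == pytest.approx(1400.0)
    assert prof.pi[("P", "COM")] == pytest.approx(1100.0)
    with pytest.raises(ValueError):
        average_profitability(revenue, cost)
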