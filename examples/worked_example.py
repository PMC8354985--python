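"""The two-service teaching instance: allocated-cost priorities vs. RNVC.

One operating room (1500 h/yr, staffed by a $300K nursing team) and 800
bed-days serve two services that both reimburse $1500/case. Traditional
accounting spreads the labor over OR time and ranks service II first; the
LP maximizes revenue net of variable cost instead and reverses the
priority, worth $10K/yr on the same capacity.
"""

from casemix import (AllocationRule, allocated_cost, bottom_line,
                     build_worked_example, myopic_allocation,
                     net_contribution_ranking, shadow_prices, solve,
                     utilization_by_service)

model = build_worked_example()

rule = AllocationRule(labor_rate=200.0, basis_resource="operating_room")
print("allocated cost per case:  I ->",
      allocated_cost("I", rule, model), " II ->", allocated_cost("II", rule, model))

ranking = net_contribution_ranking(model, rule)
print("traditional priority order:", list(ranking["service"]),
      "(net contribution", list(ranking["net_contribution"]), ")")

myo = myopic_allocation(model, ranking)
myo_rnvc = sum(model.profitability.pi[k] * v for k, v in myo.volumes.items())
print(f"myopic volumes {dict(myo.volumes)}; leaked {dict(myo.leaked)}; "
      f"profit ${myo_rnvc - model.network_building_cost:,.0f}")

sol = solve(model)
print(f"optimal volumes {dict(sol.x)}; profit ${bottom_line(sol, model):,.0f}")
or_hours = {p: f * 1500 for p, f in utilization_by_service(sol, model, "operating_room").items()}
print("OR-hours at the optimum:", or_hours, "of 1500")

duals = shadow_prices(sol, model, native_units=True)
print("shadow prices: one extra bed-day is worth",
      f"${duals['capacity[floor_beds@main]']:,.0f};",
      "an extra OR-hour is worth",
      f"${duals['capacity[operating_room@main]']:,.0f}",
      "(the OR has 200 h slack, so its opportunity cost is zero)")
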