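"""Fit the claims-code -> service map and convert leakage into unmet demand.

Leakage claims arrive indexed by an external coding system that maps
many-to-many onto internal service codes. The map is fitted from labeled
existing-demand records as empirical conditional frequencies; leaked
counts then split across services by those weights, conserving mass up to
logged unmapped codes.
"""

from casemix import fit_code_map, generate_instance, generate_raw_records, \
    map_leakage_to_unmet_demand

model, truth = generate_instance(seed=1, n_services=6)
records = generate_raw_records(model, truth, n_cases_per_service=500, seed=2)

cmap = fit_code_map(records["drg_records"])
code = sorted(cmap.weights)[1]
print(f"fitted {len(cmap.weights)} codes; e.g. {code} ->",
      {p: round(w, 3) for p, w in cmap.weights[code].items()},
      "(true:", {p: round(w, 3) for p, w in truth.drg_map[code].items()}, ")")

unmet, excluded = map_leakage_to_unmet_demand(records["leakage"], cmap)
total_claims = records["leakage"]["count"].sum()
print(f"{total_claims} leaked claims -> {sum(unmet.values()):.1f} unmet cases "
      f"({sum(excluded.values()):.0f} on unmapped codes, excluded and logged)")
by_service = {}
for (p, _l), v in unmet.items():
    by_service[p] = by_service.get(p, 0.0) + v
print("unmet demand per service:",
      {p: round(v, 1) for p, v in sorted(by_service.items())})
print("true unmet:", {p: round(v, 1) for p, v in sorted(truth.unmet_demand.items())})
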