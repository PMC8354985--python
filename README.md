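# casemix

Linear-programming case-mix and capacity allocation for multi-site health
care delivery networks.

Hospital networks routinely price their services with allocated costs:
labor and overhead are spread over procedures in proportion to the time
each consumes, and services are ranked by the resulting *net
contribution* (revenue − allocated cost). That ranking ignores the
opportunity cost of scarce capacity — a "profitable" procedure that
monopolizes the operating room or ward beds can crowd out more total
value than it brings in. `casemix` takes the optimization view instead:
capacity costs are sunk at the tactical horizon, so resources enter the
problem as constraints, services are valued by **revenue net of variable
cost** (RNVC = average revenue − average direct variable cost per case),
and the marginal value of every resource falls out of the LP as its
shadow price.

The package is aimed at health-care operations analysts: it provides the
instance model and file schemas, the LP itself, the estimation recipes
that turn raw records into parameters, the claims-code mappings, the
traditional-accounting comparator, a scenario engine, and a fully
seeded synthetic-data generator for testing every stage without access
to confidential hospital data.

## The model

Decision variables: `x[p,l]` — cases of service *p* performed at location
*l* over the horizon; `y[s,q,a,l]` — time of substitutable resource
(surgeon class) *s* deployed to specialty requirement *q*, activity *a*,
location *l*. With per-case margins `π[p,l]` and per-case time-equivalent
usages `u[p,a,r,l]`:

```
max  RNVC = Σ_l Σ_p π[p,l] · x[p,l]
s.t. Σ_p Σ_a u[p,a,r,l] · x[p,l]              ≤ c[r,l]    fixed resource r at l
     Σ_l Σ_p Σ_a u[p,a,r,l] · x[p,l]          ≤ c̃[r]      flexible resource r
     Σ_{p: spec(p)=q} u[p,a,l] · x[p,l]       ≤ Σ_s y[s,q,a,l]   coverage, q∈cap(s)
     Σ_q Σ_a Σ_l y[s,q,a,l]                   ≤ ĉ[s]      substitutable class s
     Δ⁻[p] ≤ Σ_l x[p,l] ≤ Δ⁺[p]                            network demand
     δ⁻[p,l] ≤ x[p,l] ≤ δ⁺[p,l]                            location demand
     x, y ≥ 0
```

Activities are the five phases of the surgical path (pre-operative care,
surgery, post-anesthesia recovery, ward stay, room turnover); usage and
capacity are time-equivalent units (quantity × duration), held in
minutes internally. The deployment variables carry the requirement index
*q* so that one deployed surgeon-minute can never cover two overlapping
specialty requirements at once. Labor and overhead appear only as
capacities or as an inert *network building cost* scalar subtracted for
bottom-line reporting — never as a per-case allocation.

## Worked example

A surgery department has one OR (1500 h/yr, nursing team $300K/yr) and
800 bed-days. Services I and II both reimburse $1500/case; I takes
120 OR-minutes and $100 of supplies, II takes 60 minutes and $200; each
occupies one bed-day. Demand is 500 (I) and 400 (II).

```
python examples/worked_example.py
```

prints

```
allocated cost per case:  I -> 500.0  II -> 400.0
traditional priority order: ['II', 'I'] (net contribution [1100.0, 1000.0] )
myopic volumes {('II', 'main'): 400.0, ('I', 'main'): 400.0}; leaked {'II': 0.0, 'I': 100.0}; profit $780,000
optimal volumes {('I', 'main'): 500.0, ('II', 'main'): 300.0}; profit $790,000
OR-hours at the optimum: {'I': 1000.0, 'II': 300.0} of 1500
shadow prices: one extra bed-day is worth $1,300; an extra OR-hour is worth $0 (the OR has 200 h slack, so its opportunity cost is zero)
```

Time-driven allocation of the $300K labor ($200/OR-hour) makes service
II look better per case (net contribution $1100 vs $1000), so a myopic
manager admits II first, exhausts the beds at 400/400, leaks 100 type-I
patients, and nets $780K. The labor cost is already committed, though:
on margins alone (I: $1400, II: $1300) the optimal mix is 500/300 —
$10K/yr more on identical capacity — and the binding resource is the
beds (shadow price $1300/bed-day), not the OR.

The other scripts in `examples/` walk the remaining capabilities: a
synthetic three-hospital network and its baseline utilization audit
(`synthetic_network.py`), the reallocation/recovery sweep
(`reallocation_sweep.py`), claims-code mapping (`code_mapping.py`), and
parameter estimation from raw phase records (`estimation_pipeline.py`).

## Command line

A thin CLI wraps the library for shell use:

```
casemix example OUT_DIR            # emit + solve the worked example
casemix validate MODEL_DIR         # schema and invariant report (exit 2 on failure)
casemix solve MODEL_DIR --out F    # solution.json with volumes, duals, utilization (exit 3 if infeasible)
casemix synth --seed N OUT_DIR     # synthetic instance + raw records + ground truth
casemix estimate RECORDS_DIR OUT   # typical usage and profitability from records
casemix mapfit RECORDS_DIR OUT     # claims-code -> service frequency map
casemix scenario MODEL_DIR SPEC.yaml OUT   # baseline / perturbation / recovery bundles
```

Every run writes a manifest with input hashes and the echoed
configuration.

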