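# Methods

## Model and assumptions

`casemix` solves a deterministic, aggregate, single-period allocation
problem: given a network of locations, a catalog of surgical services,
and capacitated resources, choose continuous case volumes `x[p,l]` and
substitutable-resource deployments `y[s,q,a,l]` maximizing revenue net
of variable cost (RNVC). The key accounting stance is that capacity
costs (infrastructure, equipment, contracted labor) are sunk at the
tactical horizon — roughly one year out, when staffing and rooms are
committed — so they are represented as constraints, never as per-case
allocations. Only direct variable cost (supplies, materials, lab tests)
enters the objective through the per-case margin `π[p,l]`.

Assumptions inherited by everything downstream:

* volumes are continuous and aggregate over the horizon; no scheduling,
  arrival variability, or patient-level detail;
* each case of a service consumes a *typical* resource bundle — median
  phase duration × mean quantity — identically at every volume level;
* demand bounds are exogenous box constraints at network and location
  level; leaked demand is recoverable only up to a scenario fraction;
* revenue and cost are location-specific averages; community cost
  defaults to the academic center's when unobserved.

### Substitutable deployment indexing

The coverage constraint for substitutable resources is keyed by
*(specialty requirement q, activity, location)* and the deployment
variable carries `q` explicitly. A formulation keyed only by resource
would let one deployed unit of a multi-capability class count toward
several overlapping requirements simultaneously (double allocation); the
extra index is the minimal refinement that makes each deployed unit
cover exactly one requirement. Requirements are keyed by specialty,
matching how surgeon classes are built (a class is the set of surgeons
with identical specialty sets); the generic capability-set interface
remains available for non-surgeon substitutables.

### Degenerate deployments

The LP objective is blind to `y`, so the solver may return any feasible
deployment, including ones that park unused class capacity in `y`.
After the main solve, deployment is canonicalized in two LP phases with
`x` fixed: minimize total deployed time (deployment then equals exactly
the time the case-mix consumes), then, holding that total, minimize the
maximum class utilization. Per-class utilization reports are therefore
reproducible rather than artifacts of solver tie-breaking; `x`, the
objective and the duals are untouched. The pooled substitutable
utilization (total deployed / total class capacity) is reported
alongside, and is the number comparable across runs regardless of
deployment choice.

## Units, numerics, tie-breaks

* Canonical time unit: **minutes**. Hours and (bed-)days convert at the
  I/O boundary (60 and 1440 min); capacities and usages never mix units
  internally. Shadow prices are $/minute internally and can be rescaled
  to the declared capacity unit (e.g. $/bed-day) for reporting.
* Horizon: one configurable `horizon_days` (default 365); daily
  capacities are annualized by multiplication.
* Solver: HiGHS via `scipy.optimize.linprog`, primal/dual tolerances
  1e-9 requested; returned points re-checked to 1e-6 (scaled). Duals are
  reported as ∂RNVC/∂bound in the orientation of the named bound, so
  capacity and upper-demand duals are ≥ 0, lower-demand duals ≤ 0, and
  non-binding rows carry exact zeros from the solver basis.
* Alternative optima: tests assert objective values and binding sets,
  not unique volumes, except on the worked example where the optimum is
  unique.
* Infinite demand bounds are an explicit `unbounded` sentinel in files;
  internally `math.inf`, and unbounded rows are simply omitted from the
  LP rather than given big-M values.
* Infeasibility diagnosis: each constraint family in turn receives
  elastic slack (scaled by the row's right-hand side so bed-minutes and
  cases are comparable); families whose relaxation restores feasibility
  are reported with the specific short rows. A fully elastic solve is
  the fallback when no single family suffices.
* Ranking ties in the traditional comparator break toward lower direct
  service cost, then lexicographic service id.
* Myopic allocation admits continuous volume greedily in ranking order;
  under several binding resources the admitted volume is the minimum
  over resources of remaining capacity / per-case usage, location by
  location with the academic center first. This multi-resource rule is
  the natural generalization of the single-bottleneck story and is a
  documented package choice.
* Directional-change codes use tolerance τ = max(1e-6 × baseline, 1e-9)
  per service so solver noise below τ never flips a sign.

## Estimation

* **Typical usage** = median phase duration (phases I–IV) × mean
  quantity; the even-sample median is midpoint-interpolated. Phase V
  (turnover) always uses the configured standard turnover duration. A
  `usage_quantile` hook generalizes the median for conservative
  planning; the default 0.5 reproduces median behavior.
* **Service selection**: annual volume ≥ a required threshold (no
  default — it is institution-specific) and, optionally, at least one
  case every month.
* **Equipment screen**: keep a type-A resource iff critical or used in
  ≥ 5% of some service's cases (boundary inclusive).
* **Capacity segmentation** to the studied scope is pluggable:
  proportional historical share (default), manual share, or peak-period
  share; output is clamped to [0, total] and the applied share is
  logged. Zero historical usage is an error prompting a manual share.
* **Code maps** are empirical conditional frequencies
  w[d→p] = count(d,p)/count(d) fitted from labeled records; unseen codes
  are excluded and logged, never imputed or smoothed. Encounter payments
  are apportioned across the encounter's mappable codes with weights
  renormalized per encounter (a primary-code-only mode is available);
  counts and dollars are conserved up to the logged exclusions.

## Scenario engine

* **baseline**: demand pinned to current academic-center volumes;
  reports utilization and a ward-bed lower bound
  Σ volume × length-of-stay / horizon.
* **casemix_perturbation**: per-service bounds at baseline × (1 ± x%),
  an extra total-volume row at baseline-total × (1 ± y%), and bottleneck
  resources capped by replacing their capacity with baseline usage (the
  linear equivalent of "utilization at most baseline" at fixed
  capacity). Reports the relative RNVC gain and ±1/0 directional codes.
* **reallocation_recovery**: at each grid point (realloc%, w%) the
  academic center may shed up to realloc% of each service's baseline
  volume to the community, the network may serve up to w% of that
  service's unmet demand wherever the LP finds best (recovery enters
  network-level bounds only), and existing demand is never dropped (the
  per-service network lower bound stays at baseline, so the baseline
  point remains feasible everywhere and the surface is anchored at the
  baseline RNVC when realloc = w = 0). Ward beds are reporting-only by
  default, with the bed requirement reported against a stated reference;
  a flag hardens them.

Because the feasible regions are nested along every scenario axis and an
LP's value is concave in its right-hand side, the RNVC surface is
non-decreasing in x%, w%, realloc% and every capacity, with
non-increasing forward differences along the reallocation axis —
properties the tests verify on synthetic instances.

## Synthetic data generator

The generator emulates the record types such a study consumes — service
catalog, multi-site resources, per-case phase records, encounter-level
financials in an external coding system, leakage claims, surgeon
rosters — with the generating parameters retained as ground truth.
Defaults describe a small but structurally faithful network: one
academic center plus two community hospitals, 12 services across four
specialties, eight surgeons partitioned into capability classes, phase
durations log-normal around known medians (σ = 0.25), quantities and
payments truncated-normal around known means (10%), a 15% leak fraction
(leakage in such systems runs 10–20% of volume), and capacities placed
so the academic operating room runs hottest (≈0.85 at baseline, beds
0.70, surgeon pool 0.62) under the default `or_bound` profile; a
`bed_bound` profile makes ward beds the constraint instead. Financial
and claims record counts scale with baseline volume, so fitted code maps
converge to the volume-weighted ground-truth conditionals. Randomness
uses one seed with per-record-type substreams, so adding services does
not reshuffle unrelated records and equal seeds give byte-identical
files.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: arrival and duration variability
at the operational level, correlated usage across phases, payer-mix
structure in payments, geographic assignment of leaked patients (claims
arrive pre-assigned to a nearest location), and coding error. Estimator
recovery results on synthetic data certify the estimators' correctness,
not the adequacy of median × mean summaries for any particular hospital.

## Problem sizes

The package's own test and demonstration runs use the default 12-service
network, 200 cases per service for estimator-recovery checks, ~1000
records per code for mapping-recovery checks, 100 random instances of
≤ 4 variables for solver-vs-enumeration checks, and 5 × 3 scenario
grids; these sizes give sampling error comfortably inside the asserted
tolerances while keeping any single run under a few seconds. All are
parameters, not limits.

## Known limitations

* Single-period, deterministic; quantile-based conservative usage and
  buffer/reserved capacity exist only as configuration hooks.
* No integer volumes; recommendations near zero volume may need manual
  rounding before operational use.
* Long-horizon decisions where labor capacity itself is variable are out
  of scope; the duals identify which resources would deserve decision
  variables in such an extension.
* The comparator implements single-basis time-driven allocation only,
  which is the form the inverted-priority phenomenon needs; multi-driver
  rate cards are out of scope.
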