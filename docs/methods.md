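# Methods

## The model

`ishipment` formulates the design and operation of an autologous cell-therapy
supply chain as a single mixed-integer linear program on a daily time grid.
The decision layers are:

1. **Establishment.** A binary `E1_m` per candidate manufacturing facility.
   Establishment carries the facility's amortised capital cost `CIM_m` and its
   fixed-variable cost `CFVM_m` (the roughly 80 % of variable manufacturing
   cost — personnel, equipment maintenance — that scales with installed
   parallel lines, not with utilisation).  Both are expressed per modelled
   horizon and are shared equally by the `NP` therapies of the horizon, which
   is what makes under-utilised facilities expensive per therapy.
2. **Matching.** Binaries `X1_{c,m}` and `X2_{m,h}` permit transport between a
   leukapheresis site `c` (or hospital `h`) and facility `m` only if the
   facility is established.
3. **Journey selection.** For each patient `p`, exactly one outbound indicator
   `Y1_{p,c,m,j,t}` and one return indicator `Y2_{p,m,h,j,t}` pick the
   facility, the courier class `j` of each leg and the departure days.
   Courier classes differ only in delivery duration (24 h vs 48 h) and
   per-day, pair-specific unit rates `U1`/`U2`; one duration per class serves
   both legs.
4. **Flows.** Unit flow variables (`OUTC`, `LSR`, `LSA`, `INM`, `OUTM`,
   `MSO`, `FTR`, `INH`) propagate each patient's sample through equality
   balances: check-in + `TLS` → ready to ship; + `TT1_j` → enters
   manufacturing; + `TMFE + TQC` → released; + `TT2_j` → delivered.  Because
   the balances are equalities, no waiting is possible anywhere; a patient's
   entire timeline is determined by the three discrete choices.  This is also
   what makes exhaustive enumeration exact on small instances (see *Oracle*).

Demand is satisfied exactly (total deliveries equal `NP`), each therapy may
only return to the hospital co-located with the patient's check-in site
(generalised to any number of site–hospital pairs), and flows are gated into
`[FMIN, FMAX] = [0, 1]` by their indicators.  Optional scenario bounds cap the
per-patient return time (`TRT_p ≤ ND`), the average return time (`ATRT`), and
the number of established facilities (`Σ E1_m ≤ U^M`).

Every generated constraint row carries a family tag, and the model exposes the
tag census so tests can assert that no family is silently missing.

### Capacity semantics

Capacity is written twice, deliberately:

- **Running-window accounting (as printed).** `CAP_{m,t} = FCAP_m − Σ INM`
  over the window `t − TMFE ≤ t̂ ≤ t`, and day-`t` net load
  `Σ INM(t) − Σ OUTM(t) ≤ CAP_{m,t}`.  Note the window includes day `t`
  itself, so a same-day entry is counted both in the window and on the load
  side; entering `k` therapies on one day therefore requires roughly `2k`
  lines of headroom.  In the edge case of a single-line facility, a lone entry
  is only feasible when an exit coincides on the same day.
- **Explicit work-in-progress safeguard.** Therapies inside their
  manufacturing window (`t − TMFE + 1 ≤ entry ≤ t`) never exceed `FCAP_m`.
  This is the independently testable statement "concurrent therapies ≤
  parallel lines".

The MILP, the solution validator and the enumeration oracle all apply the
same two checks (one shared helper), so feasibility verdicts agree across the
three routes by construction.  QC is excluded from the capacity window: QC
runs on separate capacity roughly twenty-fold larger than manufacturing and is
never limiting.

### Occupancy and utilisation

The model carries the occupancy variable `DURM_{p,m,t}`, defined recursively
as `DURM(t) − DURM(t−1) = INM(t−1) − OUTM(t−1)` with an empty day-0 state —
the telescoped form of the cumulative definition.  As defined, `DURM` is 1
from the day after entry through the release day, i.e. over `TMFE + TQC`
days.  The *reported* utilisation series (`RATIO_{m,t}`, a post-solve
quantity, not a constrained variable) instead counts therapies inside their
`TMFE`-day manufacturing window divided by `FCAP_m`, consistent with the
capacity window and with QC being non-limiting.  With that convention the
conservation identity holds exactly: summed over facilities and days,
utilisation × parallel lines = `NP × TMFE`.

### Boundary conventions

The grid is 1-based.  Variables whose defining time-shifted balance would
reach before day 1 (samples in transit or in process "before the world
began") are fixed to zero; without this, unpinned early-time flow variables
could materialise therapies with no leukapheresis sample and evade
return-time bounds.  At the other end, shifted balances are generated only
while the shifted index stays inside the horizon; together with exact demand
satisfaction this forbids journeys that would exit the horizon.

## Parameters and defaults

| symbol | meaning | default (fixtures) |
|---|---|---|
| `TLS` | leukapheresis duration | 1 day (`paper6`) |
| `TMFE` | manufacturing duration | 7 days; 19-day regime via override |
| `TQC` | quality-control duration | 7 days (`paper6`), 2 (`tiny2`) |
| `TT_j` | courier delivery duration | 1 or 2 days (24 h / 48 h classes) |
| `FCAP_m` | parallel production lines | 4 / 10 / 31 across the six candidates |
| `CQC` | QC cost per therapy | $15 000 (placeholder) |
| `CVM` | material cost per therapy | $25 000 (placeholder, per-patient overridable) |
| `CIM_m`, `CFVM_m` | capital (amortised) and fixed-variable cost per horizon | $150 000 and $300 000 per line (placeholders) |
| `FMIN`, `FMAX` | flow gates | 0 and 1 |
| `U^M` | facility-count cap | none (unconstrained); constrained scenarios default to 2 |

The `paper6` parallel-line counts (4, 31, 10, 4, 31, 10) are pinned by the
weekly-capacity totals of the reference scenarios the fixture mirrors; the
cost entries are illustrative placeholders with realistic magnitudes (roughly
$100–200k per therapy all-in, manufacturing-dominated) and are meant to be
replaced by users with their own cost tables.  `amortised_capital_cost`
documents the asset-price → per-horizon conversion.  The leukapheresis
duration is not printed in the sources the fixture mirrors; 1 day is the value
consistent with the 17- and 29-day fastest journeys.  Unit transport rates
grow with the site–facility region distance and the faster courier class costs
more per day than the slower one, so relaxing the return-time bound genuinely
trades time for money.

## Synthetic demand

The generator emulates the study conditions: the annual demand profile repeats
every trimester, so one 91-day trimester with a quarter of the annual patients
(remainder to the first trimester) is generated and optimised.  Arrivals are
uniform over (site × day) cells with at most 8 patients/day/site, enforced by
rejection resampling; draws are deterministic under a fixed seed.  Uniformity
over sites (rather than catchment-population weighting) is an assumption; real
demand is neither stationary nor independent across days, and no patient
dropout is modelled.  Passing tests therefore demonstrate correctness of the
optimisation machinery under the stated statistical structure, not forecasts
for any real catchment.

## Oracle

For instances within guard limits (≤ 5 patients, ≤ 3 facilities, ≤ 2 courier
classes) the oracle enumerates every (facility, courier-1, courier-2)
assignment per patient, derives each timeline deterministically (the equality
balances leave no slack), applies exactly the validator's feasibility checks
(horizon, return-time bounds, facility cap, both capacity checks) and
evaluates cost with the open set equal to the set of used facilities (opening
an unused facility can never reduce cost since all cost coefficients are
non-negative).  The MILP is required to match the oracle's optimal cost to
1e-6 and its feasibility verdict exactly over seeded random instance families.

## Numerical choices

- Default solver HiGHS (`scipy.optimize.milp`), single-threaded and
  deterministic; gap tolerance 1e-4 by default, 1e-6 in tests that assert
  exact oracle equality.
- The objective is minimised through a single `TOTCOST` variable defined by an
  equality row, so the cost decomposition (`CTM_p`, `TTC_p`) is part of the
  model and auditable from the solution.
- The validator re-derives every family from raw variable values (indicator
  counts, itinerary timing, flow gating, capacity, demand count, return-time
  bookkeeping) and recomputes the objective from cost tables to 1e-6 relative
  tolerance.
- No tie-breaking is imposed among equal-cost optima; facility id sets in
  reports may be non-unique even when the cost is proven optimal, which is why
  reports also state the summed weekly capacity.
- Weekly capacity of a facility is its line count when `TMFE = 7`, otherwise
  `⌊FCAP · 7 / TMFE⌋`.

## Problem sizes

Patient-level time-indexed families grow as `|P|·|C|·|M|·|J|·|T|`; the
bundled full network with a 122-day horizon yields roughly 11 700 binaries per
patient, i.e. ~10⁵ binaries at 10 patients and ~10⁶ at the hundreds-of-
patients scale.  The test suite and the reproduction script therefore work on
guard-sized random instances, the `tiny2` fixture, and a scaled-down design
run of 40 patients/year (10 per trimester) on the full six-facility network —
sizes chosen so the whole pipeline (build, solve to proven optimality,
validate, report) runs on a single CPU in minutes while exercising every
constraint family at full fidelity.

## Known limitations

- Deterministic demand per run; no stochastic programming or rolling-horizon
  re-optimisation.
- No intermediate storage or cryopreservation buffers; transport and process
  durations are fixed whole days.
- Capital allocation divides by the trimester's `NP` as modelled; annual
  figures are trimester results × 4 under the repetition assumption.
- The verbatim running-window capacity accounting is stricter than plain
  work-in-progress counting for same-day entries (see *Capacity semantics*);
  both checks are applied consistently everywhere.
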