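"""Independent arithmetic validation of solved schedules.

Every check here re-evaluates one constraint family directly from the raw
variable values returned by the solver — none of it goes through the model
matrices — so a defective build or solver answer cannot validate itself.  The
capacity check is shared with the exhaustive-enumeration oracle so that the
MILP, the validator and the oracle agree on feasibility by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .demand import DemandSchedule
from .model import ScenarioConfig
from .network import SupplyNetwork
from .solve import SolutionRecord

__all__ = ["Journey", "extract_journeys", "capacity_violations",
           "validate_solution", "recompute_objective"]

_TOL = 1e-6


@dataclass(frozen=True)
class Journey:
    """A patient's fully timed itinerary reconstructed from raw variables."""

    patient_id: str
    site_id: str
    facility_id: str
    hospital_id: str
    mode_leg1: str
    mode_leg2: str
    checkin_day: int
    depart_day: int     # leukapheresis sample ready / shipped
    entry_day: int      # enters manufacturing
    exit_day: int       # leaves manufacturing + QC
    delivery_day: int   # arrives at hospital

    @property
    def return_time_days(self) -> int:
        return self.delivery_day - self.checkin_day


def extract_journeys(sol: SolutionRecord, net: SupplyNetwork,
                     demand: DemandSchedule) -> dict[str, Journey]:
    """Reconstruct each patient's itinerary from the Y1/Y2 indicators."""
    proc = net.tmfe_days + net.tqc_days
    journeys: dict[str, Journey] = {}
    y1 = {p: [] for p in demand.patient_ids}
    y2 = {p: [] for p in demand.patient_ids}
    for (p, c, m, j, t), v in sol.family("Y1").items():
        if v > 0.5 and p in y1:
            y1[p].append((c, m, j, t))
    for (p, m, h, j, t), v in sol.family("Y2").items():
        if v > 0.5 and p in y2:
            y2[p].append((m, h, j, t))
    for a in demand.arrivals:
        p = a.patient_id
        if len(y1[p]) != 1 or len(y2[p]) != 1:
            continue  # reported by validate_solution
        c, m, j1, t1 = y1[p][0]
        m2, h, j2, t2 = y2[p][0]
        journeys[p] = Journey(
            patient_id=p, site_id=c, facility_id=m, hospital_id=h,
            mode_leg1=j1, mode_leg2=j2, checkin_day=a.day, depart_day=t1,
            entry_day=t1 + net.mode_duration(j1),
            exit_day=t2, delivery_day=t2 + net.mode_duration(j2))
    return journeys


def capacity_violations(entries_by_facility: dict[str, list[int]],
                        fcap: dict[str, int], tmfe: int, proc: int,
                        horizon: int) -> list[str]:
    """Capacity audit shared by the validator and the oracle.

    ``entries_by_facility`` maps facility id to the manufacturing entry day of
    every therapy routed there.  Applies both the running-window capacity
    accounting (capacity definition + load bound) and the explicit
    work-in-progress bound (therapies inside their manufacturing window never
    exceed the parallel lines).
    """
    out: list[str] = []
    for m, entries in entries_by_facility.items():
        cap = fcap[m]
        if not entries:
            continue
        for t in range(1, horizon + 1):
            window = sum(1 for e in entries if t - tmfe <= e <= t)
            inm_t = sum(1 for e in entries if e == t)
            outm_t = sum(1 for e in entries if e + proc == t)
            if inm_t - outm_t > cap - window + _TOL:
                out.append(f"capacity load bound violated at ({m},{t})")
            wip = sum(1 for e in entries if t - tmfe + 1 <= e <= t)
            if wip > cap + _TOL:
                out.append(f"work-in-progress exceeds {cap} lines at ({m},{t})")
    return out


def recompute_objective(sol: SolutionRecord, net: SupplyNetwork,
                        demand: DemandSchedule) -> float:
    """Total cost recomputed from raw E1/Y1/Y2 values and the cost tables."""
    open_cost = sum(net.facility(m).capital_cost
                    + net.facility(m).fixed_variable_cost
                    for m, v in sol.family("E1").items() if v > 0.5)
    material = sum(net.material_cost_of(p) for p in demand.patient_ids)
    transport = 0.0
    for (p, c, m, j, t), v in sol.family("Y1").items():
        if v > 0.5:
            transport += net.mode_duration(j) * net.transport_unit_cost_leg1[(c, m, j)]
    for (p, m, h, j, t), v in sol.family("Y2").items():
        if v > 0.5:
            transport += net.mode_duration(j) * net.transport_unit_cost_leg2[(m, h, j)]
    qc = demand.n_patients * net.qc_cost
    return open_cost + material + transport + qc


def validate_solution(sol: SolutionRecord, net: SupplyNetwork,
                      demand: DemandSchedule,
                      cfg: ScenarioConfig | None = None) -> list[str]:
    """Re-check every constraint family arithmetically from raw values.

    Returns an empty list for any genuinely feasible solution; each violation
    string names the family and the offending patient / facility / day.
    """
    cfg = cfg or ScenarioConfig()
    if cfg.manufacturing_days_override is not None:
        net = dataclasses.replace(net,
                                  tmfe_days=int(cfg.manufacturing_days_override))
    if not sol.is_feasible:
        return ["solution is not feasible; nothing to validate"]
    v: list[str] = []
    proc = net.tmfe_days + net.tqc_days
    T = net.horizon_days
    hospital_of = net.hospital_of

    # --- journey selection: exactly one transport decision per leg (24, 25)
    counts1 = {p: 0 for p in demand.patient_ids}
    counts2 = {p: 0 for p in demand.patient_ids}
    for (p, *_), val in sol.family("Y1").items():
        if val > 0.5:
            counts1[p] = counts1.get(p, 0) + 1
    for (p, *_), val in sol.family("Y2").items():
        if val > 0.5:
            counts2[p] = counts2.get(p, 0) + 1
    for p in demand.patient_ids:
        if counts1[p] != 1:
            v.append(f"patient {p}: {counts1[p]} outbound transport decisions "
                     "(exactly one required)")
        if counts2[p] != 1:
            v.append(f"patient {p}: {counts2[p]} return transport decisions "
                     "(exactly one required)")
    if v:
        return v

    journeys = extract_journeys(sol, net, demand)

    # --- establishment logic (22, 23, 28, 29) and facility-count cap (26)
    e1 = sol.family("E1")
    x1 = sol.family("X1")
    x2 = sol.family("X2")
    for (c, m), val in x1.items():
        if val > 0.5 and e1.get(m, 0.0) < 0.5:
            v.append(f"site match ({c},{m}) without established facility")
    for (m, h), val in x2.items():
        if val > 0.5 and e1.get(m, 0.0) < 0.5:
            v.append(f"hospital match ({m},{h}) without established facility")
    n_open = sum(1 for val in e1.values() if val > 0.5)
    if cfg.max_facilities is not None and n_open > cfg.max_facilities:
        v.append(f"{n_open} facilities established exceeds cap "
                 f"{cfg.max_facilities}")
    for jn in journeys.values():
        if x1.get((jn.site_id, jn.facility_id), 0.0) < 0.5:
            v.append(f"patient {jn.patient_id}: transport uses unmatched "
                     f"site-facility pair ({jn.site_id},{jn.facility_id})")
        if x2.get((jn.facility_id, jn.hospital_id), 0.0) < 0.5:
            v.append(f"patient {jn.patient_id}: transport uses unmatched "
                     f"facility-hospital pair ({jn.facility_id},{jn.hospital_id})")

    # --- co-location (generalised 30-33)
    for jn in journeys.values():
        own = hospital_of.get(demand.site_of(jn.patient_id))
        if jn.hospital_id != own:
            v.append(f"patient {jn.patient_id}: therapy delivered to "
                     f"{jn.hospital_id}, not the co-located hospital {own}")
        if jn.site_id != demand.site_of(jn.patient_id):
            v.append(f"patient {jn.patient_id}: sample shipped from "
                     f"{jn.site_id}, not the check-in site")

    # --- material balances (12-19): the unit flow must follow the itinerary
    for jn in journeys.values():
        p = jn.patient_id
        if jn.depart_day != jn.checkin_day + net.tls_days:
            v.append(f"patient {p}: sample shipped on day {jn.depart_day}, "
                     f"expected {jn.checkin_day + net.tls_days} (leukapheresis)")
        if jn.exit_day != jn.entry_day + proc:
            v.append(f"patient {p}: facility exit day {jn.exit_day}, expected "
                     f"{jn.entry_day + proc} (manufacturing + QC)")
        if jn.delivery_day > T:
            v.append(f"patient {p}: delivery day {jn.delivery_day} outside "
                     "horizon")
        checks = [
            ("OUTC", (p, jn.site_id, jn.depart_day)),
            ("LSR", (p, jn.site_id, jn.facility_id, jn.mode_leg1,
                     jn.depart_day)),
            ("LSA", (p, jn.site_id, jn.facility_id, jn.mode_leg1,
                     jn.entry_day)),
            ("INM", (p, jn.facility_id, jn.entry_day)),
            ("OUTM", (p, jn.facility_id, jn.exit_day)),
            ("MSO", (p, jn.facility_id, jn.hospital_id, jn.mode_leg2,
                     jn.exit_day)),
            ("FTR", (p, jn.facility_id, jn.hospital_id, jn.mode_leg2,
                     jn.delivery_day)),
            ("INH", (p, jn.hospital_id, jn.delivery_day)),
        ]
        for fam, idx in checks:
            if abs(sol.value(fam, idx) - 1.0) > 1e-4:
                v.append(f"patient {p}: {fam}{idx} = "
                         f"{sol.value(fam, idx):.4f}, expected 1 on itinerary")
        total = sum(val for (pp, *_), val in sol.family("INH").items()
                    if pp == p)
        if abs(total - 1.0) > 1e-4:
            v.append(f"patient {p}: total hospital arrivals {total:.4f} != 1")

    # --- flow gating (34-37): flows outside the chosen indicators
    y1 = sol.family("Y1")
    y2 = sol.family("Y2")
    for idx, val in sol.family("LSR").items():
        lo = net.fmin * y1.get(idx, 0.0) - _TOL
        hi = net.fmax * y1.get(idx, 0.0) + _TOL
        if not (lo <= val <= hi):
            v.append(f"LSR{idx} = {val:.4f} outside its indicator gate")
    for idx, val in sol.family("MSO").items():
        lo = net.fmin * y2.get(idx, 0.0) - _TOL
        hi = net.fmax * y2.get(idx, 0.0) + _TOL
        if not (lo <= val <= hi):
            v.append(f"MSO{idx} = {val:.4f} outside its indicator gate")

    # --- capacity (20, 21 + explicit WIP safeguard)
    entries: dict[str, list[int]] = {m: [] for m in net.facility_ids}
    for jn in journeys.values():
        entries[jn.facility_id].append(jn.entry_day)
    fcap = {m: net.facility(m).parallel_lines for m in net.facility_ids}
    v.extend(capacity_violations(entries, fcap, net.tmfe_days, proc, T))

    # --- demand satisfaction (27)
    total_inh = sum(sol.family("INH").values())
    if abs(total_inh - demand.n_patients) > 1e-4:
        v.append(f"total deliveries {total_inh:.4f} != demand "
                 f"{demand.n_patients}")

    # --- time bookkeeping (38-44)
    trts = []
    for jn in journeys.values():
        p = jn.patient_id
        trt = jn.return_time_days
        trts.append(trt)
        if jn.checkin_day > jn.delivery_day:
            v.append(f"patient {p}: delivery precedes check-in")
        if abs(sol.value("TRT", p) - trt) > 1e-4:
            v.append(f"patient {p}: TRT variable {sol.value('TRT', p):.4f} "
                     f"!= itinerary return time {trt}")
        if (cfg.per_patient_return_bound_days is not None
                and trt > cfg.per_patient_return_bound_days + _TOL):
            v.append(f"patient {p}: return time {trt} exceeds bound "
                     f"{cfg.per_patient_return_bound_days}")
    if trts:
        atrt = sum(trts) / len(trts)
        if abs(sol.value("ATRT") - atrt) > 1e-4:
            v.append(f"ATRT variable {sol.value('ATRT'):.4f} != mean return "
                     f"time {atrt:.4f}")
        if (cfg.average_return_bound_days is not None
                and atrt > cfg.average_return_bound_days + 1e-4):
            v.append(f"average return time {atrt:.4f} exceeds bound "
                     f"{cfg.average_return_bound_days}")

    # --- objective (8, 9, 11) recomputed from raw values
    if sol.objective_value is not None:
        recomputed = recompute_objective(sol, net, demand)
        denom = max(1.0, abs(sol.objective_value))
        if abs(recomputed - sol.objective_value) / denom > 1e-6:
            v.append(f"objective {sol.objective_value:.6f} != recomputed "
                     f"cost {recomputed:.6f}")
    return v
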