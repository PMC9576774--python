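"""Exhaustive-enumeration optimiser for tiny instances.

Because the material balances are equalities with no slack, a patient's
timeline is fully determined by three choices: the manufacturing facility and
the courier class of each transport leg.  Enumerating those choices for every
patient therefore covers the entire decision space exactly, which makes this
module usable as ground truth for the MILP on guarded-size instances.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

from .demand import DemandSchedule
from .model import ScenarioConfig
from .network import SupplyNetwork
from .validate import capacity_violations

__all__ = ["EnumeratedPlan", "OracleResult", "OracleSizeError",
           "enumerate_optimal"]

MAX_PATIENTS = 5
MAX_FACILITIES = 3
MAX_MODES = 2


class OracleSizeError(ValueError):
    """Instance exceeds the enumeration guards."""


@dataclass(frozen=True)
class EnumeratedPlan:
    """One patient's choice triple with the implied deterministic timeline."""

    patient_id: str
    facility_id: str
    mode_leg1: str
    mode_leg2: str
    checkin_day: int
    entry_day: int
    exit_day: int
    delivery_day: int

    @property
    def return_time_days(self) -> int:
        return self.delivery_day - self.checkin_day


@dataclass
class OracleResult:
    feasible: bool
    min_cost: float | None = None
    plans: tuple[EnumeratedPlan, ...] = ()
    open_facilities: tuple[str, ...] = ()


def enumerate_optimal(net: SupplyNetwork, demand: DemandSchedule,
                      cfg: ScenarioConfig | None = None) -> OracleResult:
    """Exact optimum by brute force over all facility/mode assignments."""
    cfg = cfg or ScenarioConfig()
    if cfg.manufacturing_days_override is not None:
        net = dataclasses.replace(net,
                                  tmfe_days=int(cfg.manufacturing_days_override))
    if demand.n_patients > MAX_PATIENTS:
        raise OracleSizeError(f"more than {MAX_PATIENTS} patients")
    if len(net.facilities) > MAX_FACILITIES:
        raise OracleSizeError(f"more than {MAX_FACILITIES} facilities")
    if len(net.modes) > MAX_MODES:
        raise OracleSizeError(f"more than {MAX_MODES} transport modes")

    T = net.horizon_days
    proc = net.tmfe_days + net.tqc_days
    hospital_of = net.hospital_of
    fcap = {m: net.facility(m).parallel_lines for m in net.facility_ids}
    fac_cost = {m: net.facility(m).capital_cost
                + net.facility(m).fixed_variable_cost
                for m in net.facility_ids}
    base = (sum(net.material_cost_of(p) for p in demand.patient_ids)
            + demand.n_patients * net.qc_cost)

    if demand.n_patients == 0:
        return OracleResult(feasible=True, min_cost=0.0)

    # per patient: every (facility, mode1, mode2) with its timeline and cost
    options = []
    for a in demand.arrivals:
        per_patient = []
        depart = a.day + net.tls_days
        for m in net.facility_ids:
            for j1 in net.mode_ids:
                entry = depart + net.mode_duration(j1)
                exit_ = entry + proc
                for j2 in net.mode_ids:
                    delivery = exit_ + net.mode_duration(j2)
                    if delivery > T:
                        continue
                    cost = (net.mode_duration(j1)
                            * net.transport_unit_cost_leg1[(a.site_id, m, j1)]
                            + net.mode_duration(j2)
                            * net.transport_unit_cost_leg2[
                                (m, hospital_of[a.site_id], j2)])
                    plan = EnumeratedPlan(a.patient_id, m, j1, j2, a.day,
                                          entry, exit_, delivery)
                    per_patient.append((plan, cost))
        if not per_patient:
            return OracleResult(feasible=False)
        options.append(per_patient)

    nd = cfg.per_patient_return_bound_days
    atrt_bound = cfg.average_return_bound_days
    umax = cfg.max_facilities
    np_ = demand.n_patients

    best_cost = None
    best_plans: tuple[EnumeratedPlan, ...] = ()
    best_open: tuple[str, ...] = ()
    for combo in itertools.product(*options):
        plans = [pc[0] for pc in combo]
        if nd is not None and any(pl.return_time_days > nd for pl in plans):
            continue
        if atrt_bound is not None:
            if sum(pl.return_time_days for pl in plans) / np_ > atrt_bound + 1e-9:
                continue
        used = sorted({pl.facility_id for pl in plans})
        if umax is not None and len(used) > umax:
            continue
        entries: dict[str, list[int]] = {m: [] for m in net.facility_ids}
        for pl in plans:
            entries[pl.facility_id].append(pl.entry_day)
        if capacity_violations(entries, fcap, net.tmfe_days, proc, T):
            continue
        cost = base + sum(fac_cost[m] for m in used) + sum(pc[1] for pc in combo)
        if best_cost is None or cost < best_cost - 1e-9:
            best_cost = cost
            best_plans = tuple(plans)
            best_open = tuple(used)
    if best_cost is None:
        return OracleResult(feasible=False)
    return OracleResult(feasible=True, min_cost=best_cost, plans=best_plans,
                        open_facilities=best_open)
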