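"""Key performance indicators of a solved schedule.

Cost per therapy and its split (manufacturing / transport / QC), the facilities
established with their weekly capacity, the per-facility utilisation series,
and the per-patient and average vein-to-vein return times.

Utilisation is reported as the fraction of a facility's parallel lines occupied
by therapies inside their manufacturing window on each day.  QC runs on
separate, much larger capacity and is therefore excluded from occupancy, which
makes total utilisation conserve exactly: summed over facilities and days,
utilisation x parallel lines equals (number of patients) x (manufacturing
days).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .demand import DemandSchedule
from .model import ScenarioConfig
from .network import SupplyNetwork
from .solve import SolutionRecord
from .validate import extract_journeys, recompute_objective

__all__ = ["KpiReport", "extract_kpis", "weekly_capacity"]


def weekly_capacity(parallel_lines: int, tmfe_days: int) -> int:
    """Therapies per week a facility can start.

    Equals the number of parallel lines when manufacturing takes 7 days;
    otherwise lines x 7 / manufacturing-days, rounded down.
    """
    if tmfe_days == 7:
        return parallel_lines
    return int(parallel_lines * 7 // tmfe_days)


@dataclass
class KpiReport:
    total_cost: float
    avg_cost_per_therapy: float
    cost_shares: dict            # {"manufacturing","transport","qc"} -> fraction
    facilities_built: tuple      # facility ids
    weekly_capacity_built: int
    utilisation: dict            # (facility_id, day) -> occupied fraction
    trt_per_patient: dict        # patient_id -> days
    atrt: float
    mode_usage: dict = field(default_factory=dict)  # (leg, mode_id) -> count


def extract_kpis(sol: SolutionRecord, net: SupplyNetwork,
                 demand: DemandSchedule,
                 cfg: ScenarioConfig | None = None) -> KpiReport:
    cfg = cfg or ScenarioConfig()
    if cfg.manufacturing_days_override is not None:
        net = dataclasses.replace(net,
                                  tmfe_days=int(cfg.manufacturing_days_override))
    if not sol.is_feasible:
        raise ValueError("KPIs require a feasible solution")
    np_ = demand.n_patients
    journeys = extract_journeys(sol, net, demand)

    built = tuple(sorted(m for m, val in sol.family("E1").items()
                         if val > 0.5))
    manufacturing = (sum(net.facility(m).capital_cost
                         + net.facility(m).fixed_variable_cost for m in built)
                     + sum(net.material_cost_of(p) for p in demand.patient_ids))
    transport = 0.0
    mode_usage: dict = {}
    for jn in journeys.values():
        transport += (net.mode_duration(jn.mode_leg1)
                      * net.transport_unit_cost_leg1[(jn.site_id,
                                                      jn.facility_id,
                                                      jn.mode_leg1)])
        transport += (net.mode_duration(jn.mode_leg2)
                      * net.transport_unit_cost_leg2[(jn.facility_id,
                                                     jn.hospital_id,
                                                     jn.mode_leg2)])
        mode_usage[("leg1", jn.mode_leg1)] = \
            mode_usage.get(("leg1", jn.mode_leg1), 0) + 1
        mode_usage[("leg2", jn.mode_leg2)] = \
            mode_usage.get(("leg2", jn.mode_leg2), 0) + 1
    qc = np_ * net.qc_cost
    total = manufacturing + transport + qc
    if sol.objective_value is None:
        objective = recompute_objective(sol, net, demand)
    else:
        objective = sol.objective_value
    shares = ({k: val / total for k, val in
               (("manufacturing", manufacturing), ("transport", transport),
                ("qc", qc))} if total > 0
              else {"manufacturing": 0.0, "transport": 0.0, "qc": 0.0})

    utilisation: dict = {}
    for m in built:
        lines = net.facility(m).parallel_lines
        entries = [jn.entry_day for jn in journeys.values()
                   if jn.facility_id == m]
        for t in range(1, net.horizon_days + 1):
            occupied = sum(1 for e in entries
                           if e <= t <= e + net.tmfe_days - 1)
            utilisation[(m, t)] = occupied / lines

    trt = {p: jn.return_time_days for p, jn in journeys.items()}
    atrt = sum(trt.values()) / len(trt) if trt else 0.0
    return KpiReport(
        total_cost=objective,
        avg_cost_per_therapy=objective / np_ if np_ else 0.0,
        cost_shares=shares,
        facilities_built=built,
        weekly_capacity_built=sum(
            weekly_capacity(net.facility(m).parallel_lines, net.tmfe_days)
            for m in built),
        utilisation=utilisation,
        trt_per_patient=trt,
        atrt=atrt,
        mode_usage=mode_usage,
    )
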