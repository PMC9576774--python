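"""Assembly of the patient-level supply-chain scheduling MILP.

The model selects which candidate manufacturing facilities to establish
(``E1``), matches sites and hospitals to facilities (``X1``/``X2``), chooses a
courier service class for each patient's two transport legs (``Y1``/``Y2``) and
propagates each patient's unit sample through a daily-resolution time grid via
equality material balances (leukapheresis -> outbound transport ->
manufacturing + QC -> return transport -> hospital).  The objective minimises
the total cost of all therapies: amortised capital and fixed-variable
manufacturing cost of the established facilities (allocated evenly over the
patients of the modelled trimester), per-patient material cost, transport cost
of both legs and a fixed QC cost per therapy.

Every constraint row is registered under a tag naming its constraint family so
the assembled model can be audited for completeness; the tags are the numbers
``"8"``-``"44"`` of the formulation (with ``"30-33"`` for the generalised
co-location family and ``"wip"`` for the redundant explicit work-in-progress
safeguard).  Facility utilisation (``RATIO``) is a reporting quantity computed
after solving and is deliberately not a model variable.

Boundary conventions: the grid is 1-based and empty before day 1 (nothing in
transit or in process), so any flow variable whose defining time-shifted
balance would reach before day 1 is fixed to zero; time-shifted balances are
generated only while the shifted index stays inside the horizon, which together
with exact demand satisfaction forbids journeys that would exit the horizon.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .demand import DemandSchedule
from .mip import LinearModel
from .network import SupplyNetwork, min_return_time

__all__ = ["ScenarioConfig", "ScheduleModel", "ModelStatistics", "BuildError",
           "build_model", "add_objective_and_costs", "add_material_balances",
           "add_capacity_constraints", "add_network_and_logic",
           "add_demand_and_time", "count_statistics", "expected_tags"]


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario-level knobs layered on top of a network instance.

    ``max_facilities`` is the cap on established facilities (None =
    unconstrained); ``per_patient_return_bound_days`` bounds every patient's
    vein-to-vein return time, ``average_return_bound_days`` bounds the average;
    ``manufacturing_days_override`` switches between manufacturing regimes
    (e.g. 7 vs 19 days) without editing the network fixture.
    """

    max_facilities: int | None = None
    per_patient_return_bound_days: int | None = None
    average_return_bound_days: float | None = None
    manufacturing_days_override: int | None = None


@dataclass(frozen=True)
class ModelStatistics:
    n_binary: int
    n_continuous: int
    n_constraints: int


@dataclass
class ScheduleModel:
    net: SupplyNetwork
    demand: DemandSchedule
    cfg: ScenarioConfig
    lm: LinearModel
    arrival_site: dict   # patient_id -> site_id
    arrival_day: dict    # patient_id -> day

    @property
    def horizon(self) -> int:
        return self.net.horizon_days

    @property
    def n_patients(self) -> int:
        return self.demand.n_patients

    def constraint_tags(self) -> dict[str, int]:
        return self.lm.tag_counts()


def expected_tags(cfg: ScenarioConfig, n_patients: int) -> set[str]:
    """Constraint-family tags a fully assembled model must carry."""
    tags = {"8", "11", "12", "13", "14", "15", "16", "17", "18", "19",
            "20", "21", "wip", "22", "23", "24", "25", "26", "27", "28", "29",
            "30-33", "34", "35", "36", "37", "38", "39", "40", "41", "43", "44"}
    if n_patients:
        tags.add("9")
    if cfg.per_patient_return_bound_days is not None:
        tags.add("42")
    if n_patients == 0:
        tags -= {"9", "11", "12", "13", "14", "15", "16", "17", "18", "19",
                 "24", "25", "28", "29", "30-33", "34", "35", "36", "37",
                 "38", "39", "40", "41", "42", "43", "44", "21", "wip"}
        # with no patients only the structural families (and the degenerate
        # capacity / facility-cap / demand rows) remain
        tags |= {"20", "26", "27"}
    return tags


# --------------------------------------------------------------------- build

def build_model(net: SupplyNetwork, demand: DemandSchedule,
                cfg: ScenarioConfig | None = None) -> ScheduleModel:
    """Assemble the complete MILP for a network, a demand schedule and a
    scenario configuration."""
    cfg = cfg or ScenarioConfig()
    if cfg.manufacturing_days_override is not None:
        net = dataclasses.replace(net,
                                  tmfe_days=int(cfg.manufacturing_days_override))
    if net.modes and net.horizon_days < min_return_time(net):
        raise BuildError("horizon too short for the fastest feasible journey")
    bad = demand.validate(net)
    if bad:
        raise BuildError("; ".join(bad))

    model = ScheduleModel(
        net=net, demand=demand, cfg=cfg, lm=LinearModel(),
        arrival_site={a.patient_id: a.site_id for a in demand.arrivals},
        arrival_day={a.patient_id: a.day for a in demand.arrivals},
    )
    _declare_variables(model)
    add_objective_and_costs(model)
    add_material_balances(model)
    add_capacity_constraints(model)
    add_network_and_logic(model, cfg)
    add_demand_and_time(model, cfg)
    return model


def _declare_variables(model: ScheduleModel) -> None:
    net, lm = model.net, model.lm
    P = model.demand.patient_ids
    C, H, M, J = net.site_ids, net.hospital_ids, net.facility_ids, net.mode_ids
    T = net.horizon_days
    dur = {j: net.mode_duration(j) for j in J}
    proc = net.tmfe_days + net.tqc_days

    for m in M:
        lm.add_var("E1", m, binary=True)
    for c in C:
        for m in M:
            lm.add_var("X1", (c, m), binary=True)
    for m in M:
        for h in H:
            lm.add_var("X2", (m, h), binary=True)

    ts = range(1, T + 1)
    for p in P:
        for c in C:
            for m in M:
                for j in J:
                    for t in ts:
                        lm.add_var("Y1", (p, c, m, j, t), binary=True)
        for m in M:
            for h in H:
                for j in J:
                    for t in ts:
                        lm.add_var("Y2", (p, m, h, j, t), binary=True)
        for c in C:
            for t in ts:
                col = lm.add_var("OUTC", (p, c, t))
                if t <= net.tls_days:
                    lm.fix(col, 0.0)  # no leukapheresis completed before day 1
        for c in C:
            for m in M:
                for j in J:
                    for t in ts:
                        lm.add_var("LSR", (p, c, m, j, t))
                        col = lm.add_var("LSA", (p, c, m, j, t))
                        if t <= dur[j]:
                            lm.fix(col, 0.0)  # nothing in transit before day 1
        for m in M:
            for t in ts:
                lm.add_var("INM", (p, m, t))
                col = lm.add_var("OUTM", (p, m, t))
                if t <= proc:
                    lm.fix(col, 0.0)  # nothing in process before day 1
                lm.add_var("DURM", (p, m, t))
        for m in M:
            for h in H:
                for j in J:
                    for t in ts:
                        lm.add_var("MSO", (p, m, h, j, t))
                        col = lm.add_var("FTR", (p, m, h, j, t))
                        if t <= dur[j]:
                            lm.fix(col, 0.0)
        for h in H:
            for t in ts:
                lm.add_var("INH", (p, h, t))

    for m in M:
        fcap = net.facility(m).parallel_lines
        for t in ts:
            lm.add_var("CAP", (m, t), lb=-float(max(len(P), 1)), ub=float(fcap))

    for p in P:
        lm.add_var("STT", p, lb=0.0, ub=float(T))
        lm.add_var("CTT", p, lb=0.0, ub=float(T))
        lm.add_var("TRT", p, lb=0.0, ub=float(T))
        lm.add_var("CTM", p, lb=0.0, ub=math.inf)
        lm.add_var("TTC", p, lb=0.0, ub=math.inf)
    lm.add_var("ATRT", None, lb=0.0, ub=float(T))
    lm.add_var("TOTCOST", None, lb=0.0, ub=math.inf)


def add_objective_and_costs(model: ScheduleModel) -> ScheduleModel:
    """Objective (min total cost) and the per-therapy cost definitions."""
    net, lm = model.net, model.lm
    P = model.demand.patient_ids
    np_ = len(P)
    # manufacturing cost per therapy: an equal share of every established
    # facility's amortised capital + fixed-variable cost, plus materials
    if np_:
        fac_cost = {m: (net.facility(m).capital_cost
                        + net.facility(m).fixed_variable_cost) / np_
                    for m in net.facility_ids}
        for p in P:
            terms = [(lm.var("CTM", p), 1.0)]
            terms += [(lm.var("E1", m), -fac_cost[m]) for m in net.facility_ids]
            cvm = net.material_cost_of(p)
            lm.add_constr("9", terms, cvm, cvm)
        for p in P:
            terms = [(lm.var("TTC", p), 1.0)]
            for (pp, c, m, j, t), col in lm.family("Y1").items():
                if pp == p:
                    u = net.transport_unit_cost_leg1[(c, m, j)]
                    terms.append((col, -net.mode_duration(j) * u))
            for (pp, m, h, j, t), col in lm.family("Y2").items():
                if pp == p:
                    u = net.transport_unit_cost_leg2[(m, h, j)]
                    terms.append((col, -net.mode_duration(j) * u))
            lm.add_constr("11", terms, 0.0, 0.0)
    total_qc = np_ * net.qc_cost
    terms = [(lm.var("TOTCOST"), 1.0)]
    terms += [(lm.var("CTM", p), -1.0) for p in P]
    terms += [(lm.var("TTC", p), -1.0) for p in P]
    lm.add_constr("8", terms, total_qc, total_qc)
    lm.set_objective_var(lm.var("TOTCOST"))
    return model


def add_material_balances(model: ScheduleModel) -> ScheduleModel:
    """Equality balances pushing each sample through its journey."""
    net, lm = model.net, model.lm
    P = model.demand.patient_ids
    C, H, M, J = net.site_ids, net.hospital_ids, net.facility_ids, net.mode_ids
    T = net.horizon_days
    dur = {j: net.mode_duration(j) for j in J}
    proc = net.tmfe_days + net.tqc_days

    for p in P:
        a_c, a_t = model.arrival_site[p], model.arrival_day[p]
        for c in C:
            for t in range(1, T + 1 - net.tls_days):
                inc = 1.0 if (c == a_c and t == a_t) else 0.0
                lm.add_constr("12",
                              [(lm.var("OUTC", (p, c, t + net.tls_days)), 1.0)],
                              inc, inc)
        for c in C:
            for m in M:
                for j in J:
                    d = dur[j]
                    for t in range(1, T + 1 - d):
                        lm.add_constr("13",
                                      [(lm.var("LSR", (p, c, m, j, t)), 1.0),
                                       (lm.var("LSA", (p, c, m, j, t + d)), -1.0)],
                                      0.0, 0.0)
        for c in C:
            for t in range(1, T + 1):
                terms = [(lm.var("OUTC", (p, c, t)), 1.0)]
                terms += [(lm.var("LSR", (p, c, m, j, t)), -1.0)
                          for m in M for j in J]
                lm.add_constr("14", terms, 0.0, 0.0)
        for m in M:
            for t in range(1, T + 1):
                terms = [(lm.var("INM", (p, m, t)), 1.0)]
                terms += [(lm.var("LSA", (p, c, m, j, t)), -1.0)
                          for c in C for j in J]
                lm.add_constr("15", terms, 0.0, 0.0)
        for m in M:
            for t in range(1, T + 1 - proc):
                lm.add_constr("16",
                              [(lm.var("INM", (p, m, t)), 1.0),
                               (lm.var("OUTM", (p, m, t + proc)), -1.0)],
                              0.0, 0.0)
        for m in M:
            for t in range(1, T + 1):
                terms = [(lm.var("OUTM", (p, m, t)), 1.0)]
                terms += [(lm.var("MSO", (p, m, h, j, t)), -1.0)
                          for h in H for j in J]
                lm.add_constr("17", terms, 0.0, 0.0)
        for m in M:
            for h in H:
                for j in J:
                    d = dur[j]
                    for t in range(1, T + 1 - d):
                        lm.add_constr("18",
                                      [(lm.var("FTR", (p, m, h, j, t + d)), 1.0),
                                       (lm.var("MSO", (p, m, h, j, t)), -1.0)],
                                      0.0, 0.0)
        for h in H:
            for t in range(1, T + 1):
                terms = [(lm.var("INH", (p, h, t)), 1.0)]
                terms += [(lm.var("FTR", (p, m, h, j, t)), -1.0)
                          for m in M for j in J]
                lm.add_constr("19", terms, 0.0, 0.0)
    return model


def add_capacity_constraints(model: ScheduleModel) -> ScheduleModel:
    """Facility capacity: the running-window definition and load bound, plus
    an equivalent explicit work-in-progress safeguard (concurrent therapies
    inside their manufacturing window never exceed the parallel lines)."""
    net, lm = model.net, model.lm
    P = model.demand.patient_ids
    T = net.horizon_days
    tmfe = net.tmfe_days
    for m in net.facility_ids:
        fcap = float(net.facility(m).parallel_lines)
        for t in range(1, T + 1):
            terms = [(lm.var("CAP", (m, t)), 1.0)]
            terms += [(lm.var("INM", (p, m, th)), 1.0)
                      for p in P for th in range(max(1, t - tmfe), t + 1)]
            lm.add_constr("20", terms, fcap, fcap)
            if P:
                terms = [(lm.var("CAP", (m, t)), -1.0)]
                terms += [(lm.var("INM", (p, m, t)), 1.0) for p in P]
                terms += [(lm.var("OUTM", (p, m, t)), -1.0) for p in P]
                lm.add_constr("21", terms, -math.inf, 0.0)
                wip = [(lm.var("INM", (p, m, th)), 1.0)
                       for p in P for th in range(max(1, t - tmfe + 1), t + 1)]
                lm.add_constr("wip", wip, -math.inf, fcap)
    return model


def add_network_and_logic(model: ScheduleModel,
                          cfg: ScenarioConfig) -> ScheduleModel:
    """Facility-establishment logic, single-journey selection, co-location and
    flow gating."""
    net, lm = model.net, model.lm
    P = model.demand.patient_ids
    C, H, M = net.site_ids, net.hospital_ids, net.facility_ids
    fmin, fmax = net.fmin, net.fmax
    hospital_of = net.hospital_of

    for c in C:
        for m in M:
            lm.add_constr("22", [(lm.var("X1", (c, m)), 1.0),
                                 (lm.var("E1", m), -1.0)], -math.inf, 0.0)
    for m in M:
        for h in H:
            lm.add_constr("23", [(lm.var("X2", (m, h)), 1.0),
                                 (lm.var("E1", m), -1.0)], -math.inf, 0.0)
    for p in P:
        terms = [(col, 1.0) for (pp, *_), col in lm.family("Y1").items()
                 if pp == p]
        lm.add_constr("24", terms, 1.0, 1.0)
        terms = [(col, 1.0) for (pp, *_), col in lm.family("Y2").items()
                 if pp == p]
        lm.add_constr("25", terms, 1.0, 1.0)
    umax = len(M) if cfg.max_facilities is None else int(cfg.max_facilities)
    lm.add_constr("26", [(lm.var("E1", m), 1.0) for m in M],
                  -math.inf, float(umax))
    for (p, c, m, j, t), col in lm.family("Y1").items():
        lm.add_constr("28", [(col, 1.0), (lm.var("X1", (c, m)), -1.0)],
                      -math.inf, 0.0)
    for (p, m, h, j, t), col in lm.family("Y2").items():
        lm.add_constr("29", [(col, 1.0), (lm.var("X2", (m, h)), -1.0)],
                      -math.inf, 0.0)
    # co-location, generalised to any number of site/hospital pairs: a
    # patient's return leg may only target the hospital co-located with the
    # site where they checked in
    for p in P:
        own = hospital_of[model.arrival_site[p]]
        for h in H:
            if h == own:
                continue
            terms = [(col, 1.0)
                     for (pp, m, hh, j, t), col in lm.family("Y2").items()
                     if pp == p and hh == h]
            lm.add_constr("30-33", terms, -math.inf, 0.0)
    for idx, col in lm.family("LSR").items():
        y = lm.var("Y1", idx)
        lm.add_constr("34", [(col, 1.0), (y, -fmin)], 0.0, math.inf)
        lm.add_constr("35", [(col, 1.0), (y, -fmax)], -math.inf, 0.0)
    for idx, col in lm.family("MSO").items():
        y = lm.var("Y2", idx)
        lm.add_constr("36", [(col, 1.0), (y, -fmin)], 0.0, math.inf)
        lm.add_constr("37", [(col, 1.0), (y, -fmax)], -math.inf, 0.0)
    return model


def add_demand_and_time(model: ScheduleModel,
                        cfg: ScenarioConfig) -> ScheduleModel:
    """Exact demand satisfaction, manufacturing-occupancy profile and the
    return-time bookkeeping with its optional bounds."""
    net, lm = model.net, model.lm
    P = model.demand.patient_ids
    T = net.horizon_days
    np_ = len(P)

    terms = [(col, 1.0) for col in lm.family("INH").values()]
    lm.add_constr("27", terms, float(np_), float(np_))

    # occupancy profile: DURM(t) - DURM(t-1) = INM(t-1) - OUTM(t-1)
    # (the cumulative-sum definition, telescoped, with an empty day-0 state)
    for p in P:
        for m in net.facility_ids:
            lm.add_constr("38", [(lm.var("DURM", (p, m, 1)), 1.0)], 0.0, 0.0)
            for t in range(2, T + 1):
                lm.add_constr("38",
                              [(lm.var("DURM", (p, m, t)), 1.0),
                               (lm.var("DURM", (p, m, t - 1)), -1.0),
                               (lm.var("INM", (p, m, t - 1)), -1.0),
                               (lm.var("OUTM", (p, m, t - 1)), 1.0)],
                              0.0, 0.0)
    for p in P:
        terms = [(lm.var("CTT", p), 1.0)]
        terms += [(col, -float(t))
                  for (pp, h, t), col in lm.family("INH").items() if pp == p]
        lm.add_constr("39", terms, 0.0, 0.0)
        a_t = float(model.arrival_day[p])
        lm.add_constr("40", [(lm.var("STT", p), 1.0)], a_t, a_t)
        lm.add_constr("41", [(lm.var("STT", p), 1.0),
                             (lm.var("CTT", p), -1.0)], -math.inf, 0.0)
        lm.add_constr("43", [(lm.var("TRT", p), 1.0),
                             (lm.var("CTT", p), -1.0),
                             (lm.var("STT", p), 1.0)], 0.0, 0.0)
        if cfg.per_patient_return_bound_days is not None:
            lm.add_constr("42", [(lm.var("TRT", p), 1.0)],
                          -math.inf, float(cfg.per_patient_return_bound_days))
    if np_:
        terms = [(lm.var("ATRT"), float(np_))]
        terms += [(lm.var("TRT", p), -1.0) for p in P]
        lm.add_constr("44", terms, 0.0, 0.0)
        if cfg.average_return_bound_days is not None:
            lm.set_bounds(lm.var("ATRT"), 0.0,
                          min(float(T), float(cfg.average_return_bound_days)))
    return model


def count_statistics(model: ScheduleModel) -> ModelStatistics:
    lm = model.lm
    return ModelStatistics(n_binary=lm.n_binary, n_continuous=lm.n_continuous,
                           n_constraints=lm.n_constraints)
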