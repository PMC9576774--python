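"""Scenario runner: demand scales x manufacturing regimes x facility caps x
return-time bound ladders, with tidy CSV/JSON outputs.

A scenario configuration is a small YAML/JSON mapping::

    network: paper6            # bundled fixture name or path to a network
    patients_per_year: 200
    manufacturing_days: 7      # optional override (7 or 19)
    max_facilities: 2          # optional; omit for the unconstrained scenario
    return_bound_days: 17      # optional return-time bound
    bound_type: average        # 'average' (default) or 'per_patient'
    seed: 1
    time_limit_s: 600
    gap_tol: 1.0e-4
    solver: highs
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .demand import DemandSchedule, generate_demand
from .kpis import KpiReport, extract_kpis
from .model import ScenarioConfig, build_model, count_statistics
from .network import SupplyNetwork, load_fixture, load_network
from .solve import SolutionRecord, solve, write_solution
from .validate import validate_solution

__all__ = ["ScenarioResult", "load_scenario_config", "run_scenario",
           "sweep_return_bounds"]

log = logging.getLogger("ishipment")


@dataclass
class ScenarioResult:
    label: str
    status: str
    bound_days: float | None
    objective_value: float | None
    gap_fraction: float
    kpis: KpiReport | None
    solution: SolutionRecord | None
    violations: tuple[str, ...] = ()


def load_scenario_config(source) -> dict:
    """Accept a dict, a YAML/JSON file path, or a YAML string."""
    if isinstance(source, dict):
        return dict(source)
    p = Path(str(source))
    if p.exists():
        return yaml.safe_load(p.read_text())
    return yaml.safe_load(str(source))


def _resolve_network(spec: str | SupplyNetwork) -> SupplyNetwork:
    if isinstance(spec, SupplyNetwork):
        return spec
    p = Path(str(spec))
    if p.exists():
        return load_network(p)
    return load_fixture(str(spec))


def _scenario_cfg(conf: dict, bound_days=None) -> ScenarioConfig:
    bound = conf.get("return_bound_days") if bound_days is None else bound_days
    bound_type = conf.get("bound_type", "average")
    return ScenarioConfig(
        max_facilities=conf.get("max_facilities"),
        per_patient_return_bound_days=(
            int(bound) if bound is not None and bound_type == "per_patient"
            else None),
        average_return_bound_days=(
            float(bound) if bound is not None and bound_type == "average"
            else None),
        manufacturing_days_override=conf.get("manufacturing_days"),
    )


def _demand_for(conf: dict, net: SupplyNetwork) -> DemandSchedule:
    if "demand_csv" in conf:
        from .demand import read_demand
        return read_demand(conf["demand_csv"], net)
    kwargs = {}
    if "trimester_days" in conf:
        kwargs["trimester_days"] = int(conf["trimester_days"])
    return generate_demand(net, int(conf["patients_per_year"]),
                           int(conf.get("seed", 0)), **kwargs)


def run_scenario(config, out_dir=None, bound_days=None) -> ScenarioResult:
    """Build demand, assemble and solve the model, validate, write reports.

    An infeasible model is an expected outcome (e.g. demand beyond aggregate
    line throughput) and is recorded as a result, not raised.
    """
    conf = load_scenario_config(config)
    label = str(conf.get("label", "scenario"))
    net = _resolve_network(conf["network"])
    demand = _demand_for(conf, net)
    cfg = _scenario_cfg(conf, bound_days)
    log.info("scenario %s: %d patients, %d sites, %d candidate facilities, "
             "%d modes, horizon %d", label, demand.n_patients, len(net.sites),
             len(net.facilities), len(net.modes), net.horizon_days)
    model = build_model(net, demand, cfg)
    stats = count_statistics(model)
    log.info("scenario %s: model has %d binaries, %d continuous, "
             "%d constraints", label, stats.n_binary, stats.n_continuous,
             stats.n_constraints)
    sol = solve(model, time_limit_s=float(conf.get("time_limit_s", 600)),
                gap_tol=float(conf.get("gap_tol", 1e-4)),
                solver=str(conf.get("solver", "highs")))
    log.info("scenario %s: solver status %s, gap %.4g", label, sol.status,
             sol.gap_fraction)
    violations: tuple[str, ...] = ()
    kpis = None
    if sol.is_feasible:
        violations = tuple(validate_solution(sol, net, demand, cfg))
        if violations:
            log.warning("scenario %s: %d validation violations", label,
                        len(violations))
        kpis = extract_kpis(sol, net, demand, cfg)
    result = ScenarioResult(
        label=label, status=sol.status,
        bound_days=bound_days if bound_days is not None
        else conf.get("return_bound_days"),
        objective_value=sol.objective_value, gap_fraction=sol.gap_fraction,
        kpis=kpis, solution=sol, violations=violations)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: ScenarioResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.solution is not None:
        write_solution(result.solution, out_dir / "solution.json")
    if result.kpis is None:
        (out_dir / "kpis.csv").write_text(
            f"label,status\n{result.label},{result.status}\n")
        return
    k = result.kpis
    pd.DataFrame([{
        "label": result.label, "status": result.status,
        "bound_days": result.bound_days, "total_cost": k.total_cost,
        "avg_cost_per_therapy": k.avg_cost_per_therapy,
        "share_manufacturing": k.cost_shares["manufacturing"],
        "share_transport": k.cost_shares["transport"],
        "share_qc": k.cost_shares["qc"],
        "facilities_built": "+".join(k.facilities_built),
        "weekly_capacity_built": k.weekly_capacity_built,
        "atrt_days": k.atrt,
        "gap_fraction": result.gap_fraction,
    }]).to_csv(out_dir / "kpis.csv", index=False)
    pd.DataFrame(
        [{"facility_id": m, "day": t, "ratio": r}
         for (m, t), r in sorted(k.utilisation.items())]
    ).to_csv(out_dir / "utilisation.csv", index=False)
    (out_dir / "trt.json").write_text(json.dumps(k.trt_per_patient, indent=1,
                                                 sort_keys=True))


def sweep_return_bounds(config, bounds, out_dir=None) -> pd.DataFrame:
    """One solve per return-time bound; returns the consolidated tidy table.

    Individual infeasible bounds are recorded as rows and the sweep continues.
    """
    conf = load_scenario_config(config)
    rows = []
    for b in sorted(bounds):
        res = run_scenario(conf, out_dir=None, bound_days=b)
        rows.append({
            "bound_days": b, "status": res.status,
            "total_cost": res.objective_value,
            "avg_cost_per_therapy": (res.kpis.avg_cost_per_therapy
                                     if res.kpis else None),
            "atrt_days": res.kpis.atrt if res.kpis else None,
            "facilities_built": "+".join(res.kpis.facilities_built)
            if res.kpis else "",
            "gap_fraction": res.gap_fraction,
        })
    table = pd.DataFrame(rows).sort_values("bound_days").reset_index(drop=True)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "sweep.csv", index=False)
    return table
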