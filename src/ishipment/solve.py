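"""Solver-agnostic MILP solving.

Solvers are looked up in a registry; the default backend is HiGHS through
:func:`scipy.optimize.milp`.  Additional backends can be registered with
:func:`register_solver` without touching the model-building code.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ScheduleModel

__all__ = ["SolutionRecord", "SolverError", "solve", "register_solver",
           "available_solvers", "write_solution", "read_solution"]

_NONZERO_TOL = 1e-7


class SolverError(EnvironmentError):
    pass


@dataclass
class SolutionRecord:
    """Solved variable values plus solver status metadata.

    ``variables`` maps each variable family name to a dict of
    ``index -> value`` holding the nonzero entries only.
    """

    status: str                      # optimal | feasible_gap | infeasible | timeout
    objective_value: float | None = None
    gap_fraction: float = 0.0
    variables: dict = field(default_factory=dict)
    solver_name: str = ""
    wall_time_s: float = 0.0

    @property
    def is_feasible(self) -> bool:
        return self.status in ("optimal", "feasible_gap")

    def value(self, family: str, index=None) -> float:
        return float(self.variables.get(family, {}).get(index, 0.0))

    def family(self, family: str) -> dict:
        return self.variables.get(family, {})


def _solve_scipy_highs(model: ScheduleModel, time_limit_s: float,
                       gap_tol: float) -> SolutionRecord:
    from scipy.optimize import milp

    c, constraint, bounds, integrality = model.lm.to_scipy()
    t0 = time.perf_counter()
    res = milp(c=c, constraints=constraint, bounds=bounds,
               integrality=integrality,
               options={"time_limit": float(time_limit_s),
                        "mip_rel_gap": float(gap_tol),
                        "disp": False})
    wall = time.perf_counter() - t0
    gap = float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else 0.0
    if res.status == 2:
        return SolutionRecord(status="infeasible", solver_name="highs",
                              wall_time_s=wall)
    if res.x is None:
        return SolutionRecord(status="timeout", solver_name="highs",
                              wall_time_s=wall)
    status = "optimal" if res.status == 0 else "feasible_gap"
    x = np.asarray(res.x)
    variables: dict = {}
    for fam, members in model.lm._families.items():
        vals = {idx: float(x[col]) for idx, col in members.items()
                if abs(x[col]) > _NONZERO_TOL}
        variables[fam] = vals
    return SolutionRecord(status=status, objective_value=float(res.fun),
                          gap_fraction=gap, variables=variables,
                          solver_name="highs", wall_time_s=wall)


_SOLVERS = {"highs": _solve_scipy_highs}


def register_solver(name: str, fn) -> None:
    """Register a backend callable ``fn(model, time_limit_s, gap_tol)``."""
    _SOLVERS[name] = fn


def available_solvers() -> tuple[str, ...]:
    return tuple(sorted(_SOLVERS))


def solve(model: ScheduleModel, time_limit_s: float = 600.0,
          gap_tol: float = 1e-4, solver: str = "highs") -> SolutionRecord:
    """Solve an assembled model, returning the best incumbent with its gap."""
    if solver not in _SOLVERS:
        raise SolverError(
            f"solver {solver!r} is not available; registered: "
            f"{', '.join(available_solvers())}")
    return _SOLVERS[solver](model, time_limit_s, gap_tol)


# ------------------------------------------------------------- serialisation

def write_solution(sol: SolutionRecord, path) -> None:
    doc = {
        "status": sol.status,
        "objective_value": sol.objective_value,
        "gap_fraction": sol.gap_fraction,
        "solver_name": sol.solver_name,
        "wall_time_s": sol.wall_time_s,
        "variables": {
            fam: [{"index": list(idx) if isinstance(idx, tuple) else idx,
                   "value": val}
                  for idx, val in sorted(vals.items(), key=lambda kv: str(kv[0]))]
            for fam, vals in sol.variables.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_solution(path) -> SolutionRecord:
    doc = json.loads(Path(path).read_text())
    variables = {}
    for fam, entries in doc.get("variables", {}).items():
        d = {}
        for e in entries:
            idx = e["index"]
            if isinstance(idx, list):
                idx = tuple(idx)
            d[idx] = float(e["value"])
        variables[fam] = d
    return SolutionRecord(status=doc["status"],
                          objective_value=doc.get("objective_value"),
                          gap_fraction=float(doc.get("gap_fraction", 0.0)),
                          variables=variables,
                          solver_name=doc.get("solver_name", ""),
                          wall_time_s=float(doc.get("wall_time_s", 0.0)))
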