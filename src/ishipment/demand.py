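"""Synthetic patient arrival schedules.

Demand is modelled per trimester: the annual demand profile repeats every
trimester, so one 91-day trimester with a quarter of the annual patients is the
unit of optimisation.  Within the trimester, arrivals are drawn uniformly over
(site x day) cells subject to the per-site daily leukapheresis capacity
(default 8 patients/day), with rejection resampling on full cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import SupplyNetwork, min_return_time

__all__ = ["PatientArrival", "DemandSchedule", "DemandError", "CapacityError",
           "generate_demand", "read_demand", "write_demand", "TRIMESTER_DAYS"]

TRIMESTER_DAYS = 91


class DemandError(ValueError):
    pass


class CapacityError(DemandError):
    """Requested demand cannot be placed under the site daily caps."""


@dataclass(frozen=True)
class PatientArrival:
    patient_id: str
    site_id: str
    day: int  # 1-based check-in day


@dataclass
class DemandSchedule:
    arrivals: tuple[PatientArrival, ...]

    @property
    def n_patients(self) -> int:
        return len(self.arrivals)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(a.patient_id for a in self.arrivals)

    def site_of(self, patient_id: str) -> str:
        return next(a.site_id for a in self.arrivals
                    if a.patient_id == patient_id)

    def day_of(self, patient_id: str) -> int:
        return next(a.day for a in self.arrivals
                    if a.patient_id == patient_id)

    def counts_by_cell(self) -> dict:
        """(site_id, day) -> number of check-ins."""
        out: dict = {}
        for a in self.arrivals:
            out[(a.site_id, a.day)] = out.get((a.site_id, a.day), 0) + 1
        return out

    def validate(self, net: SupplyNetwork | None = None) -> list[str]:
        v: list[str] = []
        seen: set[str] = set()
        for a in self.arrivals:
            if a.patient_id in seen:
                v.append(f"duplicate patient_id {a.patient_id}")
            seen.add(a.patient_id)
            if a.day < 1:
                v.append(f"patient {a.patient_id}: day {a.day} outside horizon")
        if net is not None:
            sites = {s.site_id: s for s in net.sites}
            for a in self.arrivals:
                if a.site_id not in sites:
                    v.append(f"patient {a.patient_id}: unknown site {a.site_id}")
                elif a.day > net.horizon_days:
                    v.append(f"patient {a.patient_id}: day {a.day} outside horizon")
            for (c, d), n in self.counts_by_cell().items():
                if c in sites and n > sites[c].daily_capacity:
                    v.append(f"site {c} day {d}: {n} arrivals exceed "
                             f"daily capacity {sites[c].daily_capacity}")
        return v


def generate_demand(net: SupplyNetwork, annual_patients: int, seed: int,
                    trimester_index: int = 0,
                    trimester_days: int = TRIMESTER_DAYS) -> DemandSchedule:
    """Draw one trimester of patient arrivals.

    ``annual_patients`` is split evenly over four trimesters; any remainder is
    assigned to the first trimester.  Sites and days are sampled uniformly over
    the (site x day) grid; draws landing on a cell already at its daily cap are
    rejected and redrawn.  Deterministic for a fixed seed.
    """
    if annual_patients < 0:
        raise DemandError("annual_patients must be >= 0")
    n = annual_patients // 4 + (annual_patients % 4 if trimester_index == 0 else 0)
    total_cells = sum(s.daily_capacity for s in net.sites) * trimester_days
    if n > total_cells:
        raise CapacityError(
            f"{n} arrivals cannot be placed: site caps admit only "
            f"{total_cells} over {trimester_days} days")
    if trimester_days + min_return_time(net) > net.horizon_days:
        raise DemandError(
            "network horizon too short for a full trimester of arrivals plus "
            "the fastest journey; increase horizon_days or shrink the window")
    rng = np.random.default_rng(seed)
    sites = net.sites
    counts: dict = {}
    arrivals = []
    width = max(3, len(str(max(n, 1))))
    for i in range(n):
        while True:
            s = sites[int(rng.integers(len(sites)))]
            day = int(rng.integers(1, trimester_days + 1))
            if counts.get((s.site_id, day), 0) < s.daily_capacity:
                counts[(s.site_id, day)] = counts.get((s.site_id, day), 0) + 1
                break
        arrivals.append(PatientArrival(f"p{i + 1:0{width}d}", s.site_id, day))
    return DemandSchedule(tuple(arrivals))


def write_demand(sched: DemandSchedule, path) -> None:
    rows = sorted(sched.arrivals, key=lambda a: a.patient_id)
    pd.DataFrame([{"patient_id": a.patient_id, "site_id": a.site_id,
                   "day": a.day} for a in rows]).to_csv(Path(path), index=False)


def read_demand(path, net: SupplyNetwork | None = None) -> DemandSchedule:
    df = pd.read_csv(Path(path))
    sched = DemandSchedule(tuple(
        PatientArrival(str(r.patient_id), str(r.site_id), int(r.day))
        for r in df.itertuples()))
    violations = sched.validate(net)
    if violations:
        raise DemandError("; ".join(violations))
    return sched
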