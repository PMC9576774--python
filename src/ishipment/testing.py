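"""Seeded generators of guard-sized instances for cross-checking the MILP
against the exhaustive-enumeration oracle."""

from __future__ import annotations

import numpy as np

from .demand import DemandSchedule, PatientArrival
from .model import ScenarioConfig
from .network import (ClinicalSite, FacilityCandidate, SupplyNetwork,
                      TransportMode, min_return_time)

__all__ = ["random_tiny_instance"]


def random_tiny_instance(seed: int):
    """A random network / demand / scenario triple inside the oracle guards.

    Sizes, durations, costs and bounds are drawn so that the set covers
    feasible and infeasible instances, per-patient and average return-time
    bounds, and facility-count caps.
    """
    rng = np.random.default_rng(seed)
    n_sites = int(rng.integers(1, 3))
    n_fac = int(rng.integers(1, 4))
    n_modes = int(rng.integers(1, 3))
    sites = tuple(ClinicalSite(f"s{i}", f"g{i}", 8) for i in range(n_sites))
    facilities = tuple(
        FacilityCandidate(f"f{i}", int(rng.integers(1, 3)),
                          float(rng.integers(0, 5) * 1000),
                          float(rng.integers(1, 8) * 1000))
        for i in range(n_fac))
    modes = tuple(TransportMode(f"j{i}", i + 1) for i in range(n_modes))
    leg1 = {(c.site_id, f.facility_id, j.mode_id):
            float(rng.integers(1, 9) * 50)
            for c in sites for f in facilities for j in modes}
    leg2 = {(f.facility_id, c.hospital_id, j.mode_id):
            float(rng.integers(1, 9) * 50)
            for c in sites for f in facilities for j in modes}
    net = SupplyNetwork(
        sites=sites, facilities=facilities, modes=modes,
        tls_days=int(rng.integers(0, 2)), tmfe_days=int(rng.integers(2, 5)),
        tqc_days=int(rng.integers(0, 3)),
        qc_cost=float(rng.integers(1, 5) * 100),
        material_cost=float(rng.integers(1, 5) * 200),
        transport_unit_cost_leg1=leg1, transport_unit_cost_leg2=leg2,
        horizon_days=int(rng.integers(16, 24)))
    n_patients = int(rng.integers(1, 4))
    arrivals = tuple(
        PatientArrival(f"p{i}",
                       sites[int(rng.integers(n_sites))].site_id,
                       int(rng.integers(1, 8)))
        for i in range(n_patients))
    demand = DemandSchedule(arrivals)
    mrt = min_return_time(net)
    draw = rng.random()
    if draw < 0.3:
        cfg = ScenarioConfig(
            per_patient_return_bound_days=int(mrt + rng.integers(-2, 4)))
    elif draw < 0.6:
        cfg = ScenarioConfig(
            average_return_bound_days=float(mrt + rng.integers(-1, 4)))
    else:
        cfg = ScenarioConfig(max_facilities=int(rng.integers(1, n_fac + 1)))
    return net, demand, cfg
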