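"""Solving, independent solution validation and KPI extraction."""

import dataclasses

import pytest

import ishipment as ish
from ishipment.solve import SolverError, read_solution, write_solution
from ishipment.validate import capacity_violations, extract_journeys
from tests.conftest import make_demand


@pytest.fixture(scope="module")
def solved_tiny2():
    net = ish.load_fixture("tiny2")
    demand = make_demand(("p1", "s1", 2), ("p2", "s2", 3), ("p3", "s1", 6))
    cfg = ish.ScenarioConfig()
    sol = ish.solve(ish.build_model(net, demand, cfg), 60, 1e-6)
    return net, demand, cfg, sol


class TestSolve:
    def test_tiny2_reaches_proven_optimality(self, solved_tiny2):
        net, demand, cfg, sol = solved_tiny2
        assert sol.status == "optimal"
        assert sol.gap_fraction <= 1e-6
        oracle = ish.enumerate_optimal(net, demand, cfg)
        assert oracle.feasible
        assert sol.objective_value == pytest.approx(oracle.min_cost, rel=1e-9)

    def test_return_bound_below_fastest_journey_infeasible(self, tiny2):
        demand = make_demand(("p1", "s1", 2))
        cfg = ish.ScenarioConfig(
            per_patient_return_bound_days=ish.min_return_time(tiny2) - 1)
        sol = ish.solve(ish.build_model(tiny2, demand, cfg), 30, 1e-6)
        assert sol.status == "infeasible"

    def test_unknown_solver_is_environment_error(self, tiny2, two_patients):
        model = ish.build_model(tiny2, two_patients)
        with pytest.raises(SolverError):
            ish.solve(model, 10, 1e-4, solver="cplex")

    def test_solution_round_trips_through_json(self, solved_tiny2, tmp_path):
        _, _, _, sol = solved_tiny2
        write_solution(sol, tmp_path / "solution.json")
        back = read_solution(tmp_path / "solution.json")
        assert back.status == sol.status
        assert back.objective_value == pytest.approx(sol.objective_value)
        assert back.family("Y1") == sol.family("Y1")
        assert back.family("E1") == sol.family("E1")


class TestValidate:
    def test_solver_optimum_is_clean(self, solved_tiny2):
        net, demand, cfg, sol = solved_tiny2
        assert ish.validate_solution(sol, net, demand, cfg) == []

    def test_corrupted_return_leg_names_the_patient(self, solved_tiny2):
        net, demand, cfg, sol = solved_tiny2
        corrupted = dataclasses.replace(
            sol, variables={f: dict(v) for f, v in sol.variables.items()})
        y2 = corrupted.variables["Y2"]
        (p, m, h, j, t), = [k for k in y2 if k[0] == "p1"]
        other = next(hh for hh in net.hospital_ids if hh != h)
        del y2[(p, m, h, j, t)]
        y2[(p, m, other, j, t)] = 1.0
        violations = ish.validate_solution(corrupted, net, demand, cfg)
        assert any("p1" in v and "co-located" in v for v in violations)

    def test_overloaded_facility_flagged_at_the_right_day(self):
        # three therapies entering two lines on the same day
        entries = {"f1": [5, 5, 5]}
        violations = capacity_violations(entries, {"f1": 2}, tmfe=3, proc=5,
                                         horizon=20)
        assert any("(f1,5)" in v for v in violations)

    def test_objective_matches_raw_value_recomputation(self, solved_tiny2):
        net, demand, cfg, sol = solved_tiny2
        from ishipment.validate import recompute_objective
        assert recompute_objective(sol, net, demand) == pytest.approx(
            sol.objective_value, rel=1e-6)

    def test_each_patient_delivered_once_to_own_hospital(self, solved_tiny2):
        net, demand, cfg, sol = solved_tiny2
        journeys = extract_journeys(sol, net, demand)
        assert set(journeys) == set(demand.patient_ids)
        for p, jn in journeys.items():
            assert jn.hospital_id == net.hospital_of[demand.site_of(p)]
            inh = [idx for idx, v in sol.family("INH").items()
                   if idx[0] == p and v > 0.5]
            assert len(inh) == 1


class TestKpis:
    def test_report_fields_are_consistent(self, solved_tiny2):
        net, demand, cfg, sol = solved_tiny2
        k = ish.extract_kpis(sol, net, demand, cfg)
        assert sum(k.cost_shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert k.total_cost == pytest.approx(sol.objective_value)
        assert k.avg_cost_per_therapy == pytest.approx(
            sol.objective_value / demand.n_patients)
        assert k.atrt == pytest.approx(
            sum(k.trt_per_patient.values()) / len(k.trt_per_patient))
        assert sum(n for (leg, _), n in k.mode_usage.items()
                   if leg == "leg1") == demand.n_patients

    def test_zero_transport_cost_gives_zero_share(self, tiny2):
        net = dataclasses.replace(
            tiny2,
            transport_unit_cost_leg1={k: 0.0 for k in
                                      tiny2.transport_unit_cost_leg1},
            transport_unit_cost_leg2={k: 0.0 for k in
                                      tiny2.transport_unit_cost_leg2})
        demand = make_demand(("p1", "s1", 2))
        cfg = ish.ScenarioConfig()
        sol = ish.solve(ish.build_model(net, demand, cfg), 30, 1e-6)
        k = ish.extract_kpis(sol, net, demand, cfg)
        assert k.cost_shares["transport"] == 0.0
        assert k.avg_cost_per_therapy == pytest.approx(sol.objective_value)

    def test_utilisation_conserves_manufacturing_days(self, solved_tiny2):
        net, demand, cfg, sol = solved_tiny2
        k = ish.extract_kpis(sol, net, demand, cfg)
        lines = {f.facility_id: f.parallel_lines for f in net.facilities}
        total = sum(r * lines[m] for (m, t), r in k.utilisation.items())
        assert total == pytest.approx(demand.n_patients * net.tmfe_days)

    def test_weekly_capacity_conversion(self):
        assert ish.weekly_capacity(4, 7) == 4
        assert ish.weekly_capacity(31, 7) == 31
        assert ish.weekly_capacity(10, 19) == 3   # 10 lines, 19-day process
        assert ish.weekly_capacity(31, 19) == 11
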