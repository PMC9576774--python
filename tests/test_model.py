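"""Structure of the assembled MILP: index families, constraint registry,
balance timing and capacity semantics."""

import dataclasses

import pytest

import ishipment as ish
from ishipment.demand import DemandSchedule
from ishipment.model import BuildError, expected_tags
from tests.conftest import make_demand


def _one_facility_net(tiny2, lines):
    """tiny2 reduced to facility f1 with the given number of parallel lines."""
    f1 = dataclasses.replace(tiny2.facilities[0], parallel_lines=lines)
    leg1 = {k: v for k, v in tiny2.transport_unit_cost_leg1.items()
            if k[1] == "f1"}
    leg2 = {k: v for k, v in tiny2.transport_unit_cost_leg2.items()
            if k[0] == "f1"}
    return dataclasses.replace(tiny2, facilities=(f1,),
                               transport_unit_cost_leg1=leg1,
                               transport_unit_cost_leg2=leg2)


class TestFamilies:
    def test_tiny2_indicator_family_sizes(self, tiny2, two_patients):
        model = ish.build_model(tiny2, two_patients)
        assert len(model.lm.family("E1")) == 2
        assert len(model.lm.family("Y1")) <= 2 * 2 * 2 * 2 * 30
        assert len(model.lm.family("Y1")) == 480
        assert len(model.lm.family("Y2")) == 480

    def test_empty_demand_binary_count(self, tiny2):
        model = ish.build_model(tiny2, DemandSchedule(()))
        stats = ish.count_statistics(model)
        n_m, n_c, n_h = 2, 2, 2
        assert stats.n_binary == n_m + n_c * n_m + n_m * n_h
        sol = ish.solve(model, 30, 1e-6)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_counts_match_hand_enumeration(self, tiny2):
        """Exact variable/constraint census for a one-patient instance."""
        net = dataclasses.replace(tiny2, horizon_days=12, tmfe_days=3,
                                  tqc_days=2)
        demand = make_demand(("p1", "s1", 2))
        model = ish.build_model(
            net, demand, ish.ScenarioConfig(per_patient_return_bound_days=12))
        stats = ish.count_statistics(model)
        P, C, H, M, J, T = 1, 2, 2, 2, 2, 12
        tls, proc = 1, 5
        durs = [1, 2]
        cmjt = C * M * J * T
        mhjt = M * H * J * T
        assert stats.n_binary == M + C * M + M * H + P * (cmjt + mhjt)
        n_cont = (P * (C * T + 2 * cmjt + 3 * M * T + 2 * mhjt + H * T + 5)
                  + M * T + 2)
        assert stats.n_continuous == n_cont
        shifted1 = C * M * sum(T - d for d in durs)
        shifted2 = M * H * sum(T - d for d in durs)
        n_rows = (
            P + P + 1                                  # cost definitions
            + P * C * (T - tls) + P * shifted1 + P * C * T + P * M * T
            + P * M * (T - proc) + P * M * T + P * shifted2 + P * H * T
            + 3 * M * T                                # capacity + safeguard
            + C * M + M * H + 2 * P + 1                # matches, journeys, cap
            + P * cmjt + P * mhjt                      # indicator gating
            + P * (H - 1)                              # co-location
            + 2 * P * cmjt + 2 * P * mhjt              # flow bounds
            + 1                                        # demand satisfaction
            + P * M * T                                # occupancy profile
            + 5 * P + 1                                # time bookkeeping
        )
        assert stats.n_constraints == n_rows

    def test_counts_monotone_in_patients(self, tiny2):
        d1 = make_demand(("p1", "s1", 2))
        d2 = make_demand(("p1", "s1", 2), ("p2", "s2", 3))
        s1 = ish.count_statistics(ish.build_model(tiny2, d1))
        s2 = ish.count_statistics(ish.build_model(tiny2, d2))
        assert s2.n_binary > s1.n_binary
        assert s2.n_continuous > s1.n_continuous
        assert s2.n_constraints > s1.n_constraints

    def test_registry_covers_every_constraint_family(self, tiny2,
                                                     two_patients):
        cfg = ish.ScenarioConfig(max_facilities=2,
                                 per_patient_return_bound_days=20)
        model = ish.build_model(tiny2, two_patients, cfg)
        assert set(model.constraint_tags()) == expected_tags(cfg, 2)

    def test_horizon_too_short_is_build_error(self, tiny2, two_patients):
        net = dataclasses.replace(tiny2, horizon_days=7)
        with pytest.raises(BuildError, match="horizon"):
            ish.build_model(net, two_patients)


class TestBalanceTiming:
    def test_sample_leaves_one_leukapheresis_duration_after_checkin(
            self, tiny2):
        demand = make_demand(("p1", "s1", 3))
        sol = ish.solve(ish.build_model(tiny2, demand), 30, 1e-6)
        outc = {idx for idx, v in sol.family("OUTC").items() if v > 0.5}
        assert outc == {("p1", "s1", 4)}  # arrival day 3 + TLS 1

    def test_facility_exit_follows_manufacturing_and_qc(self, tiny2):
        demand = make_demand(("p1", "s2", 5))
        sol = ish.solve(ish.build_model(tiny2, demand), 30, 1e-6)
        (p, m, t_in), = (idx for idx, v in sol.family("INM").items()
                         if v > 0.5)
        (_, _, t_out), = (idx for idx, v in sol.family("OUTM").items()
                          if v > 0.5)
        assert t_out == t_in + tiny2.tmfe_days + tiny2.tqc_days

    def test_fastest_journey_arrives_at_min_return_time(self, tiny2):
        demand = make_demand(("p1", "s1", 2))
        cfg = ish.ScenarioConfig(
            per_patient_return_bound_days=ish.min_return_time(tiny2))
        sol = ish.solve(ish.build_model(tiny2, demand, cfg), 30, 1e-6)
        assert sol.status == "optimal"
        (p, h, t), = (idx for idx, v in sol.family("INH").items() if v > 0.5)
        assert h == "g1"
        assert t == 2 + ish.min_return_time(tiny2)

    def test_occupancy_profile_spans_entry_to_exit(self, tiny2):
        """The per-day occupancy indicator is 1 from the day after entry
        through the exit day, as the cumulative balance defines it."""
        demand = make_demand(("p1", "s1", 2))
        sol = ish.solve(ish.build_model(tiny2, demand), 30, 1e-6)
        (_, m, t_in), = (idx for idx, v in sol.family("INM").items()
                         if v > 0.5)
        proc = tiny2.tmfe_days + tiny2.tqc_days
        occupied = {t for (p, mm, t), v in sol.family("DURM").items()
                    if mm == m and v > 0.5}
        assert occupied == set(range(t_in + 1, t_in + proc + 1))


class TestCapacity:
    def test_three_same_day_arrivals_overload_two_lines(self, tiny2):
        net = _one_facility_net(tiny2, lines=2)
        demand = make_demand(("p1", "s1", 2), ("p2", "s1", 2), ("p3", "s2", 2))
        sol = ish.solve(ish.build_model(net, demand), 30, 1e-6)
        assert sol.status == "infeasible"

    def test_two_same_day_arrivals_fit_four_lines(self, tiny2):
        # the running-window accounting counts a same-day entry both in the
        # window and on the load side, so concurrent entries need headroom
        net = _one_facility_net(tiny2, lines=4)
        demand = make_demand(("p1", "s1", 2), ("p2", "s2", 2))
        sol = ish.solve(ish.build_model(net, demand), 30, 1e-6)
        assert sol.status == "optimal"

    def test_arrivals_staggered_beyond_window_fit(self, tiny2):
        net = _one_facility_net(tiny2, lines=2)
        gap = tiny2.tmfe_days + 1
        demand = make_demand(("p1", "s1", 2), ("p2", "s1", 2 + gap),
                             ("p3", "s1", 2 + 2 * gap))
        sol = ish.solve(ish.build_model(net, demand), 30, 1e-6)
        assert sol.status == "optimal"

    def test_five_same_day_patients_on_four_lines_infeasible(self, tiny2):
        net = _one_facility_net(tiny2, lines=4)
        demand = make_demand(("p1", "s1", 2), ("p2", "s1", 2), ("p3", "s1", 2),
                             ("p4", "s2", 2), ("p5", "s2", 2))
        sol = ish.solve(ish.build_model(net, demand), 30, 1e-6)
        assert sol.status == "infeasible"


class TestNetworkLogic:
    def test_facility_cap_limits_open_set(self, tiny2, two_patients):
        cfg = ish.ScenarioConfig(max_facilities=1)
        sol = ish.solve(ish.build_model(tiny2, two_patients, cfg), 30, 1e-6)
        assert sol.status == "optimal"
        assert sum(1 for v in sol.family("E1").values() if v > 0.5) == 1

    def test_return_leg_locked_to_colocated_hospital(self, tiny2,
                                                     two_patients):
        sol = ish.solve(ish.build_model(tiny2, two_patients), 30, 1e-6)
        for (p, m, h, j, t), v in sol.family("Y2").items():
            if v > 0.5:
                own = tiny2.hospital_of[two_patients.site_of(p)]
                assert h == own
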