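"""Network data model, file I/O and journey arithmetic."""

import dataclasses
import shutil

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ishipment as ish
from ishipment.network import (NetworkIOError, NetworkValidationError,
                               amortised_capital_cost, fixture_path,
                               load_network, min_return_time, validate_network,
                               write_network)


class TestFixtures:
    def test_paper6_candidate_capacities(self, paper6):
        assert len(paper6.facilities) == 6
        assert {f.parallel_lines for f in paper6.facilities} == {4, 10, 31}
        assert validate_network(paper6) == []

    def test_tiny2_shape(self, tiny2):
        assert len(tiny2.sites) == 2
        assert len(tiny2.facilities) == 2
        assert len(tiny2.modes) == 2
        assert tiny2.horizon_days == 30

    def test_unknown_fixture(self):
        with pytest.raises(NetworkIOError):
            ish.load_fixture("nope")


class TestLoadErrors:
    def test_missing_table_names_it(self, tmp_path):
        src = fixture_path("tiny2")
        dst = tmp_path / "net"
        shutil.copytree(src, dst)
        (dst / "modes.csv").unlink()
        with pytest.raises(NetworkIOError, match="modes"):
            load_network(dst)

    def test_dangling_hospital_id(self, tmp_path):
        src = fixture_path("tiny2")
        dst = tmp_path / "net"
        shutil.copytree(src, dst)
        text = (dst / "sites.csv").read_text().replace("s2,g2", "s2,gX")
        (dst / "sites.csv").write_text(text)
        with pytest.raises(NetworkValidationError):
            load_network(dst)

    def test_non_bijective_site_hospital_map(self, tmp_path):
        src = fixture_path("tiny2")
        dst = tmp_path / "net"
        shutil.copytree(src, dst)
        text = (dst / "sites.csv").read_text().replace("s2,g2", "s2,g1")
        (dst / "sites.csv").write_text(text)
        with pytest.raises(NetworkValidationError, match="bijection"):
            load_network(dst)


class TestValidate:
    def test_valid_network_reports_nothing(self, paper6):
        assert validate_network(paper6) == []

    def test_fmin_above_fmax(self, tiny2):
        net = dataclasses.replace(tiny2, fmin=2.0, fmax=1.0)
        assert any("fmin>fmax" in v for v in validate_network(net))

    def test_horizon_shorter_than_minimal_journey(self, tiny2):
        net = dataclasses.replace(tiny2, horizon_days=5, tmfe_days=7)
        assert any("horizon shorter than minimal journey" in v
                   for v in validate_network(net))

    def test_incomplete_cost_table(self, tiny2):
        leg1 = dict(tiny2.transport_unit_cost_leg1)
        leg1.pop(("s1", "f1", "e1"))
        net = dataclasses.replace(tiny2, transport_unit_cost_leg1=leg1)
        assert any("transport_unit_cost_leg1 missing" in v
                   for v in validate_network(net))


class TestMinReturnTime:
    def test_paper6_regimes(self, paper6):
        assert min_return_time(paper6) == 17
        assert min_return_time(
            dataclasses.replace(paper6, tmfe_days=19)) == 29

    def test_all_zero_durations(self, tiny2):
        net = dataclasses.replace(
            tiny2, tls_days=0, tmfe_days=0, tqc_days=0,
            modes=tuple(dataclasses.replace(m, duration_days=0)
                        for m in tiny2.modes))
        assert min_return_time(net) == 0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 3), st.integers(1, 20), st.integers(0, 7),
           st.integers(1, 3))
    def test_monotone_in_every_duration(self, tls, tmfe, tqc, fastest):
        net0 = _durations_net(tls, tmfe, tqc, fastest)
        base = min_return_time(net0)
        for field, bumped in [("tls_days", tls + 1), ("tmfe_days", tmfe + 1),
                              ("tqc_days", tqc + 1)]:
            assert min_return_time(
                dataclasses.replace(net0, **{field: bumped})) >= base
        slower = dataclasses.replace(
            net0, modes=tuple(dataclasses.replace(m,
                                                  duration_days=m.duration_days + 1)
                              for m in net0.modes))
        assert min_return_time(slower) >= base


def _durations_net(tls, tmfe, tqc, fastest):
    net = ish.load_fixture("tiny2")
    modes = (dataclasses.replace(net.modes[0], duration_days=fastest),
             dataclasses.replace(net.modes[1], duration_days=fastest + 1))
    return dataclasses.replace(net, tls_days=tls, tmfe_days=tmfe,
                               tqc_days=tqc, modes=modes, horizon_days=500)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv-dir", "json"])
    def test_write_then_load_is_equivalent(self, tiny2, tmp_path, fmt):
        target = tmp_path / ("net" if fmt == "csv-dir" else "net.json")
        write_network(tiny2, target, fmt)
        back = load_network(target, fmt)
        assert sorted(back.sites, key=lambda s: s.site_id) == \
            sorted(tiny2.sites, key=lambda s: s.site_id)
        assert sorted(back.facilities, key=lambda f: f.facility_id) == \
            sorted(tiny2.facilities, key=lambda f: f.facility_id)
        assert sorted(back.modes, key=lambda m: m.mode_id) == \
            sorted(tiny2.modes, key=lambda m: m.mode_id)
        assert back.transport_unit_cost_leg1 == tiny2.transport_unit_cost_leg1
        assert back.transport_unit_cost_leg2 == tiny2.transport_unit_cost_leg2
        for f in ("tls_days", "tmfe_days", "tqc_days", "qc_cost",
                  "material_cost", "horizon_days", "fmin", "fmax"):
            assert getattr(back, f) == getattr(tiny2, f)


def test_amortised_capital_cost():
    # $7.3M over 10 years, one 91-day trimester -> 7.3e6/10 * 91/365
    assert amortised_capital_cost(7.3e6, 10, 91) == pytest.approx(182_000.0)
    with pytest.raises(ValueError):
        amortised_capital_cost(1.0, 0, 91)
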