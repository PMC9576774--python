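"""Static supply-network data model and file I/O.

A :class:`SupplyNetwork` holds everything about the candidate network that does
not depend on individual patients: the leukapheresis sites with their co-located
hospitals, the candidate manufacturing facilities (parallel production lines,
amortised capital and fixed-variable cost), the courier service classes
(24 h / 48 h delivery), process durations and the unit transport-cost tables for
both journey legs.

Networks are read from either a directory of CSV tables or a single JSON
document; both dialects carry the same schema and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "TransportMode", "FacilityCandidate", "ClinicalSite", "SupplyNetwork",
    "NetworkError", "NetworkIOError", "NetworkValidationError",
    "load_network", "write_network", "validate_network", "min_return_time",
    "fixture_path", "load_fixture", "amortised_capital_cost",
]

_CSV_TABLES = ("facilities", "sites", "modes",
               "transport_leg1", "transport_leg2", "globals")


class NetworkError(ValueError):
    """Base class for supply-network errors."""


class NetworkIOError(NetworkError):
    """A required table or file is missing or unreadable."""


class NetworkValidationError(NetworkError):
    """The parsed network violates a structural invariant."""


@dataclass(frozen=True)
class TransportMode:
    """A courier service class; delivery duration is the same on both legs."""

    mode_id: str
    duration_days: int


@dataclass(frozen=True)
class FacilityCandidate:
    """A candidate manufacturing facility.

    ``parallel_lines`` is the number of therapies the facility can process
    concurrently.  ``capital_cost`` is the capital investment already amortised
    to the modelled horizon; ``fixed_variable_cost`` is the utilisation-
    independent share of variable manufacturing cost (personnel, equipment
    maintenance) over the same horizon.
    """

    facility_id: str
    parallel_lines: int
    capital_cost: float
    fixed_variable_cost: float
    region: str = ""


@dataclass(frozen=True)
class ClinicalSite:
    """A leukapheresis site and its co-located administration hospital."""

    site_id: str
    hospital_id: str
    daily_capacity: int = 8


@dataclass
class SupplyNetwork:
    sites: tuple[ClinicalSite, ...]
    facilities: tuple[FacilityCandidate, ...]
    modes: tuple[TransportMode, ...]
    tls_days: int            # leukapheresis procedure duration
    tmfe_days: int           # manufacturing duration
    tqc_days: int            # quality-control duration
    qc_cost: float           # QC cost per therapy
    material_cost: float     # material (variable) cost per therapy, default
    transport_unit_cost_leg1: dict  # (site_id, facility_id, mode_id) -> $/day
    transport_unit_cost_leg2: dict  # (facility_id, hospital_id, mode_id) -> $/day
    horizon_days: int
    fmin: float = 0.0
    fmax: float = 1.0
    material_cost_overrides: dict = field(default_factory=dict)  # patient_id -> $

    # -- convenience views ---------------------------------------------------
    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    @property
    def hospital_ids(self) -> tuple[str, ...]:
        return tuple(s.hospital_id for s in self.sites)

    @property
    def facility_ids(self) -> tuple[str, ...]:
        return tuple(f.facility_id for f in self.facilities)

    @property
    def mode_ids(self) -> tuple[str, ...]:
        return tuple(m.mode_id for m in self.modes)

    @property
    def hospital_of(self) -> dict:
        """site_id -> co-located hospital_id."""
        return {s.site_id: s.hospital_id for s in self.sites}

    @property
    def site_of_hospital(self) -> dict:
        return {s.hospital_id: s.site_id for s in self.sites}

    def site(self, site_id: str) -> ClinicalSite:
        return next(s for s in self.sites if s.site_id == site_id)

    def facility(self, facility_id: str) -> FacilityCandidate:
        return next(f for f in self.facilities if f.facility_id == facility_id)

    def mode(self, mode_id: str) -> TransportMode:
        return next(m for m in self.modes if m.mode_id == mode_id)

    def mode_duration(self, mode_id: str) -> int:
        return self.mode(mode_id).duration_days

    def material_cost_of(self, patient_id: str) -> float:
        return float(self.material_cost_overrides.get(patient_id,
                                                      self.material_cost))


def min_return_time(net: SupplyNetwork) -> int:
    """Fastest possible vein-to-vein time in days.

    Leukapheresis + fastest outbound courier + manufacturing + QC + fastest
    return courier.  Pure arithmetic on the stored durations; no validation.
    """
    fastest = min((m.duration_days for m in net.modes), default=0)
    return int(net.tls_days + fastest + net.tmfe_days + net.tqc_days + fastest)


def validate_network(net: SupplyNetwork) -> list[str]:
    """Return a list of invariant violations (empty iff the network is valid)."""
    v: list[str] = []

    def dup(ids, what):
        seen, d = set(), set()
        for i in ids:
            (d if i in seen else seen).add(i)
            seen.add(i)
        if d:
            v.append(f"duplicate {what} ids: {sorted(d)}")

    dup(net.mode_ids, "mode")
    dup(net.facility_ids, "facility")
    dup(net.site_ids, "site")
    dup(net.hospital_ids, "hospital")
    if len(set(net.hospital_ids)) != len(net.sites):
        v.append("site<->hospital map is not a bijection")

    for m in net.modes:
        if m.duration_days < 1:
            v.append(f"mode {m.mode_id}: duration_days must be >= 1")
    for f in net.facilities:
        if f.parallel_lines < 1:
            v.append(f"facility {f.facility_id}: parallel_lines must be >= 1")
        if f.capital_cost < 0:
            v.append(f"facility {f.facility_id}: capital_cost must be >= 0")
        if f.fixed_variable_cost < 0:
            v.append(f"facility {f.facility_id}: fixed_variable_cost must be >= 0")
    for s in net.sites:
        if s.daily_capacity < 1:
            v.append(f"site {s.site_id}: daily_capacity must be >= 1")

    if net.tls_days < 0 or net.tqc_days < 0:
        v.append("tls_days and tqc_days must be >= 0")
    if net.tmfe_days < 1:
        v.append("tmfe_days must be >= 1")
    if net.fmin > net.fmax:
        v.append("fmin>fmax")
    if net.qc_cost < 0 or net.material_cost < 0:
        v.append("qc_cost and material_cost must be >= 0")

    # cost-table completeness over the full index sets
    for c in net.site_ids:
        for m in net.facility_ids:
            for j in net.mode_ids:
                if (c, m, j) not in net.transport_unit_cost_leg1:
                    v.append(f"transport_unit_cost_leg1 missing ({c},{m},{j})")
    for m in net.facility_ids:
        for h in net.hospital_ids:
            for j in net.mode_ids:
                if (m, h, j) not in net.transport_unit_cost_leg2:
                    v.append(f"transport_unit_cost_leg2 missing ({m},{h},{j})")
    known1 = set(net.site_ids), set(net.facility_ids), set(net.mode_ids)
    for (c, m, j) in net.transport_unit_cost_leg1:
        if c not in known1[0] or m not in known1[1] or j not in known1[2]:
            v.append(f"transport_unit_cost_leg1 references unknown ids ({c},{m},{j})")
    known2 = set(net.facility_ids), set(net.hospital_ids), set(net.mode_ids)
    for (m, h, j) in net.transport_unit_cost_leg2:
        if m not in known2[0] or h not in known2[1] or j not in known2[2]:
            v.append(f"transport_unit_cost_leg2 references unknown ids ({m},{h},{j})")

    if net.horizon_days < 1:
        v.append("horizon_days must be >= 1")
    elif net.modes and net.horizon_days < min_return_time(net):
        v.append("horizon shorter than minimal journey")
    return v


# --------------------------------------------------------------------- I/O

def _globals_from_mapping(g: dict) -> dict:
    try:
        return dict(
            tls_days=int(g["TLS"]), tmfe_days=int(g["TMFE"]),
            tqc_days=int(g["TQC"]), qc_cost=float(g["CQC"]),
            material_cost=float(g["CVM"]), horizon_days=int(g["HORIZON"]),
            fmin=float(g.get("FMIN", 0.0)), fmax=float(g.get("FMAX", 1.0)),
        )
    except KeyError as e:  # pragma: no cover - message detail only
        raise NetworkIOError(f"globals table missing key {e}") from e


def _assemble(facilities, sites, modes, leg1, leg2, g) -> SupplyNetwork:
    net = SupplyNetwork(
        sites=tuple(sites), facilities=tuple(facilities), modes=tuple(modes),
        transport_unit_cost_leg1=leg1, transport_unit_cost_leg2=leg2,
        **_globals_from_mapping(g),
    )
    violations = validate_network(net)
    if violations:
        raise NetworkValidationError("; ".join(violations))
    return net


def load_network(path, fmt: str | None = None) -> SupplyNetwork:
    """Load and validate a network from a CSV directory or a JSON file."""
    path = Path(path)
    if fmt is None:
        fmt = "csv-dir" if path.is_dir() else "json"
    if fmt == "csv-dir":
        tables = {}
        for name in _CSV_TABLES:
            f = path / f"{name}.csv"
            if not f.exists():
                raise NetworkIOError(f"missing table {name}.csv in {path}")
            tables[name] = pd.read_csv(f)
        facilities = [FacilityCandidate(str(r.facility_id), int(r.parallel_lines),
                                        float(r.capital_cost),
                                        float(r.fixed_variable_cost),
                                        str(r.region))
                      for r in tables["facilities"].itertuples()]
        sites = [ClinicalSite(str(r.site_id), str(r.hospital_id),
                              int(r.daily_capacity))
                 for r in tables["sites"].itertuples()]
        modes = [TransportMode(str(r.mode_id), int(r.duration_days))
                 for r in tables["modes"].itertuples()]
        leg1 = {(str(r.site_id), str(r.facility_id), str(r.mode_id)):
                float(r.unit_cost)
                for r in tables["transport_leg1"].itertuples()}
        leg2 = {(str(r.facility_id), str(r.hospital_id), str(r.mode_id)):
                float(r.unit_cost)
                for r in tables["transport_leg2"].itertuples()}
        g = dict(zip(tables["globals"]["key"].astype(str),
                     tables["globals"]["value"]))
        return _assemble(facilities, sites, modes, leg1, leg2, g)
    if fmt == "json":
        if not path.exists():
            raise NetworkIOError(f"missing file {path}")
        doc = json.loads(path.read_text())
        for key in ("facilities", "sites", "modes",
                    "transport_leg1", "transport_leg2", "globals"):
            if key not in doc:
                raise NetworkIOError(f"missing table {key} in {path}")
        facilities = [FacilityCandidate(str(d["facility_id"]),
                                        int(d["parallel_lines"]),
                                        float(d["capital_cost"]),
                                        float(d["fixed_variable_cost"]),
                                        str(d.get("region", "")))
                      for d in doc["facilities"]]
        sites = [ClinicalSite(str(d["site_id"]), str(d["hospital_id"]),
                              int(d.get("daily_capacity", 8)))
                 for d in doc["sites"]]
        modes = [TransportMode(str(d["mode_id"]), int(d["duration_days"]))
                 for d in doc["modes"]]
        leg1 = {(str(d["site_id"]), str(d["facility_id"]), str(d["mode_id"])):
                float(d["unit_cost"]) for d in doc["transport_leg1"]}
        leg2 = {(str(d["facility_id"]), str(d["hospital_id"]), str(d["mode_id"])):
                float(d["unit_cost"]) for d in doc["transport_leg2"]}
        return _assemble(facilities, sites, modes, leg1, leg2, doc["globals"])
    raise ValueError(f"unknown format {fmt!r}")


def write_network(net: SupplyNetwork, path, fmt: str = "csv-dir") -> None:
    """Write a network in canonical (id-sorted) order."""
    path = Path(path)
    facilities = sorted(net.facilities, key=lambda f: f.facility_id)
    sites = sorted(net.sites, key=lambda s: s.site_id)
    modes = sorted(net.modes, key=lambda m: m.duration_days)
    g = {"TLS": net.tls_days, "TMFE": net.tmfe_days, "TQC": net.tqc_days,
         "CQC": net.qc_cost, "CVM": net.material_cost,
         "HORIZON": net.horizon_days, "FMIN": net.fmin, "FMAX": net.fmax}
    if fmt == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(f) for f in facilities]).to_csv(
            path / "facilities.csv", index=False)
        pd.DataFrame([dataclasses.asdict(s) for s in sites]).to_csv(
            path / "sites.csv", index=False)
        pd.DataFrame([dataclasses.asdict(m) for m in modes]).to_csv(
            path / "modes.csv", index=False)
        pd.DataFrame(
            [{"site_id": c, "facility_id": m, "mode_id": j, "unit_cost": u}
             for (c, m, j), u in sorted(net.transport_unit_cost_leg1.items())]
        ).to_csv(path / "transport_leg1.csv", index=False)
        pd.DataFrame(
            [{"facility_id": m, "hospital_id": h, "mode_id": j, "unit_cost": u}
             for (m, h, j), u in sorted(net.transport_unit_cost_leg2.items())]
        ).to_csv(path / "transport_leg2.csv", index=False)
        pd.DataFrame({"key": list(g), "value": list(g.values())}).to_csv(
            path / "globals.csv", index=False)
    elif fmt == "json":
        doc = {
            "globals": g,
            "facilities": [dataclasses.asdict(f) for f in facilities],
            "sites": [dataclasses.asdict(s) for s in sites],
            "modes": [dataclasses.asdict(m) for m in modes],
            "transport_leg1": [
                {"site_id": c, "facility_id": m, "mode_id": j, "unit_cost": u}
                for (c, m, j), u in sorted(net.transport_unit_cost_leg1.items())],
            "transport_leg2": [
                {"facility_id": m, "hospital_id": h, "mode_id": j, "unit_cost": u}
                for (m, h, j), u in sorted(net.transport_unit_cost_leg2.items())],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def fixture_path(name: str) -> Path:
    """Path of a bundled network fixture directory (e.g. 'paper6', 'tiny2')."""
    p = Path(str(resources.files("ishipment") / "fixtures" / name))
    if not p.exists():
        raise NetworkIOError(f"no bundled fixture named {name!r}")
    return p


def load_fixture(name: str) -> SupplyNetwork:
    return load_network(fixture_path(name), "csv-dir")


def amortised_capital_cost(asset_cost: float, amortisation_years: float,
                           horizon_days: int) -> float:
    """Convert an asset price into the capital charge carried by one horizon.

    The stored ``capital_cost`` of a :class:`FacilityCandidate` is expected to
    be pre-amortised; this helper documents the conversion:
    asset cost / amortisation years x (horizon / 365 days).
    """
    if amortisation_years <= 0:
        raise ValueError("amortisation_years must be > 0")
    return asset_cost / amortisation_years * (horizon_days / 365.0)
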