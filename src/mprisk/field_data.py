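"""Domain types, validation, and tabular I/O for a microplastic sampling campaign.

A campaign is three cross-linked tables: sampling *sites*, physical *samples*
(water grab / plankton net, sediment bed load / suspended load) and individual
identified *particles*.  Files are UTF-8 CSV with one header row, "." decimal
separator and fixed column names (see ``SITE_COLUMNS`` etc.).

Particle-level rows are optional: the per-sample ``particle_count`` column is
authoritative in abundance-only mode, but when particle rows exist for a
sample they must agree with it or loading fails.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

__all__ = [
    "LocationGroup",
    "PositionTag",
    "Compartment",
    "Method",
    "Shape",
    "Color",
    "Polymer",
    "SiteRecord",
    "NetSamplingGeometry",
    "SampleRecord",
    "ParticleRecord",
    "Campaign",
    "CampaignError",
    "read_campaign",
    "write_campaign",
    "SITE_COLUMNS",
    "SAMPLE_COLUMNS",
    "PARTICLE_COLUMNS",
    "MAX_PARTICLE_DIMENSION_UM",
]

#: Definitional upper bound on a microplastic's maximum dimension (5 mm).
MAX_PARTICLE_DIMENSION_UM = 5000.0

#: Default plankton-net deployment duration, seconds (5 minutes).
DEFAULT_NET_DURATION_S = 300.0


class LocationGroup(str, enum.Enum):
    """River location a site belongs to: treatment plant, hydro-dam, confluence."""

    WWTP = "WWTP"
    NHD = "NHD"
    CONFLUENCE = "CONFLUENCE"


class PositionTag(str, enum.Enum):
    """Position of the site relative to its location's feature."""

    US = "US"  # upstream
    EF = "EF"  # effluent (WWTP only)
    DS = "DS"  # downstream
    CON = "CON"  # at the confluence


class Compartment(str, enum.Enum):
    WATER = "water"
    SEDIMENT = "sediment"


class Method(str, enum.Enum):
    """Sampling method: WC grab water, PN plankton net, BL bed load, SSL suspended load."""

    WC = "WC"
    PN = "PN"
    BL = "BL"
    SSL = "SSL"


#: Methods valid for each compartment.
WATER_METHODS = frozenset({Method.WC, Method.PN})
SEDIMENT_METHODS = frozenset({Method.BL, Method.SSL})


class Shape(str, enum.Enum):
    FIBER = "fiber"
    FRAGMENT = "fragment"
    FOAM = "foam"


class Color(str, enum.Enum):
    GREEN = "green"
    BLACK = "black"
    TRANSPARENT = "transparent"
    BLUE = "blue"
    YELLOW = "yellow"
    PINK = "pink"


class Polymer(str, enum.Enum):
    PE = "PE"
    PP = "PP"
    PS = "PS"
    PET = "PET"
    PVC = "PVC"
    #: Spectral match below the identification threshold; excluded from
    #: polymer composition tables and hazard scoring.
    UNKNOWN = "UNKNOWN"


class CampaignError(ValueError):
    """Raised for any campaign-level validation failure.

    Carries enough context (table, row number, field) to locate the
    offending record in the source file.
    """

    def __init__(self, message: str, *, table: str | None = None,
                 row: int | None = None, fields: str | None = None):
        loc = []
        if table:
            loc.append(f"table={table}")
        if row is not None:
            loc.append(f"row={row}")
        if fields:
            loc.append(f"field={fields}")
        suffix = f" [{', '.join(loc)}]" if loc else ""
        super().__init__(message + suffix)
        self.table = table
        self.row = row
        self.fields = fields


class SiteRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    site_id: str
    location_group: LocationGroup
    position_tag: PositionTag
    latitude: float
    longitude: float
    sampled_at: datetime

    @field_validator("site_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("site_id must be non-empty")
        return v

    @field_validator("latitude")
    @classmethod
    def _lat_range(cls, v: float) -> float:
        if not -90.0 <= v <= 90.0:
            raise ValueError(f"latitude {v} outside [-90, 90]")
        return v

    @field_validator("longitude")
    @classmethod
    def _lon_range(cls, v: float) -> float:
        if not -180.0 <= v <= 180.0:
            raise ValueError(f"longitude {v} outside [-180, 180]")
        return v

    @model_validator(mode="after")
    def _effluent_only_at_wwtp(self) -> "SiteRecord":
        if self.position_tag is PositionTag.EF and self.location_group is not LocationGroup.WWTP:
            raise ValueError("position_tag EF is only valid for WWTP sites")
        return self


class NetSamplingGeometry(BaseModel):
    """Plankton-net deployment: aperture area A (m^2), time-averaged flow
    velocity V (m/s) and deployment duration t (s).  The filtered volume
    follows from the continuity equation Q = A*V and Volume = Q*t."""

    model_config = ConfigDict(frozen=True)

    aperture_area: float
    mean_velocity: float
    duration: float = DEFAULT_NET_DURATION_S

    @field_validator("aperture_area", "mean_velocity", "duration")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be strictly positive, got {v}")
        return v


class SampleRecord(BaseModel):
    """One physical sample with its normalization denominator.

    Exactly one denominator must be present and match the method:
    ``grab_volume`` (L) for WC, ``net_geometry`` for PN, ``dry_mass``
    (kg dry weight) for BL/SSL.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    site_id: str
    compartment: Compartment
    method: Method
    grab_volume: Optional[float] = None
    net_geometry: Optional[NetSamplingGeometry] = None
    dry_mass: Optional[float] = None
    particle_count: int

    @field_validator("sample_id", "site_id")
    @classmethod
    def _nonempty(cls, v: str, info) -> str:
        if not v:
            raise ValueError(f"{info.field_name} must be non-empty")
        return v

    @field_validator("particle_count")
    @classmethod
    def _count_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError(f"particle_count must be non-negative, got {v}")
        return v

    @model_validator(mode="after")
    def _method_compartment_denominator(self) -> "SampleRecord":
        if self.method in WATER_METHODS and self.compartment is not Compartment.WATER:
            raise ValueError(f"method {self.method.value} requires compartment water")
        if self.method in SEDIMENT_METHODS and self.compartment is not Compartment.SEDIMENT:
            raise ValueError(f"method {self.method.value} requires compartment sediment")
        present = {
            "grab_volume": self.grab_volume is not None,
            "net_geometry": self.net_geometry is not None,
            "dry_mass": self.dry_mass is not None,
        }
        expected = {
            Method.WC: "grab_volume",
            Method.PN: "net_geometry",
            Method.BL: "dry_mass",
            Method.SSL: "dry_mass",
        }[self.method]
        extras = [k for k, p in present.items() if p and k != expected]
        if extras:
            raise ValueError(
                f"method {self.method.value} takes only {expected}; also got {extras}")
        if not present[expected]:
            raise ValueError(f"method {self.method.value} requires {expected}")
        if self.grab_volume is not None and not self.grab_volume > 0:
            raise ValueError(f"grab_volume must be strictly positive, got {self.grab_volume}")
        if self.dry_mass is not None and not self.dry_mass > 0:
            raise ValueError(f"dry_mass must be strictly positive, got {self.dry_mass}")
        return self


class ParticleRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    particle_id: str
    sample_id: str
    max_dimension: float  # µm
    shape: Shape
    color: Color
    polymer: Polymer

    @field_validator("max_dimension")
    @classmethod
    def _dimension_range(cls, v: float) -> float:
        if not 0 < v <= MAX_PARTICLE_DIMENSION_UM:
            raise ValueError(
                f"max_dimension {v} µm outside (0, {MAX_PARTICLE_DIMENSION_UM:g}] µm "
                "(microplastic definitional bound)")
        return v


@dataclass
class Campaign:
    """A validated, cross-linked sampling campaign."""

    sites: list[SiteRecord]
    samples: list[SampleRecord]
    particles: list[ParticleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def site_by_id(self) -> dict[str, SiteRecord]:
        return {s.site_id: s for s in self.sites}

    @property
    def sample_by_id(self) -> dict[str, SampleRecord]:
        return {s.sample_id: s for s in self.samples}

    def particles_of(self, sample_id: str) -> list[ParticleRecord]:
        return [p for p in self.particles if p.sample_id == sample_id]

    @property
    def has_particle_data(self) -> bool:
        return len(self.particles) > 0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            dup = sorted({i for i in site_ids if site_ids.count(i) > 1})
            raise CampaignError(f"duplicate site_id values {dup}", table="sites", fields="site_id")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dup = sorted({i for i in sample_ids if sample_ids.count(i) > 1})
            raise CampaignError(f"duplicate sample_id values {dup}",
                                table="samples", fields="sample_id")
        particle_ids = [p.particle_id for p in self.particles]
        if len(set(particle_ids)) != len(particle_ids):
            dup = sorted({i for i in particle_ids if particle_ids.count(i) > 1})
            raise CampaignError(f"duplicate particle_id values {dup}",
                                table="particles", fields="particle_id")

        known_sites = set(site_ids)
        for i, s in enumerate(self.samples):
            if s.site_id not in known_sites:
                raise CampaignError(f"sample {s.sample_id!r} references unknown site "
                                    f"{s.site_id!r}", table="samples", row=i, fields="site_id")
        known_samples = set(sample_ids)
        per_sample_counts: dict[str, int] = {}
        for i, p in enumerate(self.particles):
            if p.sample_id not in known_samples:
                raise CampaignError(f"particle {p.particle_id!r} references unknown sample "
                                    f"{p.sample_id!r}", table="particles", row=i,
                                    fields="sample_id")
            per_sample_counts[p.sample_id] = per_sample_counts.get(p.sample_id, 0) + 1

        # particle_count is authoritative in abundance-only mode; with
        # particle rows present for a sample the two must agree.
        for sid, n in per_sample_counts.items():
            declared = self.sample_by_id[sid].particle_count
            if n != declared:
                raise CampaignError(
                    f"sample {sid!r} declares particle_count={declared} but has "
                    f"{n} particle rows", table="samples", fields="particle_count")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["site_id", "location_group", "position_tag",
                "latitude", "longitude", "sampled_at"]
SAMPLE_COLUMNS = ["sample_id", "site_id", "compartment", "method", "grab_volume_L",
                  "net_area_m2", "net_velocity_m_s", "net_duration_s",
                  "dry_mass_kg", "particle_count"]
PARTICLE_COLUMNS = ["particle_id", "sample_id", "max_dimension_um",
                    "shape", "color", "polymer"]

_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


def _check_columns(df: pd.DataFrame, expected: list[str], table: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CampaignError(f"missing column(s) {missing}", table=table,
                            fields=",".join(missing))


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def _build(model, table: str, row: int, **kwargs):
    try:
        return model(**kwargs)
    except ValidationError as exc:
        first = exc.errors()[0]
        fields = ".".join(str(p) for p in first["loc"]) or None
        raise CampaignError(first["msg"], table=table, row=row, fields=fields) from exc


def read_campaign(site_table: str | Path, sample_table: str | Path,
                  particle_table: str | Path | None = None) -> Campaign:
    """Load and cross-validate a campaign from CSV files.

    ``particle_table`` may be omitted or point to a header-only file
    (abundance-only mode).  Any invariant violation raises
    :class:`CampaignError` naming the table, row and field.
    """
    sites_df = pd.read_csv(site_table, dtype=str, keep_default_na=False)
    _check_columns(sites_df, SITE_COLUMNS, "sites")
    sites = [
        _build(SiteRecord, "sites", i,
               site_id=r["site_id"], location_group=r["location_group"],
               position_tag=r["position_tag"], latitude=float(r["latitude"]),
               longitude=float(r["longitude"]),
               sampled_at=datetime.strptime(r["sampled_at"], _TIME_FORMAT))
        for i, r in sites_df.iterrows()
    ]

    samples_df = pd.read_csv(sample_table, dtype=str, keep_default_na=False)
    _check_columns(samples_df, SAMPLE_COLUMNS, "samples")
    samples = []
    for i, r in samples_df.iterrows():
        area = _opt_float(r["net_area_m2"])
        velocity = _opt_float(r["net_velocity_m_s"])
        duration = _opt_float(r["net_duration_s"])
        geometry = None
        if any(v is not None for v in (area, velocity, duration)):
            if area is None or velocity is None:
                raise CampaignError("net geometry requires net_area_m2 and net_velocity_m_s",
                                    table="samples", row=i, fields="net_area_m2")
            kwargs = {"aperture_area": area, "mean_velocity": velocity}
            if duration is not None:
                kwargs["duration"] = duration
            geometry = _build(NetSamplingGeometry, "samples", i, **kwargs)
        samples.append(_build(
            SampleRecord, "samples", i,
            sample_id=r["sample_id"], site_id=r["site_id"],
            compartment=r["compartment"], method=r["method"],
            grab_volume=_opt_float(r["grab_volume_L"]),
            net_geometry=geometry,
            dry_mass=_opt_float(r["dry_mass_kg"]),
            particle_count=int(r["particle_count"])))

    particles: list[ParticleRecord] = []
    if particle_table is not None:
        particles_df = pd.read_csv(particle_table, dtype=str, keep_default_na=False)
        _check_columns(particles_df, PARTICLE_COLUMNS, "particles")
        particles = [
            _build(ParticleRecord, "particles", i,
                   particle_id=r["particle_id"], sample_id=r["sample_id"],
                   max_dimension=float(r["max_dimension_um"]),
                   shape=r["shape"], color=r["color"], polymer=r["polymer"])
            for i, r in particles_df.iterrows()
        ]

    return Campaign(sites=sites, samples=samples, particles=particles)


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))  # shortest round-trip representation


def write_campaign(campaign: Campaign, site_table: str | Path,
                   sample_table: str | Path, particle_table: str | Path) -> None:
    """Write the three campaign CSVs; inverse of :func:`read_campaign`."""
    sites_df = pd.DataFrame(
        [{
            "site_id": s.site_id,
            "location_group": s.location_group.value,
            "position_tag": s.position_tag.value,
            "latitude": _fmt(s.latitude),
            "longitude": _fmt(s.longitude),
            "sampled_at": s.sampled_at.strftime(_TIME_FORMAT),
        } for s in campaign.sites],
        columns=SITE_COLUMNS)
    sites_df.to_csv(site_table, index=False, encoding="utf-8")

    samples_df = pd.DataFrame(
        [{
            "sample_id": s.sample_id,
            "site_id": s.site_id,
            "compartment": s.compartment.value,
            "method": s.method.value,
            "grab_volume_L": _fmt(s.grab_volume),
            "net_area_m2": _fmt(s.net_geometry.aperture_area if s.net_geometry else None),
            "net_velocity_m_s": _fmt(s.net_geometry.mean_velocity if s.net_geometry else None),
            "net_duration_s": _fmt(s.net_geometry.duration if s.net_geometry else None),
            "dry_mass_kg": _fmt(s.dry_mass),
            "particle_count": s.particle_count,
        } for s in campaign.samples],
        columns=SAMPLE_COLUMNS)
    samples_df.to_csv(sample_table, index=False, encoding="utf-8")

    particles_df = pd.DataFrame(
        [{
            "particle_id": p.particle_id,
            "sample_id": p.sample_id,
            "max_dimension_um": _fmt(p.max_dimension),
            "shape": p.shape.value,
            "color": p.color.value,
            "polymer": p.polymer.value,
        } for p in campaign.particles],
        columns=PARTICLE_COLUMNS)
    particles_df.to_csv(particle_table, index=False, encoding="utf-8")
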